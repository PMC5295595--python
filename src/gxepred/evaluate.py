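"""Cross-validation harness and model comparison.

CV1 masks every record of a random 20% of lines (prediction of newly
genotyped lines); CV2 spreads each multi-environment line's records across
the five folds, so a masked line stays observed in other environments
(sparse-testing prediction). Five folds, twenty replicates: 100
(training, testing) runs per scheme/model/trait, with the same partitions
analyzed by every model.

Prediction ability is the Pearson correlation between observed and
predicted values of the masked cells, computed within environment. Runs
where either vector has zero variance (or fewer than 3 pairs) are recorded
as missing and excluded from averages, with the exclusion count reported —
coercing them to zero would bias model comparisons.

Aggregation follows the mean-over-runs-within-environment-first convention;
grand means average the environment means. Model differences are assessed
by a two-way ANOVA without interaction (environment as blocking factor) and
Tukey's HSD at alpha = 0.05, reported as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError
from .io import LineEnvTable
from .kernels import IncidenceMap, RelationshipKernel
from .models import (
    MODEL_TERMS,
    SamplerConfig,
    build_model,
    fit_gibbs,
    predict_cells,
)

__all__ = [
    "CVPartition",
    "CVResult",
    "make_cv1",
    "make_cv2",
    "prediction_ability",
    "run_grid",
    "tukey_compare",
]

_SCHEME_CODE = {"CV1": 1, "CV2": 2}


@dataclass
class CVPartition:
    scheme: str
    replicate: int
    fold: int
    masked_cells: frozenset  # of (line, environment)
    seed_used: int


@dataclass
class CVResult:
    """Long table of per-run, per-environment prediction abilities.

    ``rows`` has columns (scheme, model_id, trait, environment, replicate,
    fold, pearson_r, n_pairs); ``pearson_r`` is NaN where the correlation
    was undefined. ``failures`` lists (scheme, model, replicate, fold,
    message) for fits that errored; the grid continues past them.
    """

    rows: pd.DataFrame
    failures: list = field(default_factory=list)

    @property
    def n_undefined(self) -> int:
        return int(self.rows["pearson_r"].isna().sum())

    def per_env_summary(self) -> pd.DataFrame:
        """Mean ± SD of prediction ability over runs, per environment."""
        g = self.rows.groupby(
            ["scheme", "model_id", "trait", "environment"], sort=False
        )["pearson_r"]
        out = g.agg(mean_r="mean", sd_r="std", n_runs="count").reset_index()
        out["n_excluded"] = (
            g.apply(lambda s: int(s.isna().sum())).to_numpy()
        )
        return out

    def grand_means(self) -> pd.DataFrame:
        """Average of the per-environment means, per scheme/model/trait."""
        env_means = self.per_env_summary()
        return (
            env_means.groupby(["scheme", "model_id", "trait"], sort=False)[
                "mean_r"
            ]
            .mean()
            .reset_index()
            .rename(columns={"mean_r": "grand_mean_r"})
        )


def _rng_for(seed: int, scheme: str, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), _SCHEME_CODE[scheme], int(replicate)]
        )
    )


def make_cv1(
    lines, observed_cells, k: int = 5, replicates: int = 20, seed: int = 0
) -> list[CVPartition]:
    """Fold partitions that mask whole lines (lines untested anywhere).

    Per replicate a seeded permutation of the lines is split into ``k``
    near-equal folds (sizes differ by at most one); a fold's partition masks
    every observed cell of its lines.
    """
    lines = [str(x) for x in lines]
    if k > len(lines):
        raise ConfigError(f"k={k} exceeds the {len(lines)} available lines")
    cells_by_line: dict[str, list] = {}
    for l, e in observed_cells:
        cells_by_line.setdefault(str(l), []).append((str(l), str(e)))
    parts = []
    for rep in range(1, replicates + 1):
        rng = _rng_for(seed, "CV1", rep)
        perm = [lines[i] for i in rng.permutation(len(lines))]
        for fold, chunk in enumerate(np.array_split(perm, k), start=1):
            masked = frozenset(
                cell for line in chunk for cell in cells_by_line.get(line, [])
            )
            parts.append(CVPartition("CV1", rep, fold, masked, seed))
    return parts


def make_cv2(
    observed_cells,
    k: int = 5,
    replicates: int = 20,
    seed: int = 0,
    allocation: str = "stratified",
) -> list[CVPartition]:
    """Fold partitions that mask individual cells (lines untested in some
    environments).

    ``stratified`` (default) deals each line's observed cells round-robin
    across the folds in a seeded random environment order; the starting fold
    rotates over a seeded random line order, which balances fold sizes while
    every multi-environment line keeps at least one training cell in every
    fold. ``random`` assigns maskable cells to folds uniformly. Lines
    observed in a single environment are never masked.
    """
    if allocation not in ("stratified", "random"):
        raise ConfigError(f"unknown CV2 allocation {allocation!r}")
    cells_by_line: dict[str, list] = {}
    for l, e in observed_cells:
        cells_by_line.setdefault(str(l), []).append((str(l), str(e)))
    maskable_lines = [l for l, cs in cells_by_line.items() if len(cs) >= 2]
    if not maskable_lines:
        raise DataError(
            "CV2 has no maskable cells: no line is observed in >= 2 "
            "environments"
        )
    parts = []
    for rep in range(1, replicates + 1):
        rng = _rng_for(seed, "CV2", rep)
        folds: list[set] = [set() for _ in range(k)]
        if allocation == "stratified":
            line_order = rng.permutation(len(maskable_lines))
            for pos, li in enumerate(line_order):
                cs = cells_by_line[maskable_lines[li]]
                order = rng.permutation(len(cs))
                start = pos % k
                for i, ci in enumerate(order):
                    folds[(start + i) % k].add(cs[ci])
        else:
            pool = [c for l in maskable_lines for c in cells_by_line[l]]
            order = rng.permutation(len(pool))
            for i, ci in enumerate(order):
                folds[i % k].add(pool[ci])
        for fold, masked in enumerate(folds, start=1):
            parts.append(CVPartition("CV2", rep, fold, frozenset(masked), seed))
    return parts


def prediction_ability(
    observed: LineEnvTable,
    predicted: LineEnvTable,
    environment: str,
) -> float:
    """Pearson correlation between observed and predicted values of one
    environment, paired by line. NaN when either vector has zero variance
    (recorded as missing, never coerced to 0)."""
    env = str(environment)
    obs = observed.frame.query("environment == @env")
    pre = predicted.frame.query("environment == @env")
    merged = obs.merge(
        pre, on=["trait", "environment", "line"], suffixes=("_obs", "_pred")
    )
    if len(merged) < 3:
        raise DataError(
            f"need >= 3 paired values in environment {env!r}, "
            f"got {len(merged)}"
        )
    a = merged["value_obs"].to_numpy(dtype=float)
    b = merged["value_pred"].to_numpy(dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_grid(
    blues: LineEnvTable,
    kernels: dict[str, RelationshipKernel],
    models,
    schemes,
    sampler_config: SamplerConfig | None = None,
    k: int = 5,
    replicates: int = 20,
    seed: int = 0,
    cv2_allocation: str = "stratified",
) -> CVResult:
    """Fit every (scheme, model, partition) combination and score it.

    Partitions are generated once per (scheme, trait) from seeds derived
    only from (master seed, scheme, replicate), so adding or removing models
    never perturbs them; sampler seeds additionally mix in the model and
    fold so chains are independent. A failed fit is recorded and the grid
    continues.
    """
    models = list(models)
    schemes = list(schemes)
    for m in models:
        if m not in MODEL_TERMS:
            raise ConfigError(f"unknown model {m!r}")
    for s in schemes:
        if s not in _SCHEME_CODE:
            raise ConfigError(f"unknown scheme {s!r}")
    config = sampler_config or SamplerConfig()

    rows = []
    failures = []
    frame = blues.frame
    for trait in frame["trait"].unique():
        tdf = frame[frame["trait"] == trait]
        observed = list(zip(tdf["line"], tdf["environment"]))
        cell_map = IncidenceMap.from_cells(observed)
        trait_blues = LineEnvTable(tdf)
        defs = {m: build_model(m, kernels, cell_map) for m in models}
        for scheme in schemes:
            if scheme == "CV1":
                parts = make_cv1(
                    cell_map.lines, observed, k=k, replicates=replicates,
                    seed=seed,
                )
            else:
                parts = make_cv2(
                    observed, k=k, replicates=replicates, seed=seed,
                    allocation=cv2_allocation,
                )
            keys = list(zip(tdf["line"], tdf["environment"]))
            for model_id in models:
                for part in parts:
                    # seed depends on the model's identity, not its position,
                    # so results per model are stable across model lists
                    fit_seed = int(
                        np.random.SeedSequence(
                            [
                                int(seed),
                                _SCHEME_CODE[scheme],
                                int(model_id[1:]),
                                part.replicate,
                                part.fold,
                            ]
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    run_cfg = replace(config, seed=fit_seed)
                    masked = part.masked_cells
                    in_mask = np.fromiter(
                        (key in masked for key in keys), bool, len(keys)
                    )
                    train = LineEnvTable(tdf[~in_mask])
                    test = LineEnvTable(tdf[in_mask])
                    try:
                        fit = fit_gibbs(train, defs[model_id], run_cfg)
                        preds = predict_cells(fit, sorted(masked))
                    except Exception as exc:  # noqa: BLE001
                        failures.append(
                            (
                                scheme,
                                model_id,
                                part.replicate,
                                part.fold,
                                f"{type(exc).__name__}: {exc}",
                            )
                        )
                        continue
                    for env in sorted({e for _, e in masked}):
                        n_pairs = sum(1 for _, e in masked if e == env)
                        if n_pairs < 3:
                            continue
                        r = prediction_ability(test, preds, env)
                        rows.append(
                            (
                                scheme,
                                model_id,
                                trait,
                                env,
                                part.replicate,
                                part.fold,
                                r,
                                n_pairs,
                            )
                        )
    frame_out = pd.DataFrame(
        rows,
        columns=[
            "scheme",
            "model_id",
            "trait",
            "environment",
            "replicate",
            "fold",
            "pearson_r",
            "n_pairs",
        ],
    )
    return CVResult(rows=frame_out, failures=failures)


def tukey_compare(
    result: CVResult,
    scheme: str,
    trait: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Tukey HSD on model means with environment as blocking factor.

    Uses the per-environment mean correlations as responses in a two-way
    ANOVA without interaction (model + environment), then compares model
    means with the studentized range at ``alpha``. Returns the model means,
    the HSD threshold, and a compact letter display (models sharing a
    letter are not significantly different).
    """
    summary = result.per_env_summary()
    sub = summary[summary["scheme"] == str(scheme)]
    if trait is not None:
        sub = sub[sub["trait"] == str(trait)]
    table = sub.pivot_table(
        index="environment", columns="model_id", values="mean_r"
    ).dropna()
    n_env, n_mod = table.shape
    if n_mod < 2:
        raise DataError("tukey_compare needs >= 2 models")
    if n_env < 2:
        raise DataError("tukey_compare needs >= 2 environments")

    y = table.to_numpy()
    model_means = y.mean(axis=0)
    env_means = y.mean(axis=1)
    grand = y.mean()
    resid = y - env_means[:, None] - model_means[None, :] + grand
    df_err = (n_env - 1) * (n_mod - 1)
    mse = float((resid**2).sum() / df_err)

    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, n_mod, df_err))
    hsd = q_crit * np.sqrt(mse / n_env)

    order = np.argsort(-model_means)
    models_sorted = [table.columns[i] for i in order]
    means_sorted = model_means[order]
    # models within HSD of each other form contiguous intervals on the
    # sorted means; maximal intervals become the letters
    intervals = []
    for i in range(n_mod):
        j = i
        while j + 1 < n_mod and means_sorted[i] - means_sorted[j + 1] <= hsd:
            j += 1
        intervals.append((i, j))
    maximal = [
        iv
        for iv in dict.fromkeys(intervals)
        if not any(
            o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals
        )
    ]
    maximal.sort()
    letters = {m: "" for m in models_sorted}
    for letter_i, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + letter_i)
        for m in models_sorted[lo: hi + 1]:
            letters[m] += ch

    return {
        "scheme": str(scheme),
        "alpha": float(alpha),
        "model_means": {
            m: float(v) for m, v in zip(models_sorted, means_sorted)
        },
        "hsd": float(hsd),
        "mse": mse,
        "df_error": int(df_err),
        "letters": letters,
    }
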