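"""Per-environment trial adjustment.

Fits the design model

    y_jkm = mu + L_j + r_k + b_m(k) + e_jkm

within one environment, with fixed line effects L_j and independent random
replicate and block-within-replicate effects, by EM-REML on Henderson's
mixed-model equations. Line BLUEs come from the fixed-line fit; a second fit
with lines random supplies the line variance used for broad-sense
heritability on an entry-mean basis:

    within one environment   H² = σg² / (σg² + σe²/r)
    across s environments    H² = σg² / (σg² + σge²/s + σe²/(r·s))

EM iterations stop when the relative change of every component falls below
1e-8 (at most 500 iterations); non-positive steps are floored at 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DataError, NumericalError
from .io import LineEnvTable, PlotRecordTable

__all__ = [
    "TrialFit",
    "HeritabilityEstimate",
    "fit_trial",
    "heritability_within",
    "heritability_across",
    "adjust_all",
]

_EM_MAX_ITER = 500
_EM_TOL = 1e-8
_EM_FLOOR = 1e-10


@dataclass
class TrialFit:
    trait: str
    environment: str
    blues: dict[str, float]
    var_rep: float
    var_block: float
    var_error: float
    var_line_random: float
    n_reps_effective: float

    def heritability(self) -> "HeritabilityEstimate":
        return heritability_within(
            self.var_line_random, self.var_error, self.n_reps_effective
        )


@dataclass
class HeritabilityEstimate:
    scope: str  # "within-env" | "across-env"
    h2: float
    components: dict[str, float]


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(labels))
    idx = {v: i for i, v in enumerate(levels)}
    z = np.zeros((len(labels), len(levels)))
    z[np.arange(len(labels)), [idx[v] for v in labels]] = 1.0
    return z, levels


def _em_reml(y, X, Z_list, start=None):
    """EM-REML for y = X b + Σ Z_i u_i + e with iid random factors.

    Returns (b, [u_i], [σ_i²], σe²). The coefficient matrix uses the
    variance-ratio (λ) form, so prediction error variances are σe²·C⁻¹.
    """
    n = y.size
    p = X.shape[1]
    rank_x = np.linalg.matrix_rank(X)
    if n - rank_x <= 0:
        raise DataError("no residual degrees of freedom for REML")
    q = [Z.shape[1] for Z in Z_list]
    W = np.hstack([X] + list(Z_list)) if Z_list else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    var_y = float(np.var(y)) or 1.0
    k = len(Z_list)
    sig = list(start) if start is not None else [var_y / (k + 1)] * k
    sig = [max(s, _EM_FLOOR) for s in sig]
    sig_e = max(var_y / (k + 1) if start is None else var_y / 2, _EM_FLOOR)

    offs = np.cumsum([p] + q)
    for _ in range(_EM_MAX_ITER):
        C = WtW.copy()
        for i in range(k):
            lam = min(sig_e / max(sig[i], _EM_FLOOR), 1e12)
            sl = slice(offs[i], offs[i + 1])
            C[sl, sl] += lam * np.eye(q[i])
        try:
            Cinv = scipy.linalg.inv(C)
        except scipy.linalg.LinAlgError as e:
            raise NumericalError(
                f"mixed-model equations singular "
                f"(condition ~ {np.linalg.cond(C):.2e})"
            ) from e
        sol = Cinv @ Wty
        new_sig = []
        for i in range(k):
            sl = slice(offs[i], offs[i + 1])
            u = sol[sl]
            tr = float(np.trace(Cinv[sl, sl]))
            new_sig.append(max((float(u @ u) + sig_e * tr) / q[i], _EM_FLOOR))
        new_sig_e = max((yty - float(sol @ Wty)) / (n - rank_x), _EM_FLOOR)
        rel = [
            abs(a - b) / max(b, _EM_FLOOR)
            for a, b in zip(new_sig + [new_sig_e], sig + [sig_e])
        ]
        sig, sig_e = new_sig, new_sig_e
        if max(rel, default=0.0) < _EM_TOL:
            break
    b = sol[:p]
    u_list = [sol[offs[i]: offs[i + 1]] for i in range(k)]
    return b, u_list, sig, sig_e


def fit_trial(
    records: PlotRecordTable, trait: str, environment: str
) -> TrialFit:
    """Adjust one trial: line BLUEs, design variances, and the random-line
    variance needed for heritability.

    Environments with a single replicate keep the block term but fix the
    replicate variance at zero so the model stays identifiable; blocks are
    dropped when every replicate holds a single block (fully confounded).
    """
    df = records.frame
    sub = df[(df["trait"] == str(trait)) & (df["environment"] == str(environment))]
    if sub.empty:
        raise DataError(f"no records for trait={trait!r}, env={environment!r}")
    if sub["line"].nunique() < 2:
        raise DataError("fit_trial needs at least 2 distinct lines")

    y = sub["value"].to_numpy(dtype=float)
    X, lines = _indicator(sub["line"])

    reps = sub["replicate"]
    rep_block = reps.str.cat(sub["block"], sep="//")
    n_reps = reps.nunique()
    use_rep = n_reps >= 2
    blocks_per_rep = rep_block.groupby(reps.values).nunique()
    use_block = rep_block.nunique() > n_reps and (blocks_per_rep > 1).any()

    Z_list, names = [], []
    if use_rep:
        Z_list.append(_indicator(reps)[0])
        names.append("rep")
    if use_block:
        Z_list.append(_indicator(rep_block)[0])
        names.append("block")

    # random-line refit for the heritability numerator (always has residual
    # degrees of freedom: only the intercept is fixed)
    X0 = np.ones((y.size, 1))
    Zl = _indicator(sub["line"])[0]
    _, _, sig_r, sig_e_r = _em_reml(y, X0, [Zl] + Z_list)
    var_line_random = sig_r[0]

    if y.size - sub["line"].nunique() >= 1:
        b, _, sig, sig_e = _em_reml(y, X, Z_list)
        blues = {line: float(v) for line, v in zip(lines, b)}
        comp = dict(zip(names, sig))
    else:
        # single plot per line: fixed-line effects exhaust the data, so the
        # BLUEs are the observed values and the design variances come from
        # the random-line fit
        blues = dict(sub.groupby("line")["value"].mean())
        comp = {}
        sig_e = sig_e_r

    counts = sub.groupby("line").size().to_numpy(dtype=float)
    r_eff = counts.size / float(np.sum(1.0 / counts))

    return TrialFit(
        trait=str(trait),
        environment=str(environment),
        blues=blues,
        var_rep=float(comp.get("rep", 0.0)),
        var_block=float(comp.get("block", 0.0)),
        var_error=float(sig_e),
        var_line_random=float(var_line_random),
        n_reps_effective=float(r_eff),
    )


def heritability_within(
    var_line: float, var_error: float, n_reps: float
) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability within one environment."""
    if var_line < 0 or var_error < 0 or n_reps < 1:
        raise DataError("variances must be >= 0 and n_reps >= 1")
    denom = var_line + var_error / n_reps
    if denom == 0:
        raise NumericalError("heritability undefined: all variances zero")
    return HeritabilityEstimate(
        scope="within-env",
        h2=float(var_line / denom),
        components={
            "var_line": float(var_line),
            "var_error": float(var_error),
            "n_reps": float(n_reps),
        },
    )


def heritability_across(
    var_line: float,
    var_gxe: float,
    var_error: float,
    n_reps: float,
    n_envs: float,
) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability across environments."""
    if min(var_line, var_gxe, var_error) < 0 or n_reps < 1 or n_envs < 1:
        raise DataError("variances must be >= 0, n_reps and n_envs >= 1")
    denom = var_line + var_gxe / n_envs + var_error / (n_reps * n_envs)
    if denom == 0:
        raise NumericalError("heritability undefined: zero denominator")
    return HeritabilityEstimate(
        scope="across-env",
        h2=float(var_line / denom),
        components={
            "var_line": float(var_line),
            "var_gxe": float(var_gxe),
            "var_error": float(var_error),
            "n_reps": float(n_reps),
            "n_envs": float(n_envs),
        },
    )


def adjust_all(
    records: PlotRecordTable,
) -> tuple[LineEnvTable, pd.DataFrame]:
    """Fit every (trait, environment) trial.

    Returns the BLUE table that downstream models consume plus a summary
    frame of design variance components and within-environment heritability.
    """
    df = records.frame
    blue_rows, summary_rows = [], []
    for (trait, env), _ in df.groupby(["trait", "environment"], sort=False):
        fit = fit_trial(records, trait, env)
        for line, value in fit.blues.items():
            blue_rows.append((trait, env, line, value))
        h2 = fit.heritability()
        summary_rows.append(
            {
                "trait": trait,
                "environment": env,
                "var_rep": fit.var_rep,
                "var_block": fit.var_block,
                "var_error": fit.var_error,
                "var_line_random": fit.var_line_random,
                "n_reps_effective": fit.n_reps_effective,
                "h2_within": h2.h2,
            }
        )
    blues = LineEnvTable(
        pd.DataFrame(
            blue_rows, columns=["trait", "environment", "line", "value"]
        )
    )
    return blues, pd.DataFrame(summary_rows)
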