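"""Reaction-norm models M1-M7 and their fitting machinery.

Each model is a sum of kernel-structured random effects over (line,
environment) cells:

    M1: y = mu + E + L + e                M5: y = mu + E + L + G + GE + e
    M2: y = mu + E + L + A + e            M6: y = mu + E + L + A + G + e
    M3: y = mu + E + L + G + e            M7: y = mu + E + L + A + G + AE + GE + e
    M4: y = mu + E + L + A + AE + e

E and L are iid factor effects (identity kernels over environment and line
labels), A and G are main-effect expansions Z K Z' of the pedigree and
genomic relationship matrices, and AE/GE carry the interaction covariance
(Z K Z') ∘ (Z_E Z_E'), i.e. kernel relatedness only between cells in the
same environment.

Two fitting routes are provided. :func:`mme_solve` solves Henderson's mixed
model equations exactly at fixed variance components — the BLUP oracle.
:func:`fit_gibbs` is a Gibbs sampler that also samples variance components
from scaled-inverse-chi-square full conditionals; every term's effects are
sampled in an orthogonalized factor basis (B with B'B diagonal and
B B' = K restricted to the training cells), which makes each coordinate's
full conditional independent and the per-iteration cost two matrix-vector
products per term.

Predictions for cells outside the training set use the multivariate-normal
conditional of each term given the training-cell effects. The sampler draws
the masked effects from that full conditional (mean plus noise) per retained
iteration — proper posterior-predictive sampling, so a term carrying no
information about a cell (e.g. the L effect of a line never phenotyped)
contributes prior noise that averages toward zero. The MME solver returns
the noise-free conditional mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigError, DataError, NumericalError
from .io import LineEnvTable
from .kernels import IncidenceMap, RelationshipKernel

__all__ = [
    "MODEL_TERMS",
    "ModelTerm",
    "ModelDefinition",
    "SamplerConfig",
    "FitResult",
    "build_model",
    "mme_solve",
    "fit_gibbs",
    "predict_cells",
]

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("E", "L"),
    "M2": ("E", "L", "A"),
    "M3": ("E", "L", "G"),
    "M4": ("E", "L", "A", "AE"),
    "M5": ("E", "L", "G", "GE"),
    "M6": ("E", "L", "A", "G"),
    "M7": ("E", "L", "A", "G", "AE", "GE"),
}

_EIG_TOL = 1e-10


@dataclass
class ModelTerm:
    """One random effect: a label plus its covariance descriptor.

    ``kind`` is ``env_iid`` / ``line_iid`` for identity-kernel factor
    effects, ``main`` for Z K Z' expansions, ``interaction`` for the
    Hadamard-restricted version. ``kernel`` is the line-level relationship
    kernel for the last two kinds.
    """

    label: str
    kind: str
    kernel: RelationshipKernel | None = None


@dataclass
class ModelDefinition:
    model_id: str
    terms: list[ModelTerm]
    cells: IncidenceMap

    def term_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)


def build_model(
    model_id: str,
    kernels: dict[str, RelationshipKernel],
    cells: IncidenceMap,
) -> ModelDefinition:
    """Assemble one of M1-M7 over the given cells.

    ``kernels`` supplies the line-level ``A`` and/or ``G`` matrices a model
    requires (A for M2/M4/M6/M7, G for M3/M5/M6/M7).
    """
    if model_id not in MODEL_TERMS:
        raise ConfigError(f"unknown model {model_id!r}; expected M1..M7")
    terms = []
    for label in MODEL_TERMS[model_id]:
        if label == "E":
            terms.append(ModelTerm("E", "env_iid"))
        elif label == "L":
            terms.append(ModelTerm("L", "line_iid"))
        else:
            base = label[0]  # A or G
            if base not in kernels or kernels[base] is None:
                raise ConfigError(
                    f"model {model_id} requires the {base} kernel"
                )
            kind = "interaction" if label.endswith("E") and len(label) == 2 else "main"
            terms.append(ModelTerm(label, kind, kernels[base]))
    return ModelDefinition(model_id, terms, cells)


# ---------------------------------------------------------------------------
# term factors
# ---------------------------------------------------------------------------


@dataclass
class _TermFactor:
    """Orthogonalized factor of one term's kernel on the training cells.

    ``B`` satisfies B B' = K_train and B'B = diag(s2); the sampled
    coordinates ``delta`` relate to the cell effects by u = B delta.
    """

    label: str
    B: np.ndarray  # (n_obs, m)
    s2: np.ndarray  # (m,)
    mean_diag: float
    term: ModelTerm
    obs_lines: list[str]
    obs_envs: list[str]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    # -- cross-covariance machinery for prediction --------------------------

    def _k_cross(self, lines_a, envs_a, lines_b, envs_b) -> np.ndarray:
        t = self.term
        if t.kind == "env_iid":
            ea = np.asarray(envs_a, dtype=object)
            eb = np.asarray(envs_b, dtype=object)
            return (ea[:, None] == eb[None, :]).astype(float)
        if t.kind == "line_iid":
            la = np.asarray(lines_a, dtype=object)
            lb = np.asarray(lines_b, dtype=object)
            return (la[:, None] == lb[None, :]).astype(float)
        ia = t.kernel.index_of(lines_a)
        ib = t.kernel.index_of(lines_b)
        k = t.kernel.matrix[np.ix_(ia, ib)]
        if t.kind == "interaction":
            ea = np.asarray(envs_a, dtype=object)
            eb = np.asarray(envs_b, dtype=object)
            k = np.where(ea[:, None] == eb[None, :], k, 0.0)
        return k

    def predict_operator(self, lines, envs) -> tuple[np.ndarray, np.ndarray]:
        """(M, C): conditional mean of new-cell effects is M @ delta and the
        conditional covariance is C (up to the term's variance)."""
        k_mo = self._k_cross(lines, envs, self.obs_lines, self.obs_envs)
        M = k_mo @ (self.B / self.s2)  # = K_mo P S^{-1}, so M M' = K_mo K_oo^+ K_om
        k_mm = self._k_cross(lines, envs, lines, envs)
        C = k_mm - M @ M.T
        C = (C + C.T) / 2.0
        return M, C


def _factor_identity(levels: list, n_obs: int) -> tuple[np.ndarray, np.ndarray]:
    uniq = list(dict.fromkeys(levels))
    idx = {v: i for i, v in enumerate(uniq)}
    B = np.zeros((n_obs, len(uniq)))
    B[np.arange(n_obs), [idx[v] for v in levels]] = 1.0
    return B, B.sum(axis=0)


def _factor_main(K: RelationshipKernel, lines: list[str], n_obs: int):
    w, v = np.linalg.eigh(K.matrix)
    keep = w > _EIG_TOL
    rows = K.index_of(lines)
    W = (v[:, keep] * np.sqrt(w[keep]))[rows]  # (n_obs, r)
    P, s, _ = np.linalg.svd(W, full_matrices=False)
    ok = s**2 > _EIG_TOL
    return P[:, ok] * s[ok], s[ok] ** 2


def _factor_interaction(K: RelationshipKernel, lines, envs, n_obs: int):
    envs_arr = np.asarray(envs, dtype=object)
    blocks_B, blocks_s2, col_rows = [], [], []
    for env in dict.fromkeys(envs):
        rows = np.where(envs_arr == env)[0]
        idx = K.index_of([lines[r] for r in rows])
        ke = K.matrix[np.ix_(idx, idx)]
        w, v = np.linalg.eigh((ke + ke.T) / 2.0)
        keep = w > _EIG_TOL
        blocks_B.append(v[:, keep] * np.sqrt(w[keep]))
        blocks_s2.append(w[keep])
        col_rows.append(rows)
    m = sum(b.shape[1] for b in blocks_B)
    B = np.zeros((n_obs, m))
    s2 = np.concatenate(blocks_s2) if m else np.zeros(0)
    off = 0
    for rows, b in zip(col_rows, blocks_B):
        B[np.ix_(rows, np.arange(off, off + b.shape[1]))] = b
        off += b.shape[1]
    return B, s2


def _build_factors(model: ModelDefinition, obs: IncidenceMap) -> list[_TermFactor]:
    lines = [l for l, _ in obs.cells]
    envs = [e for _, e in obs.cells]
    n = obs.n_cells
    out = []
    for term in model.terms:
        if term.kind == "env_iid":
            B, s2 = _factor_identity(envs, n)
        elif term.kind == "line_iid":
            B, s2 = _factor_identity(lines, n)
        elif term.kind == "main":
            B, s2 = _factor_main(term.kernel, lines, n)
        elif term.kind == "interaction":
            B, s2 = _factor_interaction(term.kernel, lines, envs, n)
        else:  # pragma: no cover
            raise ConfigError(f"unknown term kind {term.kind!r}")
        if B.shape[1] == 0:
            raise NumericalError(
                f"term {term.label}: kernel has no positive eigenvalues on "
                f"the training cells"
            )
        mean_diag = float(np.sum(s2) / n)
        out.append(_TermFactor(term.label, B, s2, mean_diag, term, lines, envs))
    return out


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass
class SamplerConfig:
    """Gibbs sampler settings.

    ``prior_r2_partition`` assigns shares of the response variance to each
    term's prior scale; by default the residual takes 0.5 and the terms
    split the rest equally. ``fixed_variances`` (term label -> value, plus
    ``"e"``) freezes components instead of sampling them, which turns the
    sampler into a Monte-Carlo BLUP evaluator. ``predictive_draws`` controls
    whether out-of-sample effects are drawn from their full conditional
    (default) or set to the conditional mean.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    prior_df: float = 5.0
    prior_r2_partition: dict[str, float] | None = None
    seed: int = 0
    standardize_response: bool = True
    fixed_variances: dict[str, float] | None = None
    predictive_draws: bool = True

    def validate(self, labels: tuple[str, ...]) -> "SamplerConfig":
        if not 0 <= self.burn_in < self.n_iter:
            raise ConfigError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.prior_df <= 0:
            raise ConfigError("prior_df must be > 0")
        if self.prior_r2_partition is not None:
            shares = dict(self.prior_r2_partition)
            missing = set(labels) - set(shares)
            if missing:
                raise ConfigError(f"prior_r2_partition missing terms {missing}")
            total = sum(shares[l] for l in labels)
            if not 0 < total < 1:
                raise ConfigError(
                    "term prior shares must leave a residual share in (0,1)"
                )
        if self.fixed_variances is not None:
            need = set(labels) | {"e"}
            missing = need - set(self.fixed_variances)
            if missing:
                raise ConfigError(f"fixed_variances missing {missing}")
        return self

    def r2_shares(self, labels: tuple[str, ...]) -> tuple[dict[str, float], float]:
        if self.prior_r2_partition is None:
            share = 0.5 / len(labels)
            return {l: share for l in labels}, 0.5
        shares = {l: float(self.prior_r2_partition[l]) for l in labels}
        return shares, 1.0 - sum(shares.values())


@dataclass
class FitResult:
    """Posterior (or BLUP) summary of one model fit.

    ``var_components`` maps term label (and ``"e"``) to posterior mean and
    SD on the fitting scale; ``cell_effects`` holds each term's posterior
    mean effect on the training cells; ``yhat`` the fitted value per
    training cell. Prediction state (factors, retained samples, response
    standardization) is kept privately so :func:`predict_cells` can score
    arbitrary cells afterwards.
    """

    model_id: str
    trait: str
    mu_hat: float
    var_components: dict[str, dict[str, float]]
    cell_effects: dict[str, np.ndarray]
    yhat: LineEnvTable
    diagnostics: dict
    _factors: list[_TermFactor] = field(repr=False, default=None)
    _obs: IncidenceMap = field(repr=False, default=None)
    _mu_samples: np.ndarray = field(repr=False, default=None)
    _delta_samples: list[np.ndarray] = field(repr=False, default=None)
    _env_stats: dict[str, tuple[float, float]] = field(repr=False, default=None)
    _sig_samples: np.ndarray = field(repr=False, default=None)  # (S, T+1)
    _predictive_draws: bool = field(repr=False, default=False)
    _pred_seed: int = field(repr=False, default=0)


def _align_response(
    y: LineEnvTable, model: ModelDefinition, trait: str | None
) -> tuple[IncidenceMap, np.ndarray, str]:
    df = y.frame
    traits = df["trait"].unique()
    if trait is None:
        if len(traits) != 1:
            raise DataError(
                f"response holds traits {list(traits)}; pass trait explicitly"
            )
        trait = traits[0]
    df = df[df["trait"] == str(trait)]
    if len(df) < 2:
        raise DataError("need at least 2 observed cells")
    values = {
        (l, e): v
        for l, e, v in zip(df["line"], df["environment"], df["value"])
    }
    known = set(model.cells.cells)
    for cell in values:
        if cell not in known:
            raise DataError(
                f"observed cell {cell!r} is not part of the model's cell map"
            )
    mask = np.array([c in values for c in model.cells.cells])
    obs = model.cells.subset(mask)
    yv = np.array([values[c] for c in obs.cells], dtype=float)
    if not np.isfinite(yv).all():
        raise DataError("response contains non-finite values")
    return obs, yv, str(trait)


def _standardize(obs: IncidenceMap, yv: np.ndarray, enabled: bool):
    stats: dict[str, tuple[float, float]] = {}
    ys = yv.copy()
    envs = np.asarray([e for _, e in obs.cells], dtype=object)
    for env in dict.fromkeys(envs):
        rows = envs == env
        if enabled:
            mu = float(yv[rows].mean())
            sd = float(yv[rows].std())
            sd = sd if sd > 0 else 1.0
        else:
            mu, sd = 0.0, 1.0
        stats[env] = (mu, sd)
        ys[rows] = (yv[rows] - mu) / sd
    return ys, stats


def _fitted_table(obs, fitted, stats, trait) -> LineEnvTable:
    rows = []
    for (line, env), v in zip(obs.cells, fitted):
        mu, sd = stats[env]
        rows.append((trait, env, line, v * sd + mu))
    return LineEnvTable(
        pd.DataFrame(rows, columns=["trait", "environment", "line", "value"])
    )


# ---------------------------------------------------------------------------
# exact solver
# ---------------------------------------------------------------------------


def mme_solve(
    y: LineEnvTable,
    model: ModelDefinition,
    variances: dict[str, float],
    var_e: float,
    trait: str | None = None,
) -> FitResult:
    """Joint BLUP of the intercept and all random effects at fixed variances.

    ``variances`` maps each term label to its σ²; ``var_e`` is the residual
    variance. Out-of-sample predictions from the result use the exact
    conditional mean. The response is used on its original scale.
    """
    labels = model.term_labels()
    missing = set(labels) - set(variances)
    if missing:
        raise ConfigError(f"variances missing for terms {missing}")
    for label in labels:
        if variances[label] <= 0:
            raise ConfigError(f"variance for {label} must be > 0")
    if var_e <= 0:
        raise ConfigError("var_e must be > 0")

    obs, yv, trait = _align_response(y, model, trait)
    factors = _build_factors(model, obs)
    n = yv.size

    Wd = np.hstack([np.ones((n, 1))] + [f.B for f in factors])
    C = Wd.T @ Wd
    off = 1
    for f in factors:
        lam = var_e / variances[f.label]
        sl = slice(off, off + f.m)
        C[sl, sl] += lam * np.eye(f.m)
        off += f.m
    rhs = Wd.T @ yv
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as e:
        raise NumericalError(
            f"mixed-model equations singular: rank {np.linalg.matrix_rank(C)}"
            f" of {C.shape[0]}"
        ) from e
    if not np.isfinite(sol).all():
        raise NumericalError("mixed-model solve produced non-finite values")

    mu_hat = float(sol[0])
    deltas, effects = [], {}
    off = 1
    fitted = np.full(n, mu_hat)
    for f in factors:
        d = sol[off: off + f.m]
        deltas.append(d)
        u = f.B @ d
        effects[f.label] = u
        fitted += u
        off += f.m

    stats = {e: (0.0, 1.0) for e in dict.fromkeys(e for _, e in obs.cells)}
    var_comp = {
        label: {"mean": float(variances[label]), "sd": 0.0} for label in labels
    }
    var_comp["e"] = {"mean": float(var_e), "sd": 0.0}
    return FitResult(
        model_id=model.model_id,
        trait=trait,
        mu_hat=mu_hat,
        var_components=var_comp,
        cell_effects=effects,
        yhat=_fitted_table(obs, fitted, stats, trait),
        diagnostics={"method": "mme", "n_obs": n},
        _factors=factors,
        _obs=obs,
        _mu_samples=np.array([mu_hat]),
        _delta_samples=[d[None, :] for d in deltas],
        _env_stats=stats,
        _sig_samples=np.array(
            [[variances[label] for label in labels] + [var_e]]
        ),
        _predictive_draws=False,
        _pred_seed=0,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def fit_gibbs(
    y: LineEnvTable,
    model: ModelDefinition,
    config: SamplerConfig,
    trait: str | None = None,
) -> FitResult:
    """Bayesian fit of one reaction-norm model.

    Effects are sampled coordinate-wise in each term's orthogonalized kernel
    basis; variance components from scaled-inverse-chi-square full
    conditionals with ``prior_df`` degrees of freedom and scales set from
    ``prior_r2_partition`` of the (possibly per-environment standardized)
    response variance. Returns posterior means over the retained samples.
    """
    labels = model.term_labels()
    config.validate(labels)
    obs, yv, trait = _align_response(y, model, trait)
    ys, stats = _standardize(obs, yv, config.standardize_response)
    factors = _build_factors(model, obs)
    n = ys.size
    rng = np.random.default_rng(np.random.SeedSequence(int(config.seed)))

    df0 = float(config.prior_df)
    var_y = float(np.var(ys)) or 1.0
    shares, resid_share = config.r2_shares(labels)
    fixed = config.fixed_variances
    s0 = {
        f.label: shares[f.label] * var_y * (df0 + 2.0) / (df0 * f.mean_diag)
        for f in factors
    }
    s0_e = resid_share * var_y * (df0 + 2.0) / df0

    if fixed is not None:
        sig = {lab: float(fixed[lab]) for lab in labels}
        sig_e = float(fixed["e"])
    else:
        sig = {f.label: shares[f.label] * var_y for f in factors}
        sig_e = resid_share * var_y

    deltas = [np.zeros(f.m) for f in factors]
    u = [np.zeros(n) for _ in factors]
    mu = float(ys.mean())
    resid = ys - mu

    n_keep = (config.n_iter - config.burn_in) // config.thin
    keep_mu = np.empty(n_keep)
    keep_delta = [np.empty((n_keep, f.m)) for f in factors]
    keep_sig = np.empty((n_keep, len(factors) + 1))
    kept = 0

    for it in range(config.n_iter):
        # intercept
        resid += mu
        mu = float(resid.mean() + rng.normal() * np.sqrt(sig_e / n))
        resid -= mu
        # term effects, coordinate-wise in the orthogonal basis
        for t, f in enumerate(factors):
            st = sig[f.label]
            btr = f.B.T @ resid + f.s2 * deltas[t]
            prec = f.s2 / sig_e + 1.0 / st
            mean = (btr / sig_e) / prec
            new_d = mean + rng.standard_normal(f.m) / np.sqrt(prec)
            new_u = f.B @ new_d
            resid += u[t] - new_u
            deltas[t] = new_d
            u[t] = new_u
        # variances
        if fixed is None:
            for t, f in enumerate(factors):
                ss = float(deltas[t] @ deltas[t])
                dfp = df0 + f.m
                sig[f.label] = (df0 * s0[f.label] + ss) / rng.chisquare(dfp)
            sse = float(resid @ resid)
            sig_e = (df0 * s0_e + sse) / rng.chisquare(df0 + n)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if kept < n_keep:
                keep_mu[kept] = mu
                for t in range(len(factors)):
                    keep_delta[t][kept] = deltas[t]
                keep_sig[kept] = [sig[f.label] for f in factors] + [sig_e]
                kept += 1

    keep_mu = keep_mu[:kept]
    keep_delta = [kd[:kept] for kd in keep_delta]
    keep_sig = keep_sig[:kept]

    mu_hat = float(keep_mu.mean())
    var_comp = {}
    for t, f in enumerate(factors):
        var_comp[f.label] = {
            "mean": float(keep_sig[:, t].mean()),
            "sd": float(keep_sig[:, t].std()),
        }
    var_comp["e"] = {
        "mean": float(keep_sig[:, -1].mean()),
        "sd": float(keep_sig[:, -1].std()),
    }
    effects = {
        f.label: f.B @ keep_delta[t].mean(axis=0)
        for t, f in enumerate(factors)
    }
    fitted = mu_hat + np.sum(list(effects.values()), axis=0)
    pred_seed = int(
        np.random.SeedSequence([int(config.seed), 777]).generate_state(1)[0]
        % (2**31)
    )
    return FitResult(
        model_id=model.model_id,
        trait=trait,
        mu_hat=mu_hat,
        var_components=var_comp,
        cell_effects=effects,
        yhat=_fitted_table(obs, fitted, stats, trait),
        diagnostics={
            "method": "gibbs",
            "n_obs": n,
            "n_samples": kept,
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "seed": int(config.seed),
        },
        _factors=factors,
        _obs=obs,
        _mu_samples=keep_mu,
        _delta_samples=keep_delta,
        _env_stats=stats,
        _sig_samples=keep_sig,
        _predictive_draws=bool(config.predictive_draws),
        _pred_seed=pred_seed,
    )


def predict_cells(fit: FitResult, cells_to_predict) -> LineEnvTable:
    """Predict (line, environment) cells from a fitted model.

    Environments must have been observed during fitting (new environments
    are outside both CV schemes); lines may be entirely new, in which case
    their iid line effect is uninformed and their A/G contributions come
    from kernel relatedness to the training lines. Predictions are returned
    on the original response scale.
    """
    cells = [(str(l), str(e)) for l, e in cells_to_predict]
    if not cells:
        raise DataError("no cells to predict")
    trained_envs = set(e for _, e in fit._obs.cells)
    for line, env in cells:
        if env not in trained_envs:
            raise DataError(
                f"environment {env!r} was not observed during fitting"
            )
    lines = [l for l, _ in cells]
    envs = [e for _, e in cells]
    n_pred = len(cells)
    n_samp = fit._mu_samples.size
    rng = np.random.default_rng(fit._pred_seed)

    total = np.tile(fit._mu_samples[:, None], (1, n_pred))  # (S, n_pred)
    for t, f in enumerate(fit._factors):
        M, C = f.predict_operator(lines, envs)
        contrib = fit._delta_samples[t] @ M.T  # (S, n_pred)
        if fit._predictive_draws and np.max(np.diag(C)) > 1e-12:
            w, v = np.linalg.eigh(C)
            keep = w > 1e-12 * max(float(w[-1]), 1.0)
            if keep.any():
                F = v[:, keep] * np.sqrt(w[keep])
                # conditional noise, scaled by each sample's term variance
                z = rng.standard_normal((n_samp, F.shape[1]))
                sd_t = np.sqrt(fit._sig_samples[:, t])
                contrib = contrib + (z @ F.T) * sd_t[:, None]
        total += contrib
    pred = total.mean(axis=0)

    rows = []
    for (line, env), v in zip(cells, pred):
        mu, sd = fit._env_stats[env]
        rows.append((fit.trait, env, line, v * sd + mu))
    return LineEnvTable(
        pd.DataFrame(rows, columns=["trait", "environment", "line", "value"])
    )
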