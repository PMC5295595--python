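"""Canned validation experiments over the synthetic study conditions.

These functions define the package's standard calibration and benchmark
runs — parameter recovery, sampler-vs-BLUP agreement, cross-validation null
and directional checks — at fixed problem sizes chosen to finish on a single
CPU in minutes. The analysis drivers, the test suite, and the acceptance
script all call the same code so their numbers agree by construction.

Problem sizes (the package's standard study conditions):

* recovery: 300 lines × 10 environments, one plot per cell, fit with M5;
* oracle agreement: 12 lines × 5 environments (60 cells), all of M1-M7;
* CV calibration/direction: 100 lines × 6 environments, five folds.
"""

from __future__ import annotations

import numpy as np

from .evaluate import run_grid
from .io import LineEnvTable
from .kernels import IncidenceMap, RelationshipKernel, pedigree_a, vanraden_g
from .models import MODEL_TERMS, SamplerConfig, build_model, fit_gibbs, mme_solve
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "recovery_config",
    "generative_kernel",
    "cell_table",
    "recovery_experiment",
    "oracle_agreement",
    "cv_null_m1",
    "cv_directional",
]

RECOVERY_TRUTH = {"E": 1.0, "G": 0.6, "GE": 0.4, "e": 1.0}


def recovery_config(seed: int) -> SimulationConfig:
    """σE²=1, σg²=0.6, σEg²=0.4, σe²=1 at 300 lines × 10 environments."""
    return SimulationConfig(
        n_lines=300,
        n_markers=1500,
        n_founders=60,
        n_generations=2,
        n_envs=10,
        n_reps=1,
        blocks_per_rep=1,
        var_env=1.0,
        var_line=0.0,
        var_g=0.6,
        var_a=0.0,
        var_ge=0.4,
        var_ae=0.0,
        var_rep=0.0,
        var_block=0.0,
        var_e=1.0,
        missing_cell_rate=0.0,
        seed=seed,
    )


def generative_kernel(study) -> RelationshipKernel:
    """The genomic kernel the simulator draws from: VanRaden G rescaled to
    unit mean diagonal, so its variance parameter is a per-line variance."""
    g = vanraden_g(study.genotypes)
    g.matrix = g.matrix / float(np.diag(g.matrix).mean())
    return g


def cell_table(study) -> LineEnvTable:
    """Cell-level response table for single-plot-per-cell studies."""
    df = study.plot_records.frame[["trait", "environment", "line", "value"]]
    return LineEnvTable(df)


def recovery_experiment(
    n_seeds: int = 10, base_seed: int = 0, n_iter: int = 2000,
    burn_in: int = 500,
) -> dict:
    """Simulate, fit M5 on the raw scale, and summarize recovered variances.

    Returns per-seed posterior means and the across-seed median relative
    error for each true component.
    """
    per_seed = []
    for i in range(n_seeds):
        seed = int(
            np.random.SeedSequence([int(base_seed), 61, i]).generate_state(1)[0]
            % (2**31)
        )
        study = simulate_study(recovery_config(seed))
        y = cell_table(study)
        g = generative_kernel(study)
        cells = IncidenceMap.from_cells(
            zip(y.frame["line"], y.frame["environment"])
        )
        model = build_model("M5", {"G": g}, cells)
        fit = fit_gibbs(
            y,
            model,
            SamplerConfig(
                n_iter=n_iter,
                burn_in=burn_in,
                thin=5,
                seed=seed,
                standardize_response=False,
            ),
        )
        per_seed.append({k: v["mean"] for k, v in fit.var_components.items()})
    medians = {
        k: float(np.median([e[k] for e in per_seed]))
        for k in per_seed[0]
    }
    rel_err = {
        k: (medians[k] - t) / t for k, t in RECOVERY_TRUTH.items()
    }
    return {"per_seed": per_seed, "medians": medians, "rel_err": rel_err}


def _small_study(seed: int, n_lines=12, n_envs=5, var_ge=0.4):
    cfg = SimulationConfig(
        n_lines=n_lines,
        n_markers=400,
        n_founders=max(4, n_lines // 3),
        n_generations=2,
        n_envs=n_envs,
        n_reps=1,
        blocks_per_rep=1,
        var_env=1.0,
        var_line=0.1,
        var_g=0.6,
        var_a=0.2,
        var_ge=var_ge,
        var_ae=0.0,
        var_rep=0.0,
        var_block=0.0,
        var_e=1.0,
        missing_cell_rate=0.0,
        seed=seed,
    )
    return simulate_study(cfg)


def oracle_agreement(
    seed: int = 0, n_iter: int = 8000, burn_in: int = 1000
) -> dict[str, float]:
    """Gibbs (fixed variances) vs exact BLUP on a 60-cell instance.

    For every model M1-M7, returns the maximum absolute difference between
    the sampler's posterior-mean fitted values and the mixed-model-equation
    solution, in standardized response units.
    """
    study = _small_study(seed)
    y = cell_table(study)
    # standardize once so the comparison is scale-free
    v = y.frame["value"]
    y.frame["value"] = (v - v.mean()) / v.std()
    g = generative_kernel(study)
    a = pedigree_a(study.pedigree)
    a.matrix = a.matrix / float(np.diag(a.matrix).mean())
    cells = IncidenceMap.from_cells(
        zip(y.frame["line"], y.frame["environment"])
    )
    out = {}
    for model_id in MODEL_TERMS:
        model = build_model(model_id, {"A": a, "G": g}, cells)
        variances = {label: 0.4 for label in MODEL_TERMS[model_id]}
        blup = mme_solve(y, model, variances, 1.0)
        gibbs = fit_gibbs(
            y,
            model,
            SamplerConfig(
                n_iter=n_iter,
                burn_in=burn_in,
                thin=2,
                seed=seed + 1,
                standardize_response=False,
                fixed_variances={**variances, "e": 1.0},
            ),
        )
        diff = np.max(
            np.abs(
                blup.yhat.frame["value"].to_numpy()
                - gibbs.yhat.frame["value"].to_numpy()
            )
        )
        out[model_id] = float(diff)
    return out


def _cv_study(seed: int, var_ge: float):
    cfg = SimulationConfig(
        n_lines=100,
        n_markers=800,
        n_founders=25,
        n_generations=2,
        n_envs=6,
        n_reps=1,
        blocks_per_rep=1,
        var_env=1.0,
        var_line=0.0,
        var_g=0.6,
        var_a=0.0,
        var_ge=var_ge,
        var_ae=0.0,
        var_rep=0.0,
        var_block=0.0,
        var_e=1.0,
        missing_cell_rate=0.0,
        seed=seed,
    )
    return simulate_study(cfg)


_CV_SAMPLER = SamplerConfig(n_iter=1200, burn_in=300, thin=3)


def cv_null_m1(seed: int = 0, replicates: int = 20) -> dict:
    """CV1 prediction ability of M1 on data with genomic signal.

    M1 carries no line-specific information for unobserved lines, so its
    per-environment mean ability should sit near zero; what remains is the
    Monte-Carlo noise of the sampled line effects.
    """
    study = _cv_study(seed, var_ge=0.4)
    y = cell_table(study)
    result = run_grid(
        y, {}, ["M1"], ["CV1"],
        sampler_config=_CV_SAMPLER,
        k=5, replicates=replicates, seed=seed,
    )
    per_env = result.per_env_summary()
    return {
        "per_env_mean": dict(
            zip(per_env["environment"], per_env["mean_r"].astype(float))
        ),
        "max_abs_mean": float(per_env["mean_r"].abs().max()),
        "n_runs": int(
            result.rows[["replicate", "fold"]].drop_duplicates().shape[0]
        ),
    }


def cv_directional(
    n_seeds: int = 10, base_seed: int = 0, replicates: int = 2
) -> dict:
    """Directional cross-validation contrasts on synthetic data.

    Measures, per seed: grand-mean ability of M3 under CV1 and CV2; of M5
    under CV2 with interaction variance present (σEg² = 0.4) and absent
    (σEg² = 0). Returns 10-seed medians of the contrasts CV2-CV1 (M3),
    M5-M3 under CV2 with G×E, and |M5-M3| under CV2 without G×E.
    """
    cv2_m3_minus_cv1, m5_minus_m3, m5_m3_noge = [], [], []
    for i in range(n_seeds):
        seed = int(
            np.random.SeedSequence([int(base_seed), 82, i]).generate_state(1)[0]
            % (2**31)
        )
        study = _cv_study(seed, var_ge=0.4)
        y = cell_table(study)
        g = generative_kernel(study)
        res = run_grid(
            y, {"G": g}, ["M3", "M5"], ["CV1", "CV2"],
            sampler_config=_CV_SAMPLER,
            k=5, replicates=replicates, seed=seed,
        )
        gm = res.grand_means().set_index(["scheme", "model_id", "trait"])[
            "grand_mean_r"
        ]
        trait = study.config.trait
        cv2_m3_minus_cv1.append(
            float(gm[("CV2", "M3", trait)] - gm[("CV1", "M3", trait)])
        )
        m5_minus_m3.append(
            float(gm[("CV2", "M5", trait)] - gm[("CV2", "M3", trait)])
        )

        study0 = _cv_study(seed + 1, var_ge=0.0)
        y0 = cell_table(study0)
        g0 = generative_kernel(study0)
        res0 = run_grid(
            y0, {"G": g0}, ["M3", "M5"], ["CV2"],
            sampler_config=_CV_SAMPLER,
            k=5, replicates=replicates, seed=seed,
        )
        gm0 = res0.grand_means().set_index(["scheme", "model_id", "trait"])[
            "grand_mean_r"
        ]
        trait0 = study0.config.trait
        m5_m3_noge.append(
            float(gm0[("CV2", "M5", trait0)] - gm0[("CV2", "M3", trait0)])
        )
    return {
        "cv2_minus_cv1_m3": float(np.median(cv2_m3_minus_cv1)),
        "m5_minus_m3_cv2": float(np.median(m5_minus_m3)),
        "m5_minus_m3_cv2_no_ge": float(np.median(m5_m3_noge)),
        "per_seed": {
            "cv2_minus_cv1_m3": cv2_m3_minus_cv1,
            "m5_minus_m3_cv2": m5_minus_m3,
            "m5_minus_m3_cv2_no_ge": m5_m3_noge,
        },
    }
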