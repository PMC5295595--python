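import numpy as np
import pandas as pd
import pytest

from gxepred import (
    IncidenceMap,
    LineEnvTable,
    MODEL_TERMS,
    RelationshipKernel,
    SamplerConfig,
    build_model,
    fit_gibbs,
    mme_solve,
    predict_cells,
)
from gxepred.errors import ConfigError, DataError
from gxepred.experiments import cell_table, generative_kernel
from gxepred.simulate import SimulationConfig, simulate_study


class TestBuildModel:
    @pytest.mark.parametrize(
        "model_id,expected",
        [
            ("M1", ("E", "L")),
            ("M2", ("E", "L", "A")),
            ("M3", ("E", "L", "G")),
            ("M4", ("E", "L", "A", "AE")),
            ("M5", ("E", "L", "G", "GE")),
            ("M6", ("E", "L", "A", "G")),
            ("M7", ("E", "L", "A", "G", "AE", "GE")),
        ],
    )
    def test_term_sets(self, model_id, expected, grid_table):
        _, cells, kernel = grid_table
        model = build_model(model_id, {"A": kernel, "G": kernel}, cells)
        assert model.term_labels() == expected

    def test_missing_kernel_is_error(self, grid_table):
        _, cells, kernel = grid_table
        with pytest.raises(ConfigError, match="requires the A kernel"):
            build_model("M2", {"G": kernel}, cells)
        # M5 needs only G
        model = build_model("M5", {"G": kernel}, cells)
        assert model.term_labels() == ("E", "L", "G", "GE")


class TestMmeSolve:
    def test_constant_response_gives_zero_effects(self, grid_table):
        table, cells, kernel = grid_table
        const = LineEnvTable(table.frame.assign(value=3.25))
        model = build_model("M3", {"G": kernel}, cells)
        fit = mme_solve(const, model, {"E": 1.0, "L": 1.0, "G": 1.0}, 1.0)
        assert fit.mu_hat == pytest.approx(3.25, abs=1e-8)
        for effects in fit.cell_effects.values():
            assert np.max(np.abs(effects)) < 1e-8

    def test_ridge_limit_effects_vanish(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M1", {}, cells)
        tiny = mme_solve(table, model, {"E": 1e-10, "L": 1e-10}, 1.0)
        assert np.max(np.abs(tiny.cell_effects["L"])) < 1e-6
        assert tiny.yhat.frame["value"].std() < 1e-6  # yhat -> mu

    def test_matches_dense_joint_solve(self, grid_table):
        """Hand-built dense mixed-model system on a 3-observation subset."""
        table, cells, kernel = grid_table
        sub = LineEnvTable(table.frame.iloc[[0, 13, 26]])
        model = build_model("M3", {"G": kernel}, cells)
        var = {"E": 0.7, "L": 0.4, "G": 0.9}
        fit = mme_solve(sub, model, var, 1.3)
        # dense construction: V = sum sigma2 * K_obs + var_e I
        obs = [(l, e) for l, e in zip(sub.frame["line"], sub.frame["environment"])]
        y = sub.frame["value"].to_numpy()
        idx = {l: i for i, l in enumerate(kernel.ids)}
        n = len(obs)
        V = 1.3 * np.eye(n)
        for (la, ea), i in zip(obs, range(n)):
            for (lb, eb), j in zip(obs, range(n)):
                V[i, j] += var["E"] * (ea == eb)
                V[i, j] += var["L"] * (la == lb)
                V[i, j] += var["G"] * kernel.matrix[idx[la], idx[lb]]
        ones = np.ones(n)
        vinv = np.linalg.inv(V)
        mu = float(ones @ vinv @ y / (ones @ vinv @ ones))
        assert fit.mu_hat == pytest.approx(mu, abs=1e-10)
        # fitted values = mu + total BLUP = mu + C Vinv (y - mu)
        C = V - 1.3 * np.eye(n)
        fitted = mu + C @ vinv @ (y - mu * ones)
        np.testing.assert_allclose(
            fit.yhat.frame["value"].to_numpy(), fitted, atol=1e-10
        )

    def test_exchangeability_under_cell_permutation(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M5", {"G": kernel}, cells)
        var = {"E": 0.5, "L": 0.3, "G": 0.6, "GE": 0.4}
        fit1 = mme_solve(table, model, var, 1.0)
        perm = table.frame.sample(frac=1.0, random_state=4)
        fit2 = mme_solve(LineEnvTable(perm), model, var, 1.0)
        a = fit1.yhat.frame.sort_values(["environment", "line"])["value"]
        b = fit2.yhat.frame.sort_values(["environment", "line"])["value"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_nesting_m5_collapses_to_m3(self, grid_table):
        table, cells, kernel = grid_table
        m3 = build_model("M3", {"G": kernel}, cells)
        m5 = build_model("M5", {"G": kernel}, cells)
        var3 = {"E": 0.5, "L": 0.3, "G": 0.6}
        f3 = mme_solve(table, m3, var3, 1.0)
        f5 = mme_solve(table, m5, {**var3, "GE": 1e-9}, 1.0)
        np.testing.assert_allclose(
            f3.yhat.frame["value"].to_numpy(),
            f5.yhat.frame["value"].to_numpy(),
            atol=1e-6,
        )


class TestGibbs:
    def test_fixed_variance_posterior_matches_blup(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M5", {"G": kernel}, cells)
        var = {"E": 0.5, "L": 0.3, "G": 0.4, "GE": 0.2}
        blup = mme_solve(table, model, var, 1.0)
        gibbs = fit_gibbs(
            table,
            model,
            SamplerConfig(
                n_iter=6000, burn_in=1000, thin=2, seed=7,
                standardize_response=False,
                fixed_variances={**var, "e": 1.0},
            ),
        )
        diff = np.abs(
            blup.yhat.frame["value"].to_numpy()
            - gibbs.yhat.frame["value"].to_numpy()
        )
        assert diff.max() < 0.05

    def test_seeded_determinism(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M3", {"G": kernel}, cells)
        cfg = SamplerConfig(n_iter=400, burn_in=100, seed=5)
        f1 = fit_gibbs(table, model, cfg)
        f2 = fit_gibbs(table, model, cfg)
        assert f1.mu_hat == f2.mu_hat
        for k in f1.var_components:
            assert f1.var_components[k] == f2.var_components[k]

    def test_null_permutation_keeps_genomic_share_small(self):
        """Permuting the response against the genotypes should leave the
        genomic variance share near its prior."""
        cfg = SimulationConfig(
            n_lines=200, n_markers=600, n_founders=40, n_envs=5, n_reps=1,
            blocks_per_rep=1, var_env=1.0, var_line=0.0, var_g=0.6,
            var_a=0.0, var_ge=0.0, var_ae=0.0, var_rep=0.0, var_block=0.0,
            var_e=1.0, missing_cell_rate=0.0, seed=21,
        )
        study = simulate_study(cfg)
        y = cell_table(study)
        rng = np.random.default_rng(0)
        # permute line labels within environment: destroys the line-genotype link
        frame = y.frame.copy()
        for env, sub in frame.groupby("environment"):
            frame.loc[sub.index, "value"] = rng.permutation(
                sub["value"].to_numpy()
            )
        y_null = LineEnvTable(frame)
        g = generative_kernel(study)
        cells = IncidenceMap.from_cells(
            zip(frame["line"], frame["environment"])
        )
        model = build_model("M3", {"G": g}, cells)
        fit = fit_gibbs(
            y_null, model,
            SamplerConfig(n_iter=2000, burn_in=500, seed=1,
                          standardize_response=False),
        )
        vg = fit.var_components["G"]["mean"]
        ve = fit.var_components["e"]["mean"]
        assert vg / (vg + ve) < 0.15


class TestPrediction:
    def test_observed_cell_prediction_equals_fitted(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M3", {"G": kernel}, cells)
        fit = mme_solve(table, model, {"E": 0.5, "L": 0.3, "G": 0.6}, 1.0)
        target = table.frame.iloc[7]
        pred = predict_cells(fit, [(target["line"], target["environment"])])
        fitted = fit.yhat.frame
        match = fitted[
            (fitted["line"] == target["line"])
            & (fitted["environment"] == target["environment"])
        ]["value"].iloc[0]
        assert pred.frame["value"].iloc[0] == pytest.approx(match, abs=1e-8)

    def test_m1_unobserved_line_prediction_is_mu_plus_env(self, grid_table):
        table, cells, kernel = grid_table
        # hold out line l11 entirely
        train = LineEnvTable(table.frame[table.frame["line"] != "l11"])
        model = build_model("M1", {}, cells)
        fit = mme_solve(train, model, {"E": 0.5, "L": 0.3}, 1.0)
        pred = predict_cells(fit, [("l11", "e0"), ("l11", "e3")])
        env_effect = {
            e: fit.cell_effects["E"][
                [c[1] for c in fit._obs.cells].index(e)
            ]
            for e in ("e0", "e3")
        }
        for _, row in pred.frame.iterrows():
            assert row["value"] == pytest.approx(
                fit.mu_hat + env_effect[row["environment"]], abs=1e-8
            )

    def test_genomic_duplicate_line_prediction(self, grid_table):
        """An unobserved line genotypically identical to a training line
        gets that line's genomic component."""
        table, cells, kernel = grid_table
        lines = list(kernel.ids) + ["clone"]
        k = np.zeros((13, 13))
        k[:12, :12] = kernel.matrix
        k[12, :12] = kernel.matrix[0, :]
        k[:12, 12] = kernel.matrix[:, 0]
        k[12, 12] = kernel.matrix[0, 0]
        kernel2 = RelationshipKernel(lines, k, "G")
        cells2 = IncidenceMap.from_cells(
            [(l, e) for e in ("e0", "e1", "e2", "e3", "e4") for l in lines]
        )
        model = build_model("M3", {"G": kernel2}, cells2)
        fit = mme_solve(table, model, {"E": 0.5, "L": 0.3, "G": 0.6}, 1.0)
        pred = predict_cells(fit, [("clone", "e0")])
        obs_cells = fit._obs.cells
        g_l00 = fit.cell_effects["G"][obs_cells.index(("l00", "e0"))]
        e_e0 = fit.cell_effects["E"][
            [c[1] for c in obs_cells].index("e0")
        ]
        assert pred.frame["value"].iloc[0] == pytest.approx(
            fit.mu_hat + e_e0 + g_l00, abs=1e-6
        )

    def test_unknown_environment_is_error(self, grid_table):
        table, cells, kernel = grid_table
        model = build_model("M1", {}, cells)
        fit = mme_solve(table, model, {"E": 0.5, "L": 0.3}, 1.0)
        with pytest.raises(DataError, match="environment"):
            predict_cells(fit, [("l00", "new_env")])

    def test_standardization_roundtrip_on_predictions(self, grid_table):
        """Per-environment standardization must not change within-environment
        ranking of predictions."""
        table, cells, kernel = grid_table
        hold = table.frame.index % 5 == 4  # cells spread over all envs
        train = LineEnvTable(table.frame[~hold])
        holdout = [
            tuple(r)
            for r in table.frame[hold][["line", "environment"]].to_numpy()
        ]
        model = build_model("M3", {"G": kernel}, cells)
        preds = {}
        for std in (True, False):
            cfg = SamplerConfig(
                n_iter=3000, burn_in=500, seed=3, standardize_response=std,
                predictive_draws=False,
            )
            fit = fit_gibbs(train, model, cfg)
            p = predict_cells(fit, holdout)
            preds[std] = p.frame.sort_values("line")["value"].to_numpy()
        r = np.corrcoef(preds[True], preds[False])[0, 1]
        assert r > 0.95
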