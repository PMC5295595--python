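import numpy as np
import pandas as pd
import pytest

from gxepred import (
    CVResult,
    LineEnvTable,
    make_cv1,
    make_cv2,
    prediction_ability,
    run_grid,
    tukey_compare,
)
from gxepred.errors import ConfigError, DataError
from gxepred.experiments import cell_table, generative_kernel
from gxepred.models import SamplerConfig
from gxepred.simulate import SimulationConfig, simulate_study

_FAST = SamplerConfig(n_iter=400, burn_in=100, thin=2)


def _full_grid_cells(n_lines, n_envs):
    lines = [f"l{i:03d}" for i in range(n_lines)]
    envs = [f"e{j}" for j in range(n_envs)]
    return lines, envs, [(l, e) for e in envs for l in lines]


class TestCV1:
    def test_fold_sizes_287_lines(self):
        lines, _, cells = _full_grid_cells(287, 2)
        parts = make_cv1(lines, cells, k=5, replicates=1, seed=0)
        sizes = sorted(
            len({l for l, _ in p.masked_cells}) for p in parts
        )
        assert sizes == [57, 57, 57, 58, 58]

    def test_partition_property(self):
        lines, _, cells = _full_grid_cells(23, 3)
        parts = make_cv1(lines, cells, k=5, replicates=2, seed=1)
        for rep in (1, 2):
            rep_parts = [p for p in parts if p.replicate == rep]
            masked_lines = [
                {l for l, _ in p.masked_cells} for p in rep_parts
            ]
            union = set().union(*masked_lines)
            assert union == set(lines)
            total = sum(len(s) for s in masked_lines)
            assert total == len(lines)  # pairwise disjoint

    def test_run_count_100(self):
        lines, _, cells = _full_grid_cells(10, 2)
        parts = make_cv1(lines, cells, k=5, replicates=20, seed=2)
        assert len(parts) == 100

    def test_k_exceeding_lines_is_error(self):
        lines, _, cells = _full_grid_cells(4, 2)
        with pytest.raises(ConfigError):
            make_cv1(lines, cells, k=5, replicates=1, seed=0)


class TestCV2:
    def test_stratified_spread_one_cell_per_fold(self):
        lines, _, cells = _full_grid_cells(8, 5)
        parts = make_cv2(cells, k=5, replicates=1, seed=3)
        for line in lines:
            per_fold = [
                sum(1 for l, _ in p.masked_cells if l == line) for p in parts
            ]
            assert per_fold.count(1) == 5  # exactly one cell per fold

    def test_masked_line_keeps_training_cells(self):
        lines, _, cells = _full_grid_cells(12, 6)
        parts = make_cv2(cells, k=5, replicates=2, seed=4)
        by_line = {}
        for l, e in cells:
            by_line.setdefault(l, set()).add((l, e))
        for p in parts:
            for line in {l for l, _ in p.masked_cells}:
                masked_of_line = {
                    c for c in p.masked_cells if c[0] == line
                }
                assert by_line[line] - masked_of_line  # non-empty training

    def test_full_grid_20x6_masks_24_per_fold(self):
        _, _, cells = _full_grid_cells(20, 6)
        parts = make_cv2(cells, k=5, replicates=1, seed=5)
        assert [len(p.masked_cells) for p in parts] == [24] * 5

    def test_single_env_lines_never_masked(self):
        cells = [("solo", "e0")] + [
            (f"l{i}", e) for i in range(6) for e in ("e0", "e1", "e2")
        ]
        parts = make_cv2(cells, k=3, replicates=2, seed=6)
        for p in parts:
            assert all(l != "solo" for l, _ in p.masked_cells)

    def test_partition_of_maskable_universe(self):
        _, _, cells = _full_grid_cells(9, 4)
        parts = make_cv2(cells, k=5, replicates=1, seed=7)
        union = set().union(*(p.masked_cells for p in parts))
        assert union == set(cells)
        assert sum(len(p.masked_cells) for p in parts) == len(cells)


class TestPredictionAbility:
    def _tables(self, obs, pred):
        def table(vals):
            return LineEnvTable(
                pd.DataFrame(
                    {
                        "trait": "t",
                        "environment": "e",
                        "line": [f"l{i}" for i in range(len(vals))],
                        "value": vals,
                    }
                )
            )

        return table(obs), table(pred)

    def test_perfect_and_inverted(self):
        o, p = self._tables([1, 2, 3], [2, 4, 6])
        assert prediction_ability(o, p, "e") == pytest.approx(1.0)
        o, p = self._tables([1, 2, 3], [3, 2, 1])
        assert prediction_ability(o, p, "e") == pytest.approx(-1.0)

    def test_zero_variance_is_missing_not_zero(self):
        o, p = self._tables([1, 2, 3], [5, 5, 5])
        assert np.isnan(prediction_ability(o, p, "e"))

    def test_too_few_pairs_is_error(self):
        o, p = self._tables([1, 2], [1, 2])
        with pytest.raises(DataError, match=">= 3"):
            prediction_ability(o, p, "e")


@pytest.fixture(scope="module")
def cv_study():
    cfg = SimulationConfig(
        n_lines=30, n_markers=200, n_founders=10, n_envs=4, n_reps=1,
        blocks_per_rep=1, var_env=1.0, var_line=0.0, var_g=0.6, var_a=0.0,
        var_ge=0.2, var_ae=0.0, var_rep=0.0, var_block=0.0, var_e=0.8,
        missing_cell_rate=0.0, seed=31,
    )
    return simulate_study(cfg)


class TestRunGrid:
    def test_determinism(self, cv_study):
        y = cell_table(cv_study)
        g = generative_kernel(cv_study)
        kwargs = dict(
            sampler_config=_FAST, k=5, replicates=1, seed=9
        )
        r1 = run_grid(y, {"G": g}, ["M3"], ["CV1"], **kwargs)
        r2 = run_grid(y, {"G": g}, ["M3"], ["CV1"], **kwargs)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)

    def test_partitions_shared_across_models(self, cv_study):
        """Adding a model must not perturb the partitions: M3's scores are
        identical whether it runs alone or alongside M1."""
        y = cell_table(cv_study)
        g = generative_kernel(cv_study)
        kwargs = dict(sampler_config=_FAST, k=5, replicates=1, seed=9)
        solo = run_grid(y, {"G": g}, ["M3"], ["CV1"], **kwargs)
        both = run_grid(y, {"G": g}, ["M1", "M3"], ["CV1"], **kwargs)
        m3 = both.rows[both.rows["model_id"] == "M3"].reset_index(drop=True)
        pd.testing.assert_frame_equal(solo.rows, m3)

    def test_masked_values_never_reach_the_fit(self, cv_study):
        """Poisoning the masked cells' values must leave results unchanged
        (the sentinel-leakage guard)."""
        y = cell_table(cv_study)
        g = generative_kernel(cv_study)
        parts = make_cv1(
            sorted(set(y.frame["line"])),
            list(zip(y.frame["line"], y.frame["environment"])),
            k=5, replicates=1, seed=12,
        )
        masked = parts[0].masked_cells
        keys = list(zip(y.frame["line"], y.frame["environment"]))
        in_mask = np.array([key in masked for key in keys])
        poisoned = y.frame.copy()
        poisoned.loc[in_mask, "value"] = 1e9

        from gxepred import IncidenceMap, build_model, fit_gibbs, predict_cells

        cells = IncidenceMap.from_cells(keys)
        model = build_model("M3", {"G": g}, cells)
        cfg = SamplerConfig(n_iter=400, burn_in=100, seed=5)
        p1 = predict_cells(
            fit_gibbs(LineEnvTable(y.frame[~in_mask]), model, cfg),
            sorted(masked),
        )
        p2 = predict_cells(
            fit_gibbs(
                LineEnvTable(poisoned[~in_mask]), model, cfg
            ),
            sorted(masked),
        )
        pd.testing.assert_frame_equal(p1.frame, p2.frame)

    def test_aggregation_shapes(self, cv_study):
        y = cell_table(cv_study)
        g = generative_kernel(cv_study)
        res = run_grid(
            y, {"G": g}, ["M1", "M3"], ["CV2"],
            sampler_config=_FAST, k=5, replicates=2, seed=3,
        )
        summary = res.per_env_summary()
        assert set(summary["model_id"]) == {"M1", "M3"}
        assert summary["environment"].nunique() == 4
        grand = res.grand_means()
        assert len(grand) == 2
        assert res.rows["pearson_r"].dropna().between(-1, 1).all()
        assert (res.rows["n_pairs"] >= 3).all()


class TestTukey:
    def _toy_result(self, shift=0.0, n_models=3, n_envs=6):
        rng = np.random.default_rng(0)
        rows = []
        for mi in range(n_models):
            for ei in range(n_envs):
                base = 0.3 + 0.05 * ei + rng.normal(0, 0.01)
                r = base + (shift if mi == 0 else 0.0)
                rows.append(
                    ("CV1", f"M{mi + 1}", "t", f"e{ei}", 1, 1, r, 10)
                )
        return CVResult(
            rows=pd.DataFrame(
                rows,
                columns=[
                    "scheme", "model_id", "trait", "environment",
                    "replicate", "fold", "pearson_r", "n_pairs",
                ],
            )
        )

    def test_identical_models_share_letter(self):
        res = self._toy_result(shift=0.0)
        out = tukey_compare(res, "CV1")
        assert set(out["letters"].values()) == {"a"}

    def test_shifted_model_gets_distinct_letter(self):
        res = self._toy_result(shift=0.5)
        out = tukey_compare(res, "CV1")
        assert out["letters"]["M1"] != out["letters"]["M2"]
        assert out["letters"]["M2"] == out["letters"]["M3"]

    def test_hand_computed_hsd_on_toy_table(self):
        res = self._toy_result(shift=0.5)
        out = tukey_compare(res, "CV1")
        table = (
            res.per_env_summary()
            .pivot_table(index="environment", columns="model_id",
                         values="mean_r")
        )
        y = table.to_numpy()
        resid = (
            y
            - y.mean(axis=1, keepdims=True)
            - y.mean(axis=0, keepdims=True)
            + y.mean()
        )
        mse = (resid**2).sum() / (5 * 2)
        from scipy.stats import studentized_range

        hsd = studentized_range.ppf(0.95, 3, 10) * np.sqrt(mse / 6)
        assert out["hsd"] == pytest.approx(hsd, rel=1e-10)

    def test_env_order_invariance(self):
        res = self._toy_result(shift=0.5)
        shuffled = CVResult(
            rows=res.rows.sample(frac=1.0, random_state=2).reset_index(
                drop=True
            )
        )
        assert (
            tukey_compare(res, "CV1")["letters"]
            == tukey_compare(shuffled, "CV1")["letters"]
        )

    def test_single_environment_is_error(self):
        res = self._toy_result()
        res.rows = res.rows[res.rows["environment"] == "e0"]
        with pytest.raises(DataError, match="environments"):
            tukey_compare(res, "CV1")
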