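"""Cross-validation designs, metrics, and the CV drivers."""

import numpy as np
import pandas as pd
import pytest

from serrblup import (PhenotypeTable, joint_environment_phenotype, make_folds,
                      prediction_accuracy, predictive_ability,
                      run_bivariate_cv, run_univariate_cv,
                      simulate_genotypes, simulate_multi_env_phenotypes)


class TestMakeFolds:
    def test_equal_partition(self):
        d = make_folds([f"L{i}" for i in range(10)], k=5, seed=1)
        sizes = [len(f) for f in d.partitions[0]]
        assert sizes == [2] * 5
        union = np.concatenate(d.partitions[0])
        assert sorted(union) == sorted(f"L{i}" for i in range(10))

    def test_near_equal_partition(self):
        d = make_folds([f"L{i}" for i in range(11)], k=5, seed=1)
        sizes = sorted(len(f) for f in d.partitions[0])
        assert sizes == [2, 2, 2, 2, 3]

    def test_seed_reproducibility(self):
        ids = [f"L{i}" for i in range(23)]
        d1, d2 = make_folds(ids, seed=9), make_folds(ids, seed=9)
        for f1, f2 in zip(d1.partitions, d2.partitions):
            for a, b in zip(f1, f2):
                np.testing.assert_array_equal(a, b)

    def test_disjoint_cover_every_replicate(self):
        d = make_folds([f"L{i}" for i in range(17)], seed=3)
        for folds in d.partitions:
            ids = np.concatenate(folds)
            assert len(ids) == len(set(ids)) == 17

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(["a", "b", "c"], k=1)


class TestMetrics:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 4.0])
        assert predictive_ability(y, y) == pytest.approx(1.0)
        assert predictive_ability(-y, y) == pytest.approx(-1.0)

    def test_constant_prediction_is_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out = predictive_ability(np.ones(4), np.array([1.0, 2, 3, 4]))
        assert np.isnan(out)

    @pytest.mark.parametrize("pa, h2, expected", [(0.5, 0.25, 1.0),
                                                  (0.3, 1.0, 0.3),
                                                  (0.0, 0.5, 0.0)])
    def test_accuracy_scaling(self, pa, h2, expected):
        assert prediction_accuracy(pa, h2) == pytest.approx(expected)

    def test_accuracy_invalid_h2(self):
        with pytest.raises(ValueError, match="heritability"):
            prediction_accuracy(0.5, 0.0)


class TestJointEnvironment:
    def _table(self):
        return PhenotypeTable(pd.DataFrame([
            {"line": "L1", "environment": "A", "value": 1.0},
            {"line": "L1", "environment": "B", "value": 2.0},
            {"line": "L1", "environment": "C", "value": 4.0},
            {"line": "L2", "environment": "A", "value": 9.0},
            {"line": "L3", "environment": "B", "value": 5.0},
            {"line": "L3", "environment": "C", "value": 5.0},
        ]))

    def test_mean_over_non_target(self):
        j = joint_environment_phenotype(self._table(), "A")
        assert j.loc["L1"] == pytest.approx(3.0)  # mean of (2, 4)
        assert j.loc["L3"] == pytest.approx(5.0)  # all equal -> that value

    def test_target_only_line_missing(self):
        j = joint_environment_phenotype(self._table(), "A")
        assert "L2" not in j.index  # L2 observed only in the target env

    def test_single_environment_rejected(self):
        t = PhenotypeTable(pd.DataFrame(
            [{"line": "L1", "environment": "A", "value": 1.0}]))
        with pytest.raises(ValueError, match="non-target"):
            joint_environment_phenotype(t, "A")


@pytest.fixture(scope="module")
def small_study():
    """Small two-environment epistatic dataset shared by the CV tests."""
    g = simulate_genotypes(60, 30, n_blocks=6, seed=77)
    phenos, truth = simulate_multi_env_phenotypes(
        g, n_additive=3, n_epistatic_pairs=5, h2=0.7, rho_g=0.8, seed=77)
    return g, phenos


class TestUnivariateCV:
    def test_serrblup_pi_one_bit_matches_errblup(self, small_study):
        g, phenos = small_study
        r_err = run_univariate_cv("ERRBLUP", g, phenos, "E2", seed=5)
        r_s = run_univariate_cv("sERRBLUP", g, phenos, "E2",
                                selection_envs="E1", pi=1.0, seed=5)
        pa_err = r_err.records["predictive_ability"].to_numpy()
        pa_s = r_s.records["predictive_ability"].to_numpy()
        np.testing.assert_array_equal(pa_err, pa_s)

    def test_same_seed_gives_paired_folds_across_models(self, small_study):
        g, phenos = small_study
        r1 = run_univariate_cv("GBLUP", g, phenos, "E2", seed=3)
        r2 = run_univariate_cv("ERRBLUP", g, phenos, "E2", seed=3)
        assert (r1.records[["replicate", "fold"]]
                .equals(r2.records[["replicate", "fold"]]))
        assert len(r1.records) == 25

    def test_rerun_is_bit_reproducible(self, small_study):
        g, phenos = small_study
        a = run_univariate_cv("GBLUP", g, phenos, "E2", seed=4)
        b = run_univariate_cv("GBLUP", g, phenos, "E2", seed=4)
        assert a.mean == b.mean
        np.testing.assert_array_equal(a.records["predictive_ability"],
                                      b.records["predictive_ability"])

    def test_within_environment_selection_runs(self, small_study):
        """Within-env mode: selection from each training fold only."""
        g, phenos = small_study
        design = make_folds(phenos.env_series("E2").index, k=5, reps=1, seed=6)
        r = run_univariate_cv("sERRBLUP", g, phenos, "E2",
                              selection_envs="E2", pi=0.05, design=design)
        assert len(r.records) == 5
        assert np.isfinite(r.mean)

    def test_h2_auto_approximation(self, small_study):
        g, phenos = small_study
        r = run_univariate_cv("GBLUP", g, phenos, "E2", h2="auto", seed=1)
        assert r.h2 is not None and 0 < r.h2 <= 1
        assert r.accuracy == pytest.approx(r.mean / np.sqrt(r.h2))

    def test_unknown_environment_rejected(self, small_study):
        g, phenos = small_study
        with pytest.raises(KeyError, match="E9"):
            run_univariate_cv("GBLUP", g, phenos, "E9")

    def test_unknown_model_rejected(self, small_study):
        g, phenos = small_study
        with pytest.raises(ValueError, match="unknown model"):
            run_univariate_cv("XBLUP", g, phenos, "E2")


class TestHeritabilityMonotonicity:
    def test_higher_heritability_raises_predictive_ability(self):
        """Raising simulated h2 from 0.2 to 0.8 raises the mean predictive
        ability of every model (aggregated over seeds)."""
        means = {h2: {"GBLUP": [], "ERRBLUP": [], "sERRBLUP": []}
                 for h2 in (0.2, 0.8)}
        for seed in range(4):
            g = simulate_genotypes(120, 200, n_blocks=20, seed=300 + seed)
            for h2 in (0.2, 0.8):
                phenos, _ = simulate_multi_env_phenotypes(
                    g, n_additive=10, n_epistatic_pairs=10, h2=h2,
                    rho_g=0.8, seed=300 + seed)
                design = make_folds(phenos.env_series("E2").index, seed=seed)
                for model, kw in [("GBLUP", {}), ("ERRBLUP", {}),
                                  ("sERRBLUP", {"selection_envs": "E1",
                                                "pi": 0.01})]:
                    res = run_univariate_cv(model, g, phenos, "E2",
                                            design=design, **kw)
                    means[h2][model].append(res.mean)
        for model in ("GBLUP", "ERRBLUP", "sERRBLUP"):
            assert np.mean(means[0.8][model]) > np.mean(means[0.2][model])


class TestBivariateCV:
    def test_records_and_flags_complete(self, small_study):
        g, phenos = small_study
        r = run_bivariate_cv("GBLUP", g, phenos, "E2", second_envs="E1",
                             seed=8, max_iter_full=20, max_iter_fold=5)
        assert len(r.records) == 25
        assert len(r.fallback_flags) == 25
        assert np.isfinite(r.mean)

    def test_same_seed_pairs_with_univariate(self, small_study):
        g, phenos = small_study
        design = make_folds(phenos.env_series("E2").index, seed=2)
        ru = run_univariate_cv("GBLUP", g, phenos, "E2", design=design)
        rb = run_bivariate_cv("GBLUP", g, phenos, "E2", second_envs="E1",
                              design=design, max_iter_full=20, max_iter_fold=5)
        assert (ru.records[["replicate", "fold"]]
                .equals(rb.records[["replicate", "fold"]]))

    def test_disjoint_environments_rejected(self):
        g = simulate_genotypes(20, 15, n_blocks=3, seed=1)
        rows = [{"line": l, "environment": "E1", "value": float(i)}
                for i, l in enumerate(g.line_ids[:10])]
        rows += [{"line": l, "environment": "E2", "value": float(i)}
                 for i, l in enumerate(g.line_ids[10:])]
        phenos = PhenotypeTable(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="share"):
            run_bivariate_cv("GBLUP", g, phenos, "E2", second_envs="E1")
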