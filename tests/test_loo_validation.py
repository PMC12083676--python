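"""Leave-one-out network scores, the downdating engine, and associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atrophynet import (LooScores, PhenotypeTable, associate,
                        loo_network_scores, run_validation_suite)


def _cohort(rng, n=12, V=25, signal=0.5):
    suvr = rng.uniform(0.8, 1.8, n)
    cov = rng.normal(size=(n, 3))
    pattern = rng.normal(size=V)
    maps = signal * suvr[:, None] * pattern[None, :] + rng.normal(size=(n, V))
    return maps, suvr, cov


class TestLooEngine:
    def test_downdate_equals_naive_refit(self, rng):
        # the from-scratch refit is the oracle for the downdating algebra
        maps, suvr, cov = _cohort(rng, n=10, V=30)
        naive = loo_network_scores(maps, suvr, cov, mode="naive")
        down = loo_network_scores(maps, suvr, cov, mode="downdate")
        assert np.allclose(naive.r, down.r, atol=1e-8)

    def test_downdate_equals_naive_with_missing_rows(self, rng):
        maps, suvr, cov = _cohort(rng, n=14, V=20)
        cov[2, 1] = np.nan
        naive = loo_network_scores(maps, suvr, cov, mode="naive")
        down = loo_network_scores(maps, suvr, cov, mode="downdate")
        assert np.isnan(naive.r[2]) and np.isnan(down.r[2])
        ok = np.isfinite(naive.r)
        assert np.allclose(naive.r[ok], down.r[ok], atol=1e-8)

    def test_no_leakage_mutation_check(self, rng):
        # r_i must be computed with subject i excluded: duplicating subject
        # i's map as an extra subject changes the LOO map, hence r_i
        maps, suvr, cov = _cohort(rng, n=12, V=25)
        base = loo_network_scores(maps, suvr, cov, mode="downdate")
        i = 4
        maps2 = np.vstack([maps, maps[i]])
        suvr2 = np.r_[suvr, suvr[i]]
        cov2 = np.vstack([cov, cov[i]])
        dup = loo_network_scores(maps2, suvr2, cov2, mode="downdate")
        assert dup.r[i] != pytest.approx(base.r[i], abs=1e-12)

    def test_planted_cohort_separates_amyloid_groups(self, rng):
        from atrophynet import SimConfig, simulate_connectome, simulate_subjects
        from atrophynet.cli_pipeline import run_full, demo_config
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            res = run_full(demo_config(tmp, seed=11))
        rec = next(r for r in res["loo_associations"]
                   if r["outcome"] == "abeta_status")
        assert rec["statistic"] > 0  # Abeta+ subjects score higher

    def test_identical_maps_abort_with_diagnostic(self, rng):
        maps = np.tile(rng.normal(size=25), (12, 1))
        suvr = rng.uniform(0.8, 1.8, 12)
        with pytest.raises(RuntimeError, match="degenerate"), \
                pytest.warns(UserWarning):
            loo_network_scores(maps, suvr, None, mode="downdate")


class TestAssociate:
    def _scores(self, r):
        r = np.asarray(r, float)
        return LooScores(r=r, predictor=np.zeros_like(r))

    def test_perfect_continuous_association(self):
        rec = associate(self._scores([1, 2, 3]), np.array([1.0, 2, 3]),
                        "continuous")
        assert rec.statistic == pytest.approx(1.0)

    def test_continuous_matches_scipy(self, rng):
        r = rng.normal(size=30)
        out = 0.4 * r + rng.normal(size=30)
        rec = associate(self._scores(r), out, "continuous")
        sr, sp = stats.pearsonr(r, out)
        assert rec.statistic == pytest.approx(sr)
        assert rec.p == pytest.approx(sp)

    def test_binary_is_welch_t(self, rng):
        r = rng.normal(size=30)
        groups = rng.integers(0, 2, 30)
        rec = associate(self._scores(r), groups, "binary")
        t, p = stats.ttest_ind(r[groups == 1], r[groups == 0],
                               equal_var=False)
        assert rec.statistic == pytest.approx(t)
        assert rec.p == pytest.approx(p)
        assert "pearson_r" in rec.extra

    def test_binary_and_continuous_agree_on_dummy_outcome(self, rng):
        # with a 0/1 outcome, |t| of the group test maps to |r| through the
        # t <-> r identity (up to the Welch vs pooled variance choice)
        n = 400
        r = rng.normal(size=n)
        groups = rng.integers(0, 2, n)
        t_rec = associate(self._scores(r), groups, "binary")
        r_rec = associate(self._scores(r), groups.astype(float), "continuous")
        t_from_r = r_rec.statistic * np.sqrt((n - 2) /
                                             (1 - r_rec.statistic**2))
        assert abs(t_rec.statistic) == pytest.approx(abs(t_from_r), rel=0.05)

    def test_type_one_error_calibrated(self, rng):
        # independent outcome: p uniform, ~5% rejections at alpha=0.05
        n_sig = 0
        reps = 1000
        for rep in range(reps):
            rep_rng = np.random.default_rng(3000 + rep)
            r = rep_rng.normal(size=25)
            out = rep_rng.normal(size=25)
            rec = associate(self._scores(r), out, "continuous")
            n_sig += rec.p < 0.05
        assert n_sig / reps == pytest.approx(0.05, abs=0.02)

    def test_sign_recovery_on_planted_cohort(self, rng):
        from atrophynet import SimConfig, simulate_connectome, simulate_subjects
        cfg = SimConfig(rng_seed=21, shape=(6, 6, 6), n_networks=6,
                        n_connectome_subjects=10, n_timepoints=80,
                        n_subjects=200)
        conn = simulate_connectome(cfg)
        _, phen, truth = simulate_subjects(cfg, conn)
        # use ground-truth atrophy load as a stand-in score carrier: the
        # planted couplings set the expected signs
        scores = LooScores(r=truth.atrophy_load,
                           predictor=phen.column("suvr"))
        pacc = associate(scores, phen.column("pacc"), "continuous")
        cfi = associate(scores, phen.column("cfi_total").astype(float),
                        "continuous")
        assert pacc.statistic < 0 and pacc.p < 0.05
        assert cfi.statistic > 0 and cfi.p < 0.05

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            associate(self._scores([1, 2, 3]), np.ones(3), "continuous")


class TestValidationSuite:
    def _full_table(self, rng, n=80):
        from atrophynet import SimConfig, simulate_connectome, simulate_subjects
        from atrophynet.phenotypes import enrich_phenotypes
        cfg = SimConfig(rng_seed=31, shape=(4, 4, 4), n_networks=4,
                        n_connectome_subjects=4, n_timepoints=60, n_subjects=n)
        conn = simulate_connectome(cfg)
        _, phen, truth = simulate_subjects(cfg, conn)
        return enrich_phenotypes(phen), truth

    def test_full_table_gives_fourteen_rows(self, rng):
        phen, truth = self._full_table(rng)
        scores = LooScores(r=rng.normal(size=len(phen)),
                           predictor=phen.column("suvr"))
        df = run_validation_suite(scores, phen, on_degenerate="record")
        assert len(df) == 14
        finite = df[df["n"] > 0]
        assert len(finite) >= 12
        assert np.isfinite(finite["statistic"]).all()
        assert np.isfinite(finite["p"]).all()
        assert (df["p_bonferroni"].dropna() >= df["p"].dropna() - 1e-15).all()

    def test_absent_outcome_is_named_error(self, rng):
        phen, _ = self._full_table(rng)
        phen.df.drop(columns=["gds"], inplace=True)
        scores = LooScores(r=rng.normal(size=len(phen)),
                           predictor=phen.column("suvr"))
        with pytest.raises(KeyError, match="gds"):
            run_validation_suite(scores, phen)

    def test_null_cohort_family_rarely_significant_after_bonferroni(self):
        # no planted couplings: Bonferroni across the 14 outcomes leaves any
        # replicate with a hit at most ~5% of the time; the count over 20
        # replicates must stay inside the exact binomial 98% band (<= 3)
        n_any = 0
        reps = 20
        from atrophynet import SimConfig, simulate_connectome, simulate_subjects
        from atrophynet.phenotypes import enrich_phenotypes
        for rep in range(reps):
            cfg = SimConfig(rng_seed=7000 + rep, shape=(3, 3, 3), n_networks=3,
                            n_connectome_subjects=2, n_timepoints=40,
                            n_subjects=60, atrophy_gain=0.0,
                            cognition_coupling=0.0)
            conn = simulate_connectome(cfg)
            _, phen, _ = simulate_subjects(cfg, conn)
            phen = enrich_phenotypes(phen)
            rep_rng = np.random.default_rng(rep)
            scores = LooScores(r=rep_rng.normal(size=60),
                               predictor=phen.column("suvr"))
            df = run_validation_suite(scores, phen, on_degenerate="record")
            n_any += (df["p_bonferroni"].dropna() <= 0.05).any()
        assert n_any <= 3
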