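"""Overlap significance, t-test filters, modality bias, resampling null."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import gsmeth as gm
from gsmeth.filters import pairwise_class_ttests
from gsmeth.matrixio import TISSUES, OmicsMatrix, SampleDesign


def _design(n_per_class=5):
    rows = []
    for t in TISSUES:
        for i in range(n_per_class):
            rows.append((f"{t}{i}", f"S{i}", t))
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue"]).set_index("sample_id")
    return SampleDesign(df)


def _matrix(values, design, modality="genotype"):
    probes = [f"p{i}" for i in range(values.shape[0])]
    return OmicsMatrix(pd.DataFrame(values, index=probes, columns=design.sample_ids), modality)


class TestOverlapPvalue:
    def test_observed_zero_is_one(self):
        assert gm.overlap_pvalue(100, 10, 10, 0) == 1.0
        assert gm.overlap_pvalue(100, 10, 10, 0, log=True) == 0.0

    def test_matches_exhaustive_enumeration(self):
        # fix the first 3-subset (exchangeability) and enumerate the second
        M, k = 10, 3
        first = set(range(k))
        counts = {obs: 0 for obs in range(k + 1)}
        total = 0
        for second in itertools.combinations(range(M), k):
            counts[len(first & set(second))] += 1
            total += 1
        for obs in range(k + 1):
            exact = sum(counts[o] for o in range(obs, k + 1)) / total
            assert gm.overlap_pvalue(M, k, k, obs) == pytest.approx(exact, rel=1e-12)

    def test_monotone_nonincreasing_in_observed(self):
        ps = [gm.overlap_pvalue(500, 40, 60, o) for o in range(41)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_log_space_consistency_and_extreme_tails(self):
        p = gm.overlap_pvalue(1000, 50, 50, 10)
        logp = gm.overlap_pvalue(1000, 50, 50, 10, log=True)
        assert np.log(p) == pytest.approx(logp, abs=1e-10)
        # far below the smallest positive double, only log form is usable
        assert gm.overlap_pvalue(250000, 300, 300, 250, log=True) < -700

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            gm.overlap_pvalue(10, 3, 3, 4)
        with pytest.raises(ValueError):
            gm.overlap_pvalue(10, 12, 3, 1)


def _bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg adjusted values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBHAdjustment:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_statsmodels_route_matches_stepup_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, _bh_stepup_oracle(pvals), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = _bh_stepup_oracle(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPairwiseClassTtests:
    def test_null_probe_raw_p_matches_t_cdf_oracle(self):
        design = _design(5)
        # fixed numeric fixture: identical values in every class
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), (1, 3))
        out = pairwise_class_ttests(_matrix(vals, design), design, ["p0"])
        # Welch t = 0 for identical samples -> one-sided P = 0.5 exactly
        t_oracle = stats.t.sf(0.0, df=8)
        for pair in ("tumor_vs_normal", "tumor_vs_blood", "normal_vs_blood"):
            assert out.loc["p0", f"p_{pair}"] == pytest.approx(t_oracle, abs=1e-12)
        assert not out.loc["p0", "pass_all"]

    def test_strongly_ordered_probe_passes(self):
        design = _design(30)
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(mu, 0.1, size=30) for mu in (1.0, 2.0, 3.0)]
        ).reshape(1, 90)
        out = pairwise_class_ttests(_matrix(vals, design), design, ["p0"], alpha=0.05)
        assert out["pass_all"].iloc[0]
        assert (out.filter(like="adj_p_").iloc[0] < 0.05).all()

    def test_wrong_direction_fails(self):
        design = _design(30)
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(mu, 0.1, size=30) for mu in (1.0, 2.0, 3.0)]
        ).reshape(1, 90)
        out = pairwise_class_ttests(
            _matrix(vals, design), design, ["p0"], direction="decreasing"
        )
        assert (out.filter(like="p_").iloc[0][:3] > 0.95).all()
        assert not out["pass_all"].iloc[0]

    def test_zero_variance_probe_flagged_untestable(self):
        design = _design(5)
        vals = np.vstack(
            [np.ones(15), np.linspace(0, 1, 15)]
        )
        out = pairwise_class_ttests(_matrix(vals, design), design, ["p0", "p1"])
        assert not out.loc["p0", "testable"]
        assert not out.loc["p0", "pass_all"]
        assert out.loc["p1", "testable"]

    def test_bonferroni_is_more_conservative(self):
        design = _design(10)
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 30)) + np.repeat([0.0, 0.5, 1.0], 10)[None, :]
        m = _matrix(vals, design)
        probes = [f"p{i}" for i in range(20)]
        bh = pairwise_class_ttests(m, design, probes, adjust="BH")
        bf = pairwise_class_ttests(m, design, probes, adjust="bonferroni")
        bh_adj = bh.filter(like="adj_p_").to_numpy()
        bf_adj = bf.filter(like="adj_p_").to_numpy()
        assert (bf_adj >= bh_adj - 1e-12).all()


class TestModalityBias:
    def test_identical_modalities_give_half(self):
        design = _design(3)
        vals = np.arange(9.0 * 2).reshape(2, 9)
        g = _matrix(vals, design, "genotype")
        m = _matrix(vals.copy(), design, "methylation")
        out = gm.modality_bias_test(g, m, ["p0", "p1"], design)
        assert (out["p_value"] == 0.5).all()

    def test_offset_detected_in_every_class(self):
        design = _design(10)
        rng = np.random.default_rng(4)
        base = rng.normal(2.0, 0.3, size=(40, 30))
        g = _matrix(base, design, "genotype")
        m = _matrix(base - 0.4 + rng.normal(0, 0.05, size=base.shape), design, "methylation")
        probes = [f"p{i}" for i in range(40)]
        out = gm.modality_bias_test(g, m, probes, design)
        assert (out["genotype_mean"] > out["methylation_mean"]).all()
        assert (out["p_value"] < 1e-10).all()
        # oracle: scipy paired one-sided t on the flattened blood cells
        cols = design.samples_of("blood")
        gv = g.data.loc[probes, cols].to_numpy().ravel()
        mv = m.data.loc[probes, cols].to_numpy().ravel()
        t_ref, p_ref = stats.ttest_rel(gv, mv, alternative="greater")
        assert out.loc["blood", "p_value"] == pytest.approx(p_ref, rel=1e-9)
        assert out.loc["blood", "t_stat"] == pytest.approx(t_ref, rel=1e-9)

    def test_degenerate_input_errors(self):
        rows = [("b0", "S0", "blood"), ("n0", "S0", "normal"), ("t0", "S0", "tumor")]
        design = SampleDesign(
            pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue"]).set_index("sample_id")
        )
        g = _matrix(np.array([[1.0, 2.0, 3.0]]), design, "genotype")
        m = _matrix(np.array([[1.5, 2.5, 3.5]]), design, "methylation")
        with pytest.raises(ValueError, match="untestable|fewer"):
            gm.modality_bias_test(g, m, ["p0"], design)
        with pytest.raises(ValueError, match="empty"):
            gm.modality_bias_test(g, m, [], design)


class TestResamplingNull:
    def _paired(self, seed=0, offset=0.0):
        params = gm.SimulationParams(
            n_probes=600, n_signal=0, modality_offset=offset, seed=seed
        )
        g, m, d, _ = gm.generate_paired_dataset(params)
        return gm.substitute_missing_with_zero(g), gm.substitute_missing_with_zero(m), d

    def test_single_iteration_collapses_range(self):
        g, m, d = self._paired()
        out = gm.resampling_null(g, m, 20, 1, d, seed=1)
        assert (out["lower_bound"] == out["upper_bound"]).all()
        assert (out["n_iter"] == 1).all()

    def test_seed_reproducibility(self):
        g, m, d = self._paired()
        a = gm.resampling_null(g, m, 30, 50, d, seed=9)
        b = gm.resampling_null(g, m, 30, 50, d, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_parameter_errors(self):
        g, m, d = self._paired()
        with pytest.raises(ValueError, match="n_iter"):
            gm.resampling_null(g, m, 10, 0, d, seed=0)
        with pytest.raises(ValueError, match="n_snps"):
            gm.resampling_null(g, m, 10_000, 5, d, seed=0)
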