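import numpy as np
import pandas as pd
import pytest

from orthocoex import diffexpr
from orthocoex.diffexpr import (
    DEParams,
    bh_adjust,
    estimate_dispersion,
    nb_lrt_blocked,
    size_factors_median_of_ratios,
)
from orthocoex.tables_io import TableError

from conftest import counts_matrix, make_design


def bh_bruteforce(p):
    """BH by the definition: sort, p*m/i, cumulative min from the right."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestSizeFactors:
    def test_hand_computed_toy(self):
        m = counts_matrix([[100, 200], [10, 20], [40, 80]])
        sf = size_factors_median_of_ratios(m)
        np.testing.assert_allclose(sf.to_numpy(), [0.7071, 1.4142], atol=5e-5)

    def test_identical_columns_give_unit_factors(self):
        m = counts_matrix([[5, 5], [9, 9], [2, 2]])
        np.testing.assert_allclose(
            size_factors_median_of_ratios(m).to_numpy(), [1.0, 1.0])

    def test_single_sample_factor_is_one(self):
        m = counts_matrix([[5], [9]])
        np.testing.assert_allclose(size_factors_median_of_ratios(m).to_numpy(), [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_equivariance(self, seed):
        # size factors are defined up to a common scale: multiplying one
        # sample's counts by c multiplies its factor relative to every
        # other sample by exactly c
        rng = np.random.default_rng(seed)
        base = rng.integers(1, 200, size=(30, 4)).astype(float)
        sf = size_factors_median_of_ratios(counts_matrix(base))
        scaled = base.copy()
        scaled[:, 2] *= 3.0
        sf2 = size_factors_median_of_ratios(counts_matrix(scaled))
        before = sf.to_numpy() / sf.iloc[0]
        after = sf2.to_numpy() / sf2.iloc[0]
        expected = before.copy()
        expected[2] *= 3.0
        np.testing.assert_allclose(after, expected, rtol=1e-12)

    def test_no_reference_gene_is_error(self):
        m = counts_matrix([[0, 5], [5, 0]])
        with pytest.raises(TableError, match="pseudo-reference"):
            size_factors_median_of_ratios(m)


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(120):
            p = rng.random(int(rng.integers(1, 21)))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        design = make_design(["t1", "t2", "t3"], reps=4)
        mu = np.exp(rng.normal(4.0, 1.0, size=2000))
        y = rng.poisson(mu[:, None], size=(2000, 12)).astype(float)
        m = counts_matrix(y, sample_ids=design.sample_ids)
        disp = estimate_dispersion(m, design, shrink_weight=0.0)
        assert np.median(disp) < 0.05

    def test_overdispersed_cell_gives_positive_alpha(self):
        # one condition, mean 100, variance far above mean:
        # (var - mean)/mean^2 must be clearly positive
        design = make_design(["t1"], reps=6)
        y = np.array([[40.0, 60.0, 150.0, 160.0, 50.0, 140.0]])
        m = counts_matrix(y, sample_ids=design.sample_ids)
        unit_sf = pd.Series(1.0, index=design.sample_ids)
        disp = estimate_dispersion(m, design, size_factors=unit_sf,
                                   shrink_weight=0.0)
        assert disp.iloc[0] > 0.05

    def test_constant_counts_hit_floor(self):
        design = make_design(["t1", "t2"], reps=3)
        y = np.full((3, 6), 7.0)
        m = counts_matrix(y, sample_ids=design.sample_ids)
        disp = estimate_dispersion(m, design, shrink_weight=0.0)
        assert (disp == diffexpr.DISPERSION_FLOOR).all()

    def test_recovers_simulated_alpha(self):
        # alpha = 0.2, n = 30 (6 blocks x 5 timepoints): median in [0.1, 0.3]
        rng = np.random.default_rng(5)
        design = make_design([f"t{i}" for i in range(1, 6)],
                             blocks=[f"cv{b}" for b in range(1, 7)])
        mu = np.exp(rng.normal(4.0, 1.5, size=1000))[:, None] * np.ones(30)
        y = rng.negative_binomial(5, 1 / (1 + 0.2 * mu)).astype(float)
        m = counts_matrix(y, sample_ids=design.sample_ids)
        disp = estimate_dispersion(m, design, shrink_weight=0.0)
        assert 0.1 <= np.median(disp) <= 0.3


def _null_counts(seed, n_genes=2000):
    """NB counts with block and depth effects but no condition effect."""
    rng = np.random.default_rng(seed)
    design = make_design([f"t{i}" for i in range(1, 6)],
                         blocks=[f"cv{b}" for b in range(1, 7)])
    base = rng.normal(4.0, 1.5, size=n_genes)
    beff = rng.normal(0, 0.25, size=(n_genes, 6))
    bidx = np.repeat(np.arange(6), 5)
    depth = rng.lognormal(0, 0.2, size=30)
    mu = np.exp(base[:, None] + beff[:, bidx]) * depth[None, :]
    y = rng.negative_binomial(5, 1 / (1 + 0.2 * mu)).astype(float)
    return counts_matrix(y, sample_ids=design.sample_ids), design


class TestBlockedLRT:
    def test_null_size_near_nominal(self):
        m, design = _null_counts(seed=7)
        res = nb_lrt_blocked(m, design)
        tested = res[res.status == "tested"]
        frac = (tested.p_value < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_strong_shift_is_significant(self):
        rng = np.random.default_rng(2)
        design = make_design([f"t{i}" for i in range(1, 6)],
                             blocks=[f"cv{b}" for b in range(1, 7)])
        mu = np.exp(rng.normal(4.0, 1.0, size=300))[:, None] * np.ones(30)
        # gene 0: 10-fold mean shift between first and last conditions
        shift = np.ones(30)
        tvec = np.tile(np.arange(5), 6)
        shift[tvec >= 3] = 10.0
        mu[0] = 50.0 * shift
        y = rng.negative_binomial(5, 1 / (1 + 0.2 * mu)).astype(float)
        m = counts_matrix(y, sample_ids=design.sample_ids)
        res = nb_lrt_blocked(m, design).set_index("gene_id")
        assert res.loc["g0", "padj"] < 0.01

    def test_statuses_and_bh_universe(self):
        design = make_design(["t1", "t2"], reps=3)
        y = np.array([
            [0, 0, 0, 0, 0, 0],        # all_zero
            [1, 0, 0, 0, 1, 0],        # low_count (total < 10)
            [30, 28, 31, 29, 30, 33],  # tested
            [10, 12, 9, 11, 10, 12],   # tested
        ], dtype=float)
        m = counts_matrix(y, sample_ids=design.sample_ids)
        res = nb_lrt_blocked(m, design).set_index("gene_id")
        assert res.loc["g0", "status"] == "all_zero"
        assert res.loc["g1", "status"] == "low_count"
        assert np.isnan(res.loc["g0", "padj"]) and np.isnan(res.loc["g1", "padj"])
        tested = res[res.status == "tested"]
        # BH over the 2 tested genes only: padj = min(1, p * 2 / rank)
        np.testing.assert_allclose(
            np.sort(tested.padj), np.sort(bh_bruteforce(tested.p_value)), atol=1e-12)

    def test_lrt_statistic_nonnegative(self):
        m, design = _null_counts(seed=9, n_genes=300)
        res = nb_lrt_blocked(m, design)
        tested = res[res.status == "tested"]
        assert (tested.lrt_statistic >= 0).all()
        assert (tested.padj >= tested.p_value - 1e-12).all()
        assert (tested.df == 4).all()

    def test_non_integer_counts_rejected(self):
        design = make_design(["t1", "t2"], reps=2)
        m = counts_matrix([[1.5, 2, 3, 4]], sample_ids=design.sample_ids)
        with pytest.raises(TableError, match="integer"):
            nb_lrt_blocked(m, design)

    def test_confounded_block_rejected(self):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(4)],
            "species": ["x"] * 4,
            "condition": ["t1", "t1", "t2", "t2"],
            "condition_order": [1, 1, 2, 2],
            "block": ["cv1", "cv1", "cv2", "cv2"],
            "replicate": [1, 2, 1, 2],
        })
        df["condition_order"] = df["condition_order"].astype("Int64")
        from orthocoex.tables_io import SampleDesign
        design = SampleDesign(df)
        m = counts_matrix(np.full((2, 4), 20.0), sample_ids=list(df["sample_id"]))
        with pytest.raises(TableError, match="confounded"):
            nb_lrt_blocked(m, design)


class TestAgainstReferenceImplementation:
    def test_size_factors_match_pydeseq2(self):
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(11)
        y = rng.negative_binomial(5, 1 / (1 + 0.2 * 50.0), size=(80, 6)) + 1
        counts_df = pd.DataFrame(
            y.T, index=[f"s{j}" for j in range(6)],
            columns=[f"g{i}" for i in range(80)])
        meta = pd.DataFrame(
            {"condition": ["a", "a", "a", "b", "b", "b"]}, index=counts_df.index)
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts_df, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = size_factors_median_of_ratios(
            counts_matrix(y, sample_ids=list(counts_df.index)))
        np.testing.assert_allclose(
            ours.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-9)
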