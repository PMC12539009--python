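"""LD blocks, k-means haplotype calls, naming, group tests, stacking, trends."""

import re

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from staygreen import haplotypes as hap
from staygreen.errors import InfeasibleClusteringError, UndefinedLDError
from staygreen.types import GenotypeMatrix

CODE_GRAMMAR = re.compile(r"^[Mm][ACGT]v*$")


def make_geno(doses, pos=None, chrom="1A", major="G", minor="C"):
    doses = np.asarray(doses, dtype=float)
    n, m = doses.shape
    markers = pd.Index([f"m{i:03d}" for i in range(m)], name="marker")
    mm = pd.DataFrame({"chrom": chrom, "pos": pos if pos is not None
                       else np.arange(1, m + 1) * 100_000,
                       "major": major, "minor": minor}, index=markers)
    idx = pd.Index([f"cv{i:03d}" for i in range(n)], name="cultivar")
    return GenotypeMatrix(pd.DataFrame(doses, index=idx, columns=markers), mm)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_r2_identity_flip_symmetry(rng):
    a = 2.0 * (rng.random(100) < 0.3)
    b = 2.0 - a
    assert hap.ld_r2(a, a) == pytest.approx(1.0)
    assert hap.ld_r2(a, b) == pytest.approx(1.0)     # allele relabelling
    c = 2.0 * (rng.random(100) < 0.4)
    assert hap.ld_r2(a, c) == pytest.approx(hap.ld_r2(c, a))
    assert hap.ld_r2(a, c) == pytest.approx(np.corrcoef(a, c)[0, 1] ** 2)


def test_ld_r2_null_expectation(rng):
    n = 221
    vals = []
    for _ in range(1000):
        a = 2.0 * (rng.random(n) < 0.3)
        b = 2.0 * (rng.random(n) < 0.3)
        vals.append(hap.ld_r2(a, b))
    assert np.mean(vals) < 0.02          # null expectation ~ 1/n


def test_ld_r2_errors(rng):
    with pytest.raises(UndefinedLDError):
        hap.ld_r2(np.zeros(50), 2.0 * (rng.random(50) < 0.5))
    with pytest.raises(UndefinedLDError):
        hap.ld_r2(np.ones(5), np.ones(5))


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------

def _chain_panel(rng, focal_r2_right, n=400):
    """Focal marker at index 0 with right-hand neighbours of given focal r2."""
    from staygreen.synth import _flip_rate_for_r2
    p = 0.4
    focal = (rng.random(n) < p).astype(float)
    cols = [2 * focal]
    for r2 in focal_r2_right:
        e = _flip_rate_for_r2(p, r2 + 0.03)   # aim slightly above the target
        flip = rng.random(n) < e
        cols.append(2 * np.where(flip, 1 - focal, focal))
    return make_geno(np.column_stack(cols))


def test_collect_block_stops_at_first_failure(rng):
    geno = _chain_panel(rng, [0.9, 0.8, 0.2, 0.9])
    members, span = hap.collect_block("m000", geno, r2_min=0.7)
    # first two right neighbours included, extension stops at the weak third
    # even though the fourth is again in high LD
    assert members == ["m000", "m001", "m002"]
    assert span == (0.1, 0.3)


def test_collect_block_singleton_when_no_neighbour_qualifies(rng):
    geno = _chain_panel(rng, [0.1, 0.1])
    members, span = hap.collect_block("m000", geno, r2_min=0.7)
    assert members == ["m000"]
    assert span == (0.1, 0.1)


def test_collect_block_symmetric_layout(rng):
    from staygreen.synth import _flip_rate_for_r2
    n, p = 500, 0.4
    focal = (rng.random(n) < p).astype(float)
    e = _flip_rate_for_r2(p, 0.92)
    def mate():
        return 2 * np.where(rng.random(n) < e, 1 - focal, focal)
    doses = np.column_stack([mate(), mate(), 2 * focal, mate(), mate()])
    geno = make_geno(doses)
    members, _ = hap.collect_block("m002", geno, r2_min=0.7)
    assert members == ["m000", "m001", "m002", "m003", "m004"]


def test_collect_block_gap_tolerance(rng):
    geno = _chain_panel(rng, [0.9, 0.2, 0.9])
    strict, _ = hap.collect_block("m000", geno, r2_min=0.7, max_gap=0)
    lenient, _ = hap.collect_block("m000", geno, r2_min=0.7, max_gap=1)
    assert strict == ["m000", "m001"]
    assert lenient == ["m000", "m001", "m003"]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _two_pattern_panel(n_a=10, n_b=10, width=6, noise=0.0, rng=None):
    a = np.tile([0.0] * width, (n_a, 1))
    b = np.tile([2.0] * width, (n_b, 1))
    X = np.vstack([a, b])
    if noise > 0:
        flip = rng.random(X.shape) < noise
        X = np.where(flip, 2 - X, X)
    return make_geno(X), np.array([0] * n_a + [1] * n_b)


def test_cluster_recovers_planted_patterns_exactly():
    geno, truth = _two_pattern_panel()
    call = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers),
                                  seed=3)
    assert adjusted_rand_score(truth, call.assignments.values) == 1.0
    assert len(call.sizes) == 2


def test_cluster_minority_below_min_members_absorbed():
    geno, _ = _two_pattern_panel(n_a=12, n_b=3)
    call = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers),
                                  seed=3)
    assert call.sizes == {0: 15}


def test_cluster_noise_robustness(rng):
    # k_max matches the planted two-pattern diversity; at 10% dose-flip
    # noise the partition still recovers the truth
    geno, truth = _two_pattern_panel(n_a=60, n_b=40, noise=0.10, rng=rng)
    call = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers),
                                  k_max=2, seed=3)
    assert adjusted_rand_score(truth, call.assignments.values) >= 0.8
    assert min(call.sizes.values()) >= 5


def test_cluster_default_kmax_splits_noisy_variants(rng):
    # with the default k_max the same noisy block yields additional variant
    # clusters, every one of which still satisfies the membership floor
    geno, truth = _two_pattern_panel(n_a=60, n_b=40, noise=0.10, rng=rng)
    call = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers),
                                  seed=3)
    assert min(call.sizes.values()) >= 5


def test_cluster_determinism_and_min_members():
    geno, _ = _two_pattern_panel(n_a=30, n_b=30)
    a = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers), seed=7)
    b = hap.cluster_haplotypes(geno, "m000", members=list(geno.markers), seed=7)
    pd.testing.assert_series_equal(a.assignments, b.assignments)
    with pytest.raises(InfeasibleClusteringError):
        small, _ = _two_pattern_panel(n_a=2, n_b=2)
        hap.cluster_haplotypes(small, "m000", members=list(small.markers))


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def _named_call(sizes_and_doses, major="G", minor="C"):
    doses = np.concatenate([np.full(n, d) for n, d in sizes_and_doses])
    geno = make_geno(doses[:, None], major=major, minor=minor)
    labels = np.concatenate([np.full(n, i) for i, (n, _) in
                             enumerate(sizes_and_doses)])
    call = hap.HaplotypeCall(
        focal="m000", members=("m000",), span_mbp=(0.1, 0.1),
        assignments=pd.Series(labels, index=geno.cultivars),
        sizes={i: n for i, (n, _) in enumerate(sizes_and_doses)})
    return hap.name_haplotypes(call, geno), call


def test_naming_major_and_minor_codes():
    named, _ = _named_call([(120, 0.0), (30, 2.0)])
    assert set(named.codes.values()) == {"MG", "mC"}


def test_naming_variant_suffix_by_descending_size():
    # two clusters both modal-major: larger keeps the bare code
    named, call = _named_call([(40, 0.0), (120, 0.0)])
    assert named.codes[1] == "MG" and named.codes[0] == "MGv"


def test_naming_single_cluster_and_grammar():
    named, _ = _named_call([(25, 0.0)], major="T", minor="A")
    assert named.codes == {0: "MT"}
    for code in named.codes.values():
        assert CODE_GRAMMAR.match(code)


def test_naming_tie_falls_to_major_with_flag():
    named, _ = _named_call([(10, 1.0)])    # modal minor frequency exactly 0.5
    assert named.codes[0] == "MG" and named.tie_flag


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def test_effect_test_student_branch_power(rng):
    y = pd.Series(np.r_[rng.normal(0, 0.1, 50), rng.normal(1, 0.1, 50)])
    g = pd.Series(np.repeat(["a", "b"], 50))
    rep = hap.haplotype_effect_test(y, g)
    assert rep.test_used == "student_t"
    assert rep.p <= 0.001
    assert rep.letters["a"] != rep.letters["b"]


def test_effect_test_welch_branch_on_unequal_variance(rng):
    y = pd.Series(np.r_[rng.normal(0, 0.1, 60), rng.normal(0.2, 1.0, 60)])
    g = pd.Series(np.repeat(["a", "b"], 60))
    rep = hap.haplotype_effect_test(y, g)
    assert rep.test_used == "welch_t"


def test_effect_test_anova_tukey_branch(rng):
    y = pd.Series(np.r_[rng.normal(0, 0.3, 40), rng.normal(1, 0.3, 40),
                        rng.normal(2, 0.3, 40)])
    g = pd.Series(np.repeat(["a", "b", "c"], 40))
    rep = hap.haplotype_effect_test(y, g)
    assert rep.test_used == "anova_tukey"
    assert rep.p < 1e-6
    assert len(set(rep.letters.values())) == 3
    assert len(rep.pairwise) == 3


def test_effect_test_kruskal_branch_on_heteroskedastic(rng):
    y = pd.Series(np.r_[rng.normal(0, 0.05, 50), rng.normal(0.5, 1.5, 50),
                        rng.normal(1, 0.05, 50)])
    g = pd.Series(np.repeat(["a", "b", "c"], 50))
    rep = hap.haplotype_effect_test(y, g)
    assert rep.test_used == "kruskal_wilcoxon"


def test_effect_test_null_levels_honest(rng):
    rejections = 0
    for _ in range(100):
        y = pd.Series(rng.normal(size=60))
        g = pd.Series(np.repeat(["a", "b", "c"], 20))
        rep = hap.haplotype_effect_test(y, g)
        rejections += rep.p < 0.05
    assert rejections <= 10


def test_effect_test_constant_group_forces_nonparametric(rng):
    y = pd.Series(np.r_[np.full(20, 1.0), rng.normal(2, 0.5, 20)])
    g = pd.Series(np.repeat(["a", "b"], 20))
    rep = hap.haplotype_effect_test(y, g)
    assert rep.test_used == "welch_t"
    assert "nonparametric" in rep.note


# ---------------------------------------------------------------------------
# stacking, carriers, trends
# ---------------------------------------------------------------------------

def test_stacking_labels():
    flags = pd.DataFrame({"A": [True, True, False, True],
                          "B": [False, True, False, True],
                          "C": [False, False, False, True]},
                         index=["c1", "c2", "c3", "c4"])
    labels = hap.stacking_classes(flags, locus_order=["A", "B", "C"])
    assert labels.loc["c1"] == "F-U-U"
    assert labels.loc["c2"] == "F-F-U"
    assert labels.loc["c3"] == "U-U-U"
    assert labels.loc["c4"] == "F-F-F"


def test_stacking_excludes_uncalled():
    flags = pd.DataFrame({"A": [True, np.nan], "B": [True, True]},
                         index=["c1", "c2"])
    labels = hap.stacking_classes(flags)
    assert list(labels.index) == ["c1"]


@pytest.mark.parametrize("carry,expected", [(3, 75.0), (0, 0.0), (4, 100.0)])
def test_carrier_fraction(carry, expected):
    sg = pd.Index([f"c{i}" for i in range(4)])
    flags = pd.DataFrame({"A": [i < carry for i in range(4)],
                          "B": [i < carry for i in range(4)]}, index=sg)
    assert hap.carrier_fraction(sg, flags) == pytest.approx(expected)


def _decade_panel(freqs, n_per=40):
    doses, decades = [], []
    for dec, f in freqs.items():
        k = int(round(f * n_per))
        doses.extend([2.0] * k + [0.0] * (n_per - k))
        decades.extend([dec] * n_per)
    geno = make_geno(np.asarray(doses)[:, None])
    geno.metadata = pd.DataFrame({"decade": decades, "origin": "DE"},
                                 index=geno.cultivars)
    return geno


def test_allele_frequency_simple_and_single_decade():
    geno = _decade_panel({1990: 0.5}, n_per=4)
    table, trend = hap.allele_frequency_trend(geno, "m000")
    assert table.loc[0, "frequency"] == pytest.approx(0.5)
    assert trend == {}                        # no trend test on one decade


def test_allele_frequency_planted_ramp_detected():
    freqs = {1970: 0.05, 1980: 0.15, 1990: 0.30, 2000: 0.45, 2010: 0.60}
    geno = _decade_panel(freqs, n_per=100)
    table, trend = hap.allele_frequency_trend(geno, "m000", origin="DE")
    assert list(table["frequency"]) == sorted(table["frequency"])
    assert trend["tau"] > 0 and trend["p"] < 0.05
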