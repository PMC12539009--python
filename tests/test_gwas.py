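"""Marker filtering, PCA, association scans, multiple testing, PVE."""

import numpy as np
import pandas as pd
import pytest

from staygreen import gwas
from staygreen.errors import EmptyPanelError, MappingError, RankError
from staygreen.types import GenotypeMatrix


def make_geno(doses: np.ndarray, chrom=None, pos=None, cultivars=None):
    n, m = doses.shape
    markers = pd.Index([f"m{i:04d}" for i in range(m)], name="marker")
    mm = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1A"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "major": "A", "minor": "G"}, index=markers)
    idx = pd.Index(cultivars if cultivars is not None
                   else [f"cv{i:04d}" for i in range(n)], name="cultivar")
    return GenotypeMatrix(pd.DataFrame(doses, index=idx, columns=markers), mm)


def null_panel(rng, n=200, m=2000, maf_range=(0.1, 0.5)):
    p = rng.uniform(*maf_range, size=m)
    return make_geno(2.0 * (rng.random((n, m)) < p))


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

def test_filter_maf_and_missing_boundaries():
    n = 100
    doses = np.zeros((n, 4))
    doses[:2, 0] = 2.0                 # MAF 0.02 -> discarded ("below 3%")
    doses[:3, 1] = 2.0                 # MAF 0.03 -> retained (boundary kept)
    doses[:30, 2] = 2.0
    doses[:30, 3] = 2.0
    doses[:6, 2] = np.nan              # 6% missing -> discarded
    doses[:5, 3] = np.nan              # 5% missing -> retained
    geno = make_geno(doses)
    filtered, report = gwas.filter_markers(geno)
    assert list(filtered.markers) == ["m0001", "m0003"]
    assert report["removed_low_maf"] == 1
    assert report["removed_missing"] == 1


def test_filter_monomorphic_and_empty():
    geno = make_geno(np.zeros((50, 3)))
    with pytest.raises(EmptyPanelError):
        gwas.filter_markers(geno)
    doses = np.zeros((50, 2))
    doses[:25, 1] = 2.0
    filtered, report = gwas.filter_markers(make_geno(doses))
    assert report["removed_monomorphic"] == 1
    assert list(filtered.markers) == ["m0001"]


def test_impute_mean_and_conservation():
    doses = np.array([[0.0, 0.0], [2.0, 2.0], [np.nan, 2.0]])
    geno = make_geno(doses)
    observed_means = geno.doses.mean()
    complete, n_imputed = gwas.impute_missing(geno)
    assert n_imputed == 1
    assert complete.doses.iloc[2, 0] == pytest.approx(1.0)
    pd.testing.assert_series_equal(complete.doses.mean(), observed_means)
    # no missing -> identity
    same, n0 = gwas.impute_missing(complete)
    assert n0 == 0
    pd.testing.assert_frame_equal(same.doses, complete.doses)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix(rng):
    base = 2.0 * (rng.random(40) < 0.4)
    geno = make_geno(np.column_stack([base] * 6))
    scores, frac = gwas.pca_markers(geno, k=1)
    assert frac.iloc[0] == pytest.approx(1.0)
    with pytest.raises(RankError):
        gwas.pca_markers(geno, k=3)


def test_pca_matches_svd_oracle(rng):
    geno = null_panel(rng, n=60, m=120)
    scores, frac = gwas.pca_markers(geno, k=3)
    X = geno.doses.to_numpy() - geno.doses.to_numpy().mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    expected = U[:, :3] * s[:3]
    for j in range(3):
        sign = np.sign(np.dot(scores.iloc[:, j], expected[:, j]))
        np.testing.assert_allclose(scores.iloc[:, j], sign * expected[:, j],
                                   atol=1e-8)
    assert np.all(np.diff(frac.values) <= 1e-12) and frac.sum() <= 1 + 1e-12


def test_pca_separates_planted_subpopulations(rng):
    n, m = 120, 300
    group = np.repeat([0, 1], n // 2)
    p = np.where(group[:, None] == 0, rng.uniform(0.1, 0.3, m),
                 rng.uniform(0.5, 0.8, m))
    geno = make_geno(2.0 * (rng.random((n, m)) < p))
    scores, _ = gwas.pca_markers(geno, k=2)
    r = np.corrcoef(scores["PC1"], group)[0, 1]
    assert abs(r) > 0.9


# ---------------------------------------------------------------------------
# single-marker scan
# ---------------------------------------------------------------------------

def test_scan_recovers_exact_effect(rng):
    geno = null_panel(rng, n=80, m=50)
    beta = -0.02
    pheno = pd.Series(beta * geno.doses["m0007"].to_numpy(),
                      index=geno.cultivars)
    res = gwas.single_marker_scan(pheno, geno)
    assert res.table.loc["m0007", "effect"] == pytest.approx(beta, abs=1e-10)
    assert res.table.loc["m0007", "p"] < 1e-12
    assert res.table["p"].idxmin() == "m0007"


def test_scan_null_type_i_error_calibrated(rng):
    geno = null_panel(rng, n=200, m=2000)
    pheno = pd.Series(rng.normal(size=200), index=geno.cultivars)
    res = gwas.single_marker_scan(pheno, geno)
    p = res.table["p"].to_numpy()
    for alpha in (0.05, 0.01):
        frac = float(np.mean(p < alpha))
        se = np.sqrt(alpha * (1 - alpha) / len(p))
        assert abs(frac - alpha) < 3 * se


def test_scan_structure_confounding_attenuated_by_pcs(rng):
    n, m = 200, 150
    group = np.repeat([0.0, 1.0], n // 2)
    p = np.where(group[:, None] == 0, 0.15, 0.7)
    doses = 2.0 * (rng.random((n, m)) < p)
    doses[:, 0] = 2.0 * group            # marker = group indicator
    geno = make_geno(doses)
    pheno = pd.Series(0.5 * group + rng.normal(0, 0.3, n), index=geno.cultivars)
    naive = gwas.single_marker_scan(pheno, geno)
    pcs, _ = gwas.pca_markers(geno, k=3)
    corrected = gwas.single_marker_scan(pheno, geno, pcs)
    eff_naive = abs(naive.table.loc["m0000", "effect"])
    eff_corr = corrected.table.loc["m0000", "effect"]
    assert np.isnan(eff_corr) or abs(eff_corr) < eff_naive


def test_scan_order_invariance(rng):
    geno = null_panel(rng, n=60, m=40)
    pheno = pd.Series(rng.normal(size=60), index=geno.cultivars)
    base = gwas.single_marker_scan(pheno, geno)
    perm_m = rng.permutation(geno.markers)
    perm_c = rng.permutation(geno.cultivars)
    shuffled = GenotypeMatrix(geno.doses.loc[perm_c, perm_m],
                              geno.marker_map.loc[perm_m])
    other = gwas.single_marker_scan(pheno, shuffled)
    pd.testing.assert_frame_equal(base.table.sort_index(),
                                  other.table.sort_index())


def test_scan_collinear_marker_flagged(rng):
    geno = null_panel(rng, n=60, m=20)
    cov = pd.DataFrame({"c1": geno.doses["m0003"].to_numpy()},
                       index=geno.cultivars)
    pheno = pd.Series(rng.normal(size=60), index=geno.cultivars)
    res = gwas.single_marker_scan(pheno, geno, cov)
    assert res.table.loc["m0003", "collinear"]
    assert np.isnan(res.table.loc["m0003", "p"])


# ---------------------------------------------------------------------------
# multilocus scan
# ---------------------------------------------------------------------------

def _ld_block_panel(rng, n=220, m=300, causal_idx=(40,), r2_mates=3):
    p = rng.uniform(0.2, 0.5, size=m)
    doses = 2.0 * (rng.random((n, m)) < p)
    for c in causal_idx:
        for j in range(1, r2_mates + 1):
            flip = rng.random(n) < 0.02
            doses[:, c + j] = np.where(flip, 2 - doses[:, c], doses[:, c])
    return make_geno(doses)


def test_multilocus_recovers_single_planted_locus(rng):
    geno = _ld_block_panel(rng, causal_idx=(40,))
    dose = geno.doses["m0040"].to_numpy()
    noise_sd = np.sqrt(np.var(dose) * 4)     # planted signal ~20% of variance
    pheno = pd.Series(-1.0 * dose + rng.normal(0, noise_sd, len(dose)),
                      index=geno.cultivars)
    res = gwas.multilocus_scan(pheno, geno)
    block = {f"m{40 + j:04d}" for j in range(4)}
    assert len(res.pseudo_qtns) == 1
    assert res.pseudo_qtns[0] in block
    assert res.table["p"].idxmin() in block


def test_multilocus_recovers_two_independent_loci(rng):
    geno = _ld_block_panel(rng, causal_idx=(40, 200))
    d1 = geno.doses["m0040"].to_numpy()
    d2 = geno.doses["m0200"].to_numpy()
    pheno = pd.Series(-0.8 * d1 + 0.8 * d2 + rng.normal(0, 1.0, len(d1)),
                      index=geno.cultivars)
    res = gwas.multilocus_scan(pheno, geno, max_iter=4)
    # both planted blocks are picked up within the first two iterations
    first_two = set(res.pseudo_qtns[:2])
    assert any(m in first_two for m in (f"m{40+j:04d}" for j in range(4)))
    assert any(m in first_two for m in (f"m{200+j:04d}" for j in range(4)))


def test_multilocus_null_rarely_selects(rng):
    empties = 0
    for _ in range(100):
        geno = null_panel(rng, n=120, m=250)
        pheno = pd.Series(rng.normal(size=120), index=geno.cultivars)
        res = gwas.multilocus_scan(pheno, geno, max_iter=3)
        empties += len(res.pseudo_qtns) == 0
    assert empties >= 95


# ---------------------------------------------------------------------------
# multiple testing and PVE
# ---------------------------------------------------------------------------

def test_bonferroni_threshold():
    out = gwas.multiple_testing(np.full(20, 0.5), alpha=0.05)
    assert out["bonferroni_threshold"] == pytest.approx(0.0025)


def brute_force_bh(p, alpha):
    """Step-up definition evaluated literally over all k."""
    m = len(p)
    order = np.argsort(p)
    sorted_p = p[order]
    kmax = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            kmax = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:kmax]] = True
    adj = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_full = np.empty(m)
    adj_full[order] = np.minimum(adj, 1.0)
    return flags, adj_full


def test_bh_matches_brute_force_on_random_vectors(rng):
    for _ in range(1000):
        m = rng.integers(1, 60)
        p = rng.uniform(1e-12, 1.0, size=m)
        out = gwas.multiple_testing(p, alpha=0.05)
        flags, adj = brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(out["fdr_flags"], flags)
        np.testing.assert_allclose(out["p_bh"], adj, atol=1e-12)


def test_multiple_testing_degenerate_inputs():
    out = gwas.multiple_testing(np.ones(10))
    assert not out["fdr_flags"].any()
    with pytest.raises(ValueError):
        gwas.multiple_testing(np.array([]))
    with pytest.raises(ValueError):
        gwas.multiple_testing(np.array([0.0, 0.5]))


def test_pve_formula_cases():
    assert gwas.pve(1.0, 0.5, 2.0) == pytest.approx(25.0)
    assert gwas.pve(1.0, 0.0, 2.0) == 0.0
    assert gwas.pve(100.0, 0.5, 1.0) == 100.0          # capped
    with pytest.raises(ValueError):
        gwas.pve(1.0, 0.5, 0.0)
    with pytest.raises(ValueError):
        gwas.pve(1.0, 0.7, 1.0)


def test_pve_matches_r2_on_hardy_weinberg_panel(rng):
    # with heterozygote-bearing (HWE) doses the 2*maf*(1-maf) additive
    # variance equals the dose variance, so PVE ~ regression R^2
    n = 4000
    p = 0.3
    dose = rng.binomial(2, p, size=n).astype(float)
    beta = 0.5
    y = beta * dose + rng.normal(0, 1.0, n)
    b_hat = np.cov(dose, y)[0, 1] / np.var(dose)
    r2 = np.corrcoef(dose, y)[0, 1] ** 2
    est = gwas.pve(b_hat, min(p, 1 - p), float(np.var(y)))
    assert est == pytest.approx(100 * r2, abs=2.0)


# ---------------------------------------------------------------------------
# Manhattan table
# ---------------------------------------------------------------------------

def test_manhattan_ordering_and_thresholds(rng):
    geno = make_geno(2.0 * (rng.random((40, 4)) < 0.4),
                     chrom=["2B", "1A", "2B", "1A"], pos=[5, 10, 1, 2])
    pheno = pd.Series(rng.normal(size=40), index=geno.cultivars)
    res = gwas.single_marker_scan(pheno, geno)
    tab = gwas.manhattan_table(res, geno.marker_map)
    assert list(tab["chrom"]) == ["1A", "1A", "2B", "2B"]
    assert tab["cum_pos"].is_monotonic_increasing
    assert (tab["bonferroni_line"] == -np.log10(res.bonferroni_threshold)).all()
    # unmapped marker raises
    with pytest.raises(MappingError):
        gwas.manhattan_table(res, geno.marker_map.iloc[:2])


def test_manhattan_constant_p_gives_constant_column(rng):
    geno = make_geno(2.0 * (rng.random((30, 3)) < 0.5))
    res = gwas.single_marker_scan(pd.Series(rng.normal(size=30),
                                            index=geno.cultivars), geno)
    res.table["p"] = 0.5
    tab = gwas.manhattan_table(res, geno.marker_map)
    assert tab["neg_log10_p"].nunique() == 1
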