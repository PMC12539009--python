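"""Marker filtering, structure correction and association scans.

The phenotype throughout is the vector of per-cultivar genotype effects on
the transformed senescence index (sqrt(PSRI + 10) scale).  Markers are
filtered at MAF >= 3% and missingness <= 5% (the stated discard rules are
"below 3%" and "more than 5%", so the boundaries are retained), missing
doses are mean-imputed, and the first principal components of the centred
dose matrix serve as covariates against population stratification.

Two scans are provided: a single-marker ordinary-least-squares scan, and a
simplified multi-locus iterative-conditioning scan in the FarmCPU/BLINK
spirit — repeatedly add the most significant Bonferroni-passing marker not
in LD (r^2 > 0.7) with an already selected pseudo-QTN to the covariate set,
rescan, and finally re-test each selected pseudo-QTN by leave-one-out.  No
kinship matrix is used, matching the covariate structure of the original
analysis.  Multiple-testing control is Bonferroni plus Benjamini-Hochberg
at a 5% FDR; per-marker PVE is 100 * 2*MAF*(1-MAF)*beta^2 / Var(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyPanelError, MappingError, RankError
from .types import GenotypeMatrix

DEFAULT_MAF_MIN = 0.03
DEFAULT_MISSING_MAX = 0.05


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

def filter_markers(geno: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN,
                   missing_max: float = DEFAULT_MISSING_MAX):
    """Discard monomorphic, low-MAF and high-missingness markers.

    Retains markers with MAF >= ``maf_min`` *and* missing rate <=
    ``missing_max`` that are polymorphic.  Returns (filtered matrix, report
    dict with per-rule removal counts).
    """
    if geno.n_markers == 0:
        raise EmptyPanelError("empty genotype matrix")
    maf = geno.maf()
    miss = geno.missing_rate()
    mono = maf == 0
    low_maf = (~mono) & (maf < maf_min)
    high_miss = miss > missing_max
    keep = ~(mono | low_maf | high_miss)
    report = {
        "n_input": int(geno.n_markers),
        "removed_monomorphic": int(mono.sum()),
        "removed_low_maf": int((low_maf & ~high_miss).sum()),
        "removed_missing": int(high_miss.sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise EmptyPanelError("all markers removed by filtering")
    return geno.subset_markers(geno.markers[keep]), report


def impute_missing(geno: GenotypeMatrix):
    """Replace missing doses by the per-marker mean of observed doses."""
    n_missing = int(geno.doses.isna().sum().sum())
    filled = geno.doses.fillna(geno.doses.mean(axis=0))
    out = GenotypeMatrix(filled, geno.marker_map, geno.metadata)
    if hasattr(geno, "causal_blocks"):
        out.causal_blocks = geno.causal_blocks
    return out, n_missing


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

def pca_markers(geno: GenotypeMatrix, k: int = 3, scale: bool = False):
    """PC scores of the centred dose matrix plus variance fractions.

    Scores are computed by singular value decomposition of the centred
    (optionally unit-scaled) dose matrix; variance fractions are relative to
    the total marker variance, nonincreasing and summing to <= 1.
    """
    X = geno.doses.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("complete matrix required; impute first")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    rank = np.linalg.matrix_rank(X)
    if k >= rank + 1 or k > min(X.shape):
        raise RankError(f"k={k} exceeds matrix rank {rank}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    var_frac = (s ** 2 / np.sum(s ** 2))[:k]
    cols = [f"PC{i+1}" for i in range(k)]
    return (pd.DataFrame(scores, index=geno.cultivars, columns=cols),
            pd.Series(var_frac, index=cols, name="variance_fraction"))


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker association table plus scan metadata."""

    table: pd.DataFrame
    alpha: float
    bonferroni_threshold: float
    n: int
    pseudo_qtns: list | None = None


def _residualise(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def single_marker_scan(pheno: pd.Series, geno: GenotypeMatrix,
                       covariates: pd.DataFrame | None = None,
                       alpha: float = 0.05) -> ScanResult:
    """OLS scan: phenotype ~ dose + covariates, one marker at a time.

    Effect is the dose coefficient with its t-test p-value; Bonferroni and
    BH/FDR flags and PVE are attached.  Markers collinear with the
    covariates are flagged and carry missing p-values.  Results are
    invariant to marker and cultivar ordering.
    """
    common = pheno.index.intersection(geno.cultivars)
    if len(common) < 10:
        raise ValueError("phenotype and genotypes overlap in < 10 cultivars")
    common = common.sort_values()
    y = pheno.loc[common].to_numpy(dtype=float)
    G = geno.doses.loc[common].to_numpy(dtype=float)
    if np.isnan(G).any():
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    n = len(common)
    X0 = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        X0 = np.column_stack([X0, covariates.loc[common].to_numpy(dtype=float)])
    Q, _ = np.linalg.qr(X0)
    y_r = _residualise(y[:, None], Q)[:, 0]
    G_r = _residualise(G, Q)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    dof = n - X0.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_r.T @ y_r) / gg
        rss = np.maximum(y_r @ y_r - beta ** 2 * gg, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tval = beta / se
    collinear = gg <= 1e-10 * n
    pvals = 2.0 * stats.t.sf(np.abs(tval), dof)
    pvals = np.where(collinear, np.nan, np.clip(pvals, np.finfo(float).tiny, 1.0))
    beta = np.where(collinear, np.nan, beta)
    se = np.where(collinear, np.nan, se)

    maf = geno.maf().to_numpy()
    var_y = float(np.var(y))
    pve_vals = np.where(np.isnan(beta), np.nan,
                        pve(np.nan_to_num(beta), maf, var_y))
    table = pd.DataFrame({
        "marker": geno.markers, "effect": beta, "se": se, "p": pvals,
        "collinear": collinear, "pve": pve_vals,
    }).set_index("marker")
    mt = multiple_testing(table["p"].dropna().to_numpy(), alpha=alpha)
    table["p_bh"] = np.nan
    table.loc[table["p"].dropna().index, "p_bh"] = mt["p_bh"]
    table["bonferroni_significant"] = table["p"] < mt["bonferroni_threshold"]
    table["fdr_significant"] = False
    table.loc[table["p"].dropna().index, "fdr_significant"] = mt["fdr_flags"]
    return ScanResult(table=table, alpha=alpha,
                      bonferroni_threshold=mt["bonferroni_threshold"], n=n)


def multilocus_scan(pheno: pd.Series, geno: GenotypeMatrix,
                    covariates: pd.DataFrame | None = None, alpha: float = 0.05,
                    max_iter: int = 10, r2_exclude: float = 0.7) -> ScanResult:
    """Iterative-conditioning multi-locus scan with pseudo-QTN selection.

    Each round scans all markers with the structure covariates plus the
    doses of already-selected pseudo-QTNs, then adds the most significant
    marker passing the Bonferroni threshold that is not in LD (r^2 >
    ``r2_exclude``) with any selected pseudo-QTN.  Iteration stops when no
    marker qualifies (or at ``max_iter``, with a warning flag).  Final
    p-values come from the last scan, except that each selected pseudo-QTN
    is re-tested leave-one-out (conditioning on the other pseudo-QTNs only).
    """
    selected: list[str] = []
    converged = False
    last = None
    for _ in range(max_iter):
        covs = _augment_covariates(covariates, geno, selected, pheno.index)
        last = single_marker_scan(pheno, geno, covs, alpha=alpha)
        tab = last.table
        cand = tab[(tab["p"] < last.bonferroni_threshold) &
                   (~tab.index.isin(selected))].sort_values("p")
        new = None
        for m in cand.index:
            if all(_r2(geno, m, s) <= r2_exclude for s in selected):
                new = m
                break
        if new is None:
            converged = True
            break
        selected.append(new)
    if last is None:
        covs = _augment_covariates(covariates, geno, selected, pheno.index)
        last = single_marker_scan(pheno, geno, covs, alpha=alpha)
    table = last.table.copy()
    # leave-one-out re-test of each pseudo-QTN
    for m in selected:
        others = [s for s in selected if s != m]
        covs = _augment_covariates(covariates, geno, others, pheno.index)
        res = single_marker_scan(pheno, geno.subset_markers([m]), covs,
                                 alpha=alpha)
        for col in ("effect", "se", "p", "pve"):
            table.loc[m, col] = res.table.loc[m, col]
    mt = multiple_testing(table["p"].dropna().to_numpy(), alpha=alpha)
    table.loc[table["p"].dropna().index, "p_bh"] = mt["p_bh"]
    table["bonferroni_significant"] = table["p"] < mt["bonferroni_threshold"]
    table.loc[table["p"].dropna().index, "fdr_significant"] = mt["fdr_flags"]
    out = ScanResult(table=table, alpha=alpha,
                     bonferroni_threshold=mt["bonferroni_threshold"],
                     n=last.n, pseudo_qtns=selected)
    out.converged = converged
    return out


def _augment_covariates(covariates, geno, selected, pheno_index):
    parts = []
    if covariates is not None:
        parts.append(covariates)
    if selected:
        parts.append(geno.doses[selected])
    if not parts:
        return None
    return pd.concat(parts, axis=1).reindex(
        pheno_index.intersection(geno.cultivars))


def _r2(geno: GenotypeMatrix, a: str, b: str) -> float:
    x = geno.doses[a].to_numpy(dtype=float)
    y = geno.doses[b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return 1.0
    return float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)


# ---------------------------------------------------------------------------
# multiple testing and effect summaries
# ---------------------------------------------------------------------------

def multiple_testing(pvalues: np.ndarray, alpha: float = 0.05) -> dict:
    """Bonferroni threshold plus Benjamini-Hochberg step-up control.

    Returns the Bonferroni threshold alpha/m, the monotone BH-adjusted
    p-values and the 5%-FDR (or ``alpha``) step-up flags.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    flags, p_bh, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {"bonferroni_threshold": alpha / m, "p_bh": p_bh, "fdr_flags": flags,
            "alpha": alpha, "m": m}


def pve(effect, maf, phenotype_variance: float):
    """Percent phenotypic variance explained: 100*2*maf*(1-maf)*beta^2/Var(y).

    The additive-variance convention assumes Hardy-Weinberg dose variance
    2*maf*(1-maf); values are capped at 100.
    """
    if phenotype_variance <= 0:
        raise ValueError("phenotype variance must be positive")
    maf_arr = np.asarray(maf, dtype=float)
    if np.any((maf_arr < 0) | (maf_arr > 0.5)):
        raise ValueError("MAF must lie in [0, 0.5]")
    val = 100.0 * 2.0 * maf_arr * (1.0 - maf_arr) * np.asarray(effect) ** 2 \
        / phenotype_variance
    val = np.minimum(val, 100.0)
    return float(val) if np.ndim(val) == 0 else val


def manhattan_table(result: ScanResult, marker_map: pd.DataFrame,
                    fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table: chromosome-major ordering, cumulative positions,
    -log10(p) and both significance thresholds."""
    tab = result.table
    missing = tab.index.difference(marker_map.index)
    if len(missing):
        raise MappingError(f"markers without map entry: {list(missing)[:5]}")
    df = tab.join(marker_map[["chrom", "pos"]])
    df = df.sort_values(["chrom", "pos"], kind="stable")
    offset, cum = 0, []
    for _, sub in df.groupby("chrom", sort=False):
        cum.append(sub["pos"] + offset)
        offset += sub["pos"].max() + 1
    df["cum_pos"] = pd.concat(cum)
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p"])
    df["bonferroni_line"] = -np.log10(result.bonferroni_threshold)
    sig_p = df.loc[df["fdr_significant"] == True, "p"]  # noqa: E712
    df["fdr_line"] = -np.log10(sig_p.max()) if len(sig_p) else np.nan
    return df.reset_index()
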