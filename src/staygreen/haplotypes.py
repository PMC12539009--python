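"""LD-guided haplotypes around focal GWAS markers, and their analysis.

A haplotype block starts at a focal marker and extends over physically
adjacent markers in both directions while their LD with the focal marker
exceeds r^2 = 0.7 (composite LD: squared dose correlation, appropriate for
an essentially inbred panel where phase is unavailable).  Cultivars are
clustered on the block dose matrix by k-means; only clusters with at least
five members are emitted, k being the largest value up to ``k_max`` whose
smallest cluster satisfies that rule.  Clusters are coded by the modal
focal-marker allele ('M' major / 'm' minor, plus the base letter, with 'v'
suffixes for repeated codes in descending size order).  A cluster is
favourable when its mean genotype effect (PSRI scale) is significantly
below the locus grand mean — favourable alleles delay senescence.

Group comparisons follow the variance-gated branching: with three or more
groups ANOVA + Tukey letters under homogeneous variances (Levene) and
Kruskal-Wallis + pairwise Wilcoxon otherwise; with two groups a Student or
Welch t-test.  Stacking classes (U-U-U ... F-F-F) combine the
favourable/unfavourable status over three configured loci, and allele
frequencies can be tracked per decade of cultivar release with a
Mann-Kendall-type trend test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import InfeasibleClusteringError, UndefinedLDError
from .types import GenotypeMatrix, HaplotypeCall


# ---------------------------------------------------------------------------
# LD and block construction
# ---------------------------------------------------------------------------

def ld_r2(a, b) -> float:
    """Squared Pearson correlation of two dose vectors (composite LD).

    Symmetric and invariant to allele relabelling (x <-> 2-x).  Requires at
    least 10 jointly observed cultivars; monomorphic input is undefined.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 10:
        raise UndefinedLDError("need >= 10 cultivars with both markers observed")
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedLDError("monomorphic marker: LD undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def collect_block(focal: str, geno: GenotypeMatrix, r2_min: float = 0.7,
                  max_gap: int = 0):
    """Extend the haplotype block from the focal marker along the chromosome.

    Walks over physically adjacent markers in map order in both directions,
    including each marker while its r^2 with the focal marker exceeds
    ``r2_min``; extension stops at the first failure per direction
    (``max_gap`` > 0 tolerates that many consecutive failures before
    stopping).  Returns (member markers in map order, (min, max) span in
    Mbp).
    """
    if focal not in geno.marker_map.index:
        raise KeyError(f"focal marker {focal!r} not in marker map")
    chrom = geno.marker_map.loc[focal, "chrom"]
    chrom_map = geno.marker_map[geno.marker_map["chrom"] == chrom].sort_values("pos")
    order = list(chrom_map.index)
    i0 = order.index(focal)
    focal_doses = geno.doses[focal]
    members = [focal]
    for direction in (-1, +1):
        fails = 0
        i = i0 + direction
        while 0 <= i < len(order):
            m = order[i]
            try:
                r2 = ld_r2(focal_doses, geno.doses[m])
            except UndefinedLDError:
                r2 = 0.0
            if r2 > r2_min:
                members.append(m)
                fails = 0
            else:
                fails += 1
                if fails > max_gap:
                    break
            i += direction
    members = [m for m in order if m in set(members)]
    pos = geno.marker_map.loc[members, "pos"]
    return members, (float(pos.min()) / 1e6, float(pos.max()) / 1e6)


# ---------------------------------------------------------------------------
# clustering and naming
# ---------------------------------------------------------------------------

def cluster_haplotypes(geno: GenotypeMatrix, focal: str, members=None,
                       k_max: int = 6, min_members: int = 5,
                       seed: int = 0) -> HaplotypeCall:
    """K-means haplotype clusters over the block dose matrix.

    k is scanned downward from ``k_max``; the first k whose smallest
    cluster holds at least ``min_members`` cultivars is accepted (k = 1 is
    the degenerate fallback).  Assignments are deterministic under a fixed
    seed; clusters below the membership floor are never emitted.
    """
    if members is None:
        members, span = collect_block(focal, geno)
    else:
        pos = geno.marker_map.loc[list(members), "pos"]
        span = (float(pos.min()) / 1e6, float(pos.max()) / 1e6)
    X = geno.doses[list(members)].to_numpy(dtype=float)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    n = X.shape[0]
    if n < min_members:
        raise InfeasibleClusteringError(
            f"only {n} cultivars; need >= {min_members}")
    n_distinct = np.unique(X, axis=0).shape[0]
    labels = np.zeros(n, dtype=int)
    for k in range(min(k_max, n // min_members, n_distinct), 1, -1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        cand = km.fit_predict(X)
        sizes = np.bincount(cand, minlength=k)
        if sizes.min() >= min_members:
            labels = cand
            break
    assignments = pd.Series(labels, index=geno.cultivars, name="cluster")
    sizes = assignments.value_counts().to_dict()
    return HaplotypeCall(focal=focal, members=tuple(members), span_mbp=span,
                         assignments=assignments, sizes=sizes)


def name_haplotypes(call: HaplotypeCall, geno: GenotypeMatrix) -> HaplotypeCall:
    """Attach M/m + base (+ 'v' variant) codes to each cluster.

    The first letter says whether the cluster's modal focal allele is the
    panel-wide major ('M') or minor ('m') allele; the second is the DNA
    base.  Clusters repeating a code get 'v' suffixes in descending size
    order.  A modal-allele tie within a cluster falls to the major allele
    and raises the tie flag.
    """
    major = geno.marker_map.loc[call.focal, "major"]
    minor = geno.marker_map.loc[call.focal, "minor"]
    doses = geno.doses[call.focal]
    raw: dict[int, str] = {}
    tie = False
    for cl in sorted(call.sizes):
        d = doses[call.assignments == cl].dropna()
        minor_freq = d.mean() / 2.0 if len(d) else 0.0
        if minor_freq == 0.5:
            tie = True
        if minor_freq > 0.5:
            raw[cl] = "m" + minor
        else:
            raw[cl] = "M" + major
    codes: dict[int, str] = {}
    by_code: dict[str, list[int]] = {}
    for cl, code in raw.items():
        by_code.setdefault(code, []).append(cl)
    for code, cls in by_code.items():
        cls.sort(key=lambda c: (-call.sizes[c], c))
        for rank, cl in enumerate(cls):
            codes[cl] = code + "v" * rank
    call.codes = codes
    call.tie_flag = tie
    return call


def flag_favourable(call: HaplotypeCall, effects: pd.Series,
                    alpha: float = 0.05) -> HaplotypeCall:
    """Mark clusters whose mean genotype effect is significantly below the
    locus grand mean (lower PSRI = more stay-green = favourable).

    The locus grand mean is the unweighted mean of the cluster means, so a
    dominant majority cluster can still differ from it; significance is a
    one-sample t-test of the cluster's effects against that reference.
    """
    eff = effects.reindex(call.assignments.index).dropna()
    assign = call.assignments.reindex(eff.index)
    cluster_means = {cl: eff[assign == cl].mean() for cl in call.sizes}
    grand = float(np.mean(list(cluster_means.values())))
    fav = {}
    for cl in call.sizes:
        vals = eff[assign == cl]
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            fav[cl] = bool(len(vals) and vals.mean() < grand)
            continue
        t, p = stats.ttest_1samp(vals, grand)
        fav[cl] = bool(vals.mean() < grand and p < alpha)
    call.favourable = fav
    return call


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class EffectTestReport:
    test_used: str
    statistic: float
    p: float
    levene_p: float
    letters: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    note: str = ""


def _letters_from_pairs(groups, sig: dict) -> dict:
    """Compact letter display: maximal cliques of the not-significantly-
    different graph, ordered by group mean, lettered a, b, c, ..."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for (a, b), s in sig.items():
        if not s:
            g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: min(groups.index(x) for x in c))
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for grp in clique:
            letters[grp] += ch
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def haplotype_effect_test(values: pd.Series, assignments: pd.Series,
                          alpha: float = 0.05,
                          min_group: int = 2) -> EffectTestReport:
    """Variance-gated group comparison of a trait across haplotype groups.

    Levene's test (alpha = 0.05) chooses the branch: with >= 3 groups,
    homogeneous variances -> one-way ANOVA with Tukey HSD letters,
    heterogeneous -> Kruskal-Wallis with Bonferroni-adjusted pairwise
    Wilcoxon letters; with 2 groups, Student's or Welch's t-test.  Any
    constant group forces the nonparametric branch (noted in the report).
    """
    df = pd.DataFrame({"y": values, "g": assignments.reindex(values.index)}).dropna()
    groups = [g for g, sub in df.groupby("g") if len(sub) >= min_group]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    df = df[df["g"].isin(groups)]
    samples = [df.loc[df["g"] == g, "y"].to_numpy() for g in groups]
    note = ""
    constant = [s.std(ddof=1) == 0 for s in samples]
    if any(constant) and not all(constant):
        equal_var = False
        levene_p = 0.0
        note = "constant group present; nonparametric branch forced"
    else:
        _, levene_p = stats.levene(*samples)
        equal_var = levene_p >= 0.05
    order = sorted(range(len(groups)), key=lambda i: samples[i].mean())
    groups = [groups[i] for i in order]
    samples = [samples[i] for i in order]

    if len(groups) == 2:
        t, p = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        letters = {groups[0]: "a", groups[1]: "b" if p < alpha else "a"}
        return EffectTestReport(name, float(t), float(p), float(levene_p),
                                letters, None, note)

    if equal_var:
        F, p = stats.f_oneway(*samples)
        name = "anova_tukey"
        tuk = stats.tukey_hsd(*samples)
        pairs = {}
        rows = []
        for i, j in itertools.combinations(range(len(groups)), 2):
            pij = float(tuk.pvalue[i, j])
            pairs[(groups[i], groups[j])] = pij < alpha
            rows.append({"group_a": groups[i], "group_b": groups[j], "p": pij})
        stat = float(F)
    else:
        H, p = stats.kruskal(*samples)
        name = "kruskal_wilcoxon"
        m = len(groups) * (len(groups) - 1) // 2
        pairs = {}
        rows = []
        for i, j in itertools.combinations(range(len(groups)), 2):
            _, pij = stats.mannwhitneyu(samples[i], samples[j],
                                        alternative="two-sided")
            pij = min(1.0, pij * m)   # Bonferroni within locus
            pairs[(groups[i], groups[j])] = pij < alpha
            rows.append({"group_a": groups[i], "group_b": groups[j], "p": pij})
        stat = float(H)
    letters = _letters_from_pairs(groups, pairs)
    return EffectTestReport(name, stat, float(p), float(levene_p), letters,
                            pd.DataFrame(rows), note)


# ---------------------------------------------------------------------------
# stacking and trends
# ---------------------------------------------------------------------------

def stacking_classes(flags: pd.DataFrame, locus_order=None) -> pd.Series:
    """Per-cultivar stacking label over the configured loci.

    ``flags``: boolean DataFrame, cultivars x loci (True = carries the
    favourable haplotype variant).  Labels join 'F'/'U' in the fixed locus
    order (e.g. F-F-F = all three favourable variants combined).  Cultivars
    uncalled (NaN) at any locus are excluded.
    """
    cols = list(locus_order) if locus_order is not None else list(flags.columns)
    sub = flags[cols].dropna()
    labels = sub.apply(lambda r: "-".join("F" if bool(v) else "U" for v in r),
                       axis=1)
    labels.name = "stacking_class"
    return labels


def carrier_fraction(stay_green: pd.Index, flags: pd.DataFrame,
                     loci=None) -> float:
    """Percent of the stay-green set carrying all configured favourable
    variants."""
    if len(stay_green) == 0:
        raise ValueError("stay-green set is empty")
    cols = list(loci) if loci is not None else list(flags.columns)
    sub = flags.reindex(stay_green)[cols].fillna(False)
    carriers = sub.all(axis=1).sum()
    return float(100.0 * carriers / len(stay_green))


def allele_frequency_trend(geno: GenotypeMatrix, marker: str,
                           allele: str = "minor",
                           origin: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Allele frequency per decade of release, with a monotone-trend test.

    Frequencies are computed within the chosen origin group (or the whole
    panel).  With >= 3 decades a Mann-Kendall-type trend test (Kendall's
    tau of frequency vs decade) is reported; decades without cultivars are
    omitted with a note.
    """
    if geno.metadata is None or "decade" not in geno.metadata.columns:
        raise ValueError("cultivar metadata with a 'decade' column required")
    meta = geno.metadata
    sel = meta.index if origin is None else meta.index[meta["origin"] == origin]
    doses = geno.doses.loc[sel, marker]
    decades = meta.loc[sel, "decade"]
    rows = []
    for dec, idx in doses.groupby(decades).groups.items():
        d = doses.loc[idx].dropna()
        if len(d) == 0:
            continue
        minor_freq = float(d.mean() / 2.0)
        freq = minor_freq if allele == "minor" else 1.0 - minor_freq
        rows.append({"decade": int(dec), "n_cultivars": len(d),
                     "frequency": freq})
    table = pd.DataFrame(rows).sort_values("decade").reset_index(drop=True)
    trend = {}
    if len(table) >= 3:
        tau, p = stats.kendalltau(table["decade"], table["frequency"])
        trend = {"tau": float(tau), "p": float(p)}
    return table, trend
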