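"""Phenotypic statistics for the split-plot senescence trial.

The response analysed throughout is the square-root transformed senescence
index, sqrt(PSRI + 10).  The trial is a split-plot: N level is the main-plot
factor (randomised over blocks), cultivars are sub-plots within blocks, and
imaging dates are repeated measures on the same sub-plot.  The linear model

    Y_ijkl = mu + N_i + B_j + nb_ij + C_k + CN_ki + cnb_kij
             + T_l + TN_li + TC_lk + TNC_lik + eps_ijkl

has three error strata: the main-plot error nb (N x block), the sub-plot
error cnb (cultivar x block within N) and the residual.  N is tested against
nb, cultivar and cultivar-x-N against cnb, and the time terms against the
residual with Greenhouse-Geisser adjusted degrees of freedom.

Variance components V_C (cultivar), V_CxN and V_R are estimated by the
expected-mean-squares method on balanced data (exactly checkable by hand)
with an REML fallback for unbalanced data; negative solutions are truncated
at zero and flagged.  From these the reliability of cultivar means is

    Reliability = V_C / (V_C + V_CxN/n + V_R/(r*n))

with n N levels and r replications.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, InestimableComponentsError,
                     StayGreenError, UndefinedCorrelationError,
                     UndefinedReliabilityError)
from .types import VarianceComponents

__all__ = [
    "transform_psri", "reliability", "greenhouse_geisser_epsilon",
    "relative_senescence_rate", "trait_correlations", "nue", "harvest_index",
    "stay_green_set", "fit_split_plot", "SplitPlotFit",
]


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------

def transform_psri(x):
    """Variance-stabilising transform sqrt(x + 10); requires x > -10."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= -10.0):
        raise ValueError("transform_psri requires x > -10")
    out = np.sqrt(arr + 10.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def reliability(vc: VarianceComponents) -> float:
    """Reliability of cultivar means: V_C / (V_C + V_CxN/n + V_R/(r*n))."""
    denom = vc.v_c + vc.v_cxn / vc.n + vc.v_r / (vc.r * vc.n)
    if denom <= 0:
        raise UndefinedReliabilityError("all variance components are zero")
    return float(vc.v_c / denom)


def relative_senescence_rate(psri_earlier, psri_later):
    """Percent change in PSRI between two dates (positive = progressing).

    Computed on the untransformed index.  Returns (value, inverted_flag);
    the flag warns that a negative earlier value inverts the sign meaning.
    """
    if psri_earlier == 0:
        raise ZeroDivisionError("RSR undefined: earlier PSRI is zero")
    value = (psri_later - psri_earlier) / psri_earlier * 100.0
    return float(value), bool(psri_earlier < 0)


def nue(grain_yield: float, soil_available_n: float) -> float:
    """Nitrogen use efficiency: grain yield (g/m2) per soil available N (g N/m2)."""
    if soil_available_n <= 0:
        raise ValueError("soil available N must be positive")
    if grain_yield < 0:
        raise ValueError("grain yield must be >= 0")
    return float(grain_yield / soil_available_n)


def harvest_index(grain_yield: float, straw_yield: float) -> float:
    """Grain yield over total above-ground biomass (grain + straw)."""
    total = grain_yield + straw_yield
    if total <= 0:
        raise ValueError("grain + straw must be positive")
    return float(grain_yield / total)


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction from a t x t covariance.

    epsilon = tr(A)^2 / ((t-1) * tr(A^2)) with A the double-centred
    covariance; bounded in [1/(t-1), 1].  Multiply time-term degrees of
    freedom by epsilon before the F-test.
    """
    S = np.asarray(cov, dtype=float)
    t = S.shape[0]
    if S.shape != (t, t) or t < 2:
        raise ValueError("need a square covariance over >= 2 time points")
    P = np.eye(t) - np.full((t, t), 1.0 / t)
    A = P @ S @ P
    denom = (t - 1) * float(np.sum(A * A))
    if denom <= 0:
        raise ValueError("degenerate covariance: epsilon undefined")
    eps = float(np.trace(A)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (t - 1), 1.0))


# ---------------------------------------------------------------------------
# correlations and derived sets
# ---------------------------------------------------------------------------

def _pearson_with_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95):
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant variable in correlation")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + conf / 2) / math.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo = hi = r
    return float(r), float(p), float(lo), float(hi)


def trait_correlations(traits: pd.DataFrame, group: pd.Series | None = None,
                       conf: float = 0.95) -> pd.DataFrame:
    """Pairwise Pearson correlations (with p and CI), per group and pooled.

    ``traits`` has one column per trait, one row per cultivar (or plot).
    Returns a long table: group, trait_a, trait_b, n, r, p, ci_lo, ci_hi.
    Pairs with a constant trait raise an undefined-correlation error.
    """
    rows = []
    groupings: list[tuple[str, pd.DataFrame]] = [("pooled", traits)]
    if group is not None:
        for g, idx in traits.groupby(group.reindex(traits.index)).groups.items():
            groupings.append((str(g), traits.loc[idx]))
    for gname, df in groupings:
        for a, b in itertools.combinations(df.columns, 2):
            sub = df[[a, b]].dropna()
            if len(sub) < 3:
                continue
            r, p, lo, hi = _pearson_with_ci(sub[a].values, sub[b].values, conf)
            rows.append({"group": gname, "trait_a": a, "trait_b": b,
                         "n": len(sub), "r": r, "p": p, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def stay_green_set(effects: pd.Series, frac: float = 0.25):
    """Flag the stay-green cultivars: lowest ``frac`` of pooled PSRI effects.

    Low PSRI means high stay-green, so the best performers have the *lowest*
    pooled genotype effects.  The set size is ceil(frac * N).  Ties at the
    cut are broken by stable cultivar-id order and flagged.
    """
    if len(effects) < 4:
        raise ValueError("need at least 4 cultivars to define a quantile set")
    k = math.ceil(frac * len(effects))
    ordered = effects.sort_index(kind="stable").sort_values(kind="stable")
    chosen = ordered.index[:k]
    cut = ordered.iloc[k - 1]
    tie = (len(effects) > k and ordered.iloc[k] == cut)
    return pd.Index(chosen), bool(tie)


# ---------------------------------------------------------------------------
# balanced factorial ANOVA machinery
# ---------------------------------------------------------------------------

def _balanced_effects(df: pd.DataFrame, factors: list[str], response: str):
    """Per-row effect columns for every factor subset of a balanced design.

    Effects are defined recursively: the effect of a term equals the cell
    mean for its factor combination minus the effects of all proper subsets
    (including the grand mean).  Returns dict: subset-tuple -> ndarray of
    per-row effects, plus the grand mean.
    """
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    effects: dict[tuple[str, ...], np.ndarray] = {(): np.full(len(df), grand)}
    for size in range(1, len(factors) + 1):
        for S in itertools.combinations(factors, size):
            cell_mean = df.groupby(list(S), observed=True)[response].transform("mean").to_numpy()
            adj = cell_mean.copy()
            for sub_size in range(0, size):
                for T in itertools.combinations(S, sub_size):
                    adj = adj - effects[T]
            effects[S] = adj
    return effects, grand


def _is_balanced(df: pd.DataFrame, factors: list[str]) -> bool:
    counts = df.groupby(factors, observed=True).size()
    full = np.prod([df[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


@dataclass
class SplitPlotFit:
    """Result of the split-plot repeated-measures fit."""

    components: dict          # date -> VarianceComponents (plus 'pooled')
    genotype_effects: pd.DataFrame   # cultivar x (date columns + 'pooled')
    anova: pd.DataFrame
    epsilon: float | None
    reliability: dict = field(default_factory=dict)  # date -> reliability
    mode: str = "unshrunken"
    method: str = "ems"


def _components_one_date(df: pd.DataFrame, response: str) -> VarianceComponents:
    """EMS variance components for a single date of a balanced split plot.

    With n N levels, r blocks and c cultivars (cultivar and cultivar x N
    random, residual = cultivar x block within N):
        E[MS_C]  = V_R + r*V_CxN + n*r*V_C
        E[MS_CN] = V_R + r*V_CxN
        E[MS_E]  = V_R
    """
    factors = ["n_level", "block", "cultivar"]
    n = df["n_level"].nunique()
    r = df["block"].nunique()
    c = df["cultivar"].nunique()
    if n * r < 2 or (n == 1 and r == 1):
        raise InestimableComponentsError("no replication: components inestimable")
    eff, _ = _balanced_effects(df, factors, response)
    ss = {S: float(np.sum(v ** 2)) for S, v in eff.items() if S}
    ms_c = ss[("cultivar",)] / (c - 1)
    if n > 1:
        ms_cn = ss[("n_level", "cultivar")] / ((n - 1) * (c - 1))
    else:
        ms_cn = None
    # residual: cultivar x block (within N)
    ss_e = ss[("block", "cultivar")]
    df_e = (r - 1) * (c - 1)
    if n > 1 and r > 1:
        ss_e += ss[("n_level", "block", "cultivar")]
        df_e += (n - 1) * (r - 1) * (c - 1)
    ms_e = ss_e / df_e if df_e > 0 else 0.0
    truncated = False
    v_r = ms_e
    if ms_cn is None:
        v_cxn = 0.0
        v_c = (ms_c - ms_e) / r
    else:
        v_cxn = (ms_cn - ms_e) / r
        v_c = (ms_c - ms_cn) / (n * r)
    if v_cxn < 0:
        v_cxn, truncated = 0.0, True
    if v_c < 0:
        v_c, truncated = 0.0, True
    return VarianceComponents(v_c=float(v_c), v_cxn=float(v_cxn), v_r=float(v_r),
                              n=n, r=r, truncated=truncated)


def _components_reml(df: pd.DataFrame, response: str) -> VarianceComponents:
    """REML fallback for unbalanced data via a linear mixed model."""
    import statsmodels.formula.api as smf
    data = df.rename(columns={response: "y"}).copy()
    md = smf.mixedlm("y ~ C(n_level) * C(block)", data=data,
                     groups=data["cultivar"], re_formula="1",
                     vc_formula={"cxn": "0 + C(n_level)"})
    fit = md.fit(reml=True, method="lbfgs")
    v_c = float(fit.cov_re.iloc[0, 0])
    v_cxn = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    v_r = float(fit.scale)
    n = df["n_level"].nunique()
    r = df["block"].nunique()
    return VarianceComponents(v_c=max(v_c, 0.0), v_cxn=max(v_cxn, 0.0),
                              v_r=max(v_r, 0.0), n=n, r=r,
                              truncated=(v_c < 0 or v_cxn < 0))


def _anova_table(df: pd.DataFrame, response: str) -> tuple[pd.DataFrame, float | None]:
    """Repeated-measures split-plot ANOVA on balanced long data.

    Tests N (and block) against the main-plot error N x B; cultivar and
    cultivar x N against the sub-plot error C x B(N); and the time terms
    against the pooled time-by-error residual with Greenhouse-Geisser
    adjusted degrees of freedom.
    """
    factors = ["n_level", "block", "cultivar", "date"]
    levels = {f: df[f].nunique() for f in factors}
    eff, _ = _balanced_effects(df, factors, response)
    ss = {S: float(np.sum(v ** 2)) for S, v in eff.items() if S}
    dof = {S: int(np.prod([levels[f] - 1 for f in S])) for S in ss}

    def pool(terms):
        terms = [t for t in terms if t in ss]
        return sum(ss[t] for t in terms), sum(dof[t] for t in terms)

    ss_mp, df_mp = pool([("n_level", "block")])
    ss_sp, df_sp = pool([("block", "cultivar"), ("n_level", "block", "cultivar")])
    time_resid_terms = [("block", "date"), ("n_level", "block", "date"),
                        ("block", "cultivar", "date"),
                        ("n_level", "block", "cultivar", "date")]
    ss_res, df_res = pool(time_resid_terms)

    epsilon = None
    t = levels["date"]
    if t >= 2:
        wide = df.pivot_table(index=["n_level", "block", "cultivar"],
                              columns="date", values=response)
        cov = np.cov(wide.to_numpy(dtype=float), rowvar=False)
        epsilon = greenhouse_geisser_epsilon(np.atleast_2d(cov))

    tested = [
        (("n_level",), "N", ss_mp, df_mp, "main-plot", False),
        (("block",), "block", ss_mp, df_mp, "main-plot", False),
        (("cultivar",), "cultivar", ss_sp, df_sp, "sub-plot", False),
        (("n_level", "cultivar"), "cultivar:N", ss_sp, df_sp, "sub-plot", False),
        (("date",), "time", ss_res, df_res, "residual", True),
        (("n_level", "date"), "time:N", ss_res, df_res, "residual", True),
        (("cultivar", "date"), "time:cultivar", ss_res, df_res, "residual", True),
        (("n_level", "cultivar", "date"), "time:N:cultivar", ss_res, df_res,
         "residual", True),
    ]
    rows = []
    for S, name, e_ss, e_df, stratum, is_time in tested:
        if S not in ss or e_df == 0 or dof[S] == 0:
            continue
        ms = ss[S] / dof[S]
        ems = e_ss / e_df
        F = ms / ems if ems > 0 else np.inf
        d1, d2 = dof[S], e_df
        if is_time and epsilon is not None:
            d1, d2 = d1 * epsilon, d2 * epsilon
        p = float(stats.f.sf(F, d1, d2))
        rows.append({"term": name, "ss": ss[S], "df": dof[S], "ms": ms,
                     "F": F, "df1": d1, "df2": d2, "p": p,
                     "error_stratum": stratum})
    for (e_ss, e_df), name in [((ss_mp, df_mp), "main-plot error (N x B)"),
                               ((ss_sp, df_sp), "sub-plot error (C x B within N)"),
                               ((ss_res, df_res), "residual")]:
        if e_df > 0:
            rows.append({"term": name, "ss": e_ss, "df": e_df, "ms": e_ss / e_df,
                         "F": np.nan, "df1": np.nan, "df2": np.nan, "p": np.nan,
                         "error_stratum": ""})
    return pd.DataFrame(rows), epsilon


def fit_split_plot(obs: pd.DataFrame, response: str = "value",
                   pooled_dates=None, effects: str = "unshrunken") -> SplitPlotFit:
    """Fit the split-plot repeated-measures model to long-format data.

    Parameters
    ----------
    obs : long DataFrame with columns ``cultivar``, ``n_level``, ``block``,
        ``date`` and the (already transformed) response column.
    pooled_dates : dates whose per-plot means define the pooled genotype
        effects (default: all dates present).
    effects : ``"unshrunken"`` (adjusted cultivar means, default) or
        ``"shrunken"`` (cultivar means shrunk by the reliability factor, the
        random-effect prediction for balanced data).

    Returns per-date and pooled variance components, genotype effects
    (centred within each date), the ANOVA table and the Greenhouse-Geisser
    epsilon.  Results are invariant to the row order of ``obs``.
    """
    if effects not in ("unshrunken", "shrunken"):
        raise ConfigurationError("effects must be 'unshrunken' or 'shrunken'")
    needed = {"cultivar", "n_level", "block", "date", response}
    if not needed.issubset(obs.columns):
        raise ConfigurationError(f"observations need columns {sorted(needed)}")
    df = obs[["cultivar", "n_level", "block", "date", response]].copy()
    df = df.sort_values(["date", "n_level", "block", "cultivar"],
                        kind="stable").reset_index(drop=True)
    if df["n_level"].nunique() == 1 and df["block"].nunique() == 1:
        raise InestimableComponentsError("unreplicated design (r=1 and n=1)")

    dates = sorted(df["date"].unique())
    pooled_dates = dates if pooled_dates is None else [d for d in pooled_dates
                                                       if d in dates]
    balanced = _is_balanced(df, ["n_level", "block", "cultivar", "date"])
    method = "ems" if balanced else "reml"

    components: dict = {}
    rel: dict = {}
    eff_cols: dict = {}
    datasets = [(d, df[df["date"] == d]) for d in dates]
    pooled_df = (df[df["date"].isin(pooled_dates)]
                 .groupby(["cultivar", "n_level", "block"], observed=True, as_index=False)
                 [response].mean())
    pooled_df["date"] = "pooled"
    datasets.append(("pooled", pooled_df))
    for label, sub in datasets:
        if balanced or label == "pooled":
            vc = _components_one_date(sub, response)
        else:
            vc = _components_reml(sub, response)
        components[label] = vc
        try:
            rel[label] = reliability(vc)
        except UndefinedReliabilityError:
            rel[label] = np.nan
        means = sub.groupby("cultivar", observed=True)[response].mean()
        centred = means - means.mean()
        if effects == "shrunken":
            shrink = rel[label] if np.isfinite(rel[label]) else 0.0
            centred = centred * shrink
        eff_cols[label] = centred
    genotype_effects = pd.DataFrame(eff_cols).sort_index()

    epsilon = None
    anova = pd.DataFrame()
    if balanced and len(dates) >= 2:
        anova, epsilon = _anova_table(df, response)
    return SplitPlotFit(components=components, genotype_effects=genotype_effects,
                        anova=anova, epsilon=epsilon, reliability=rel,
                        mode=effects, method=method)
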