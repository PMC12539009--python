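"""Synthetic split-plot trials with known ground truth.

Everything downstream of raw data collection can be exercised without the
field: this module generates a structured inbred SNP panel with LD blocks
around planted causal loci, cultivar-specific logistic senescence
trajectories in thermal time whose onset depends on N level and on the
planted alleles, per-band plot reflectances consistent with the target
PSRI/NDVI/NDRE values, grain and straw yields negatively coupled to the
area under the senescence curve (most strongly at low N), and daily
temperature series.

All randomness flows from a single master seed; each component derives its
own child stream deterministically, so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box

from . import thermal
from .errors import ConfigurationError, LayoutError
from .phenostats import transform_psri
from .raster import GridTransform
from .types import (CENTRAL_DATES, CausalSpec, GenotypeMatrix,
                    SenescenceParams, TrialDesign)

WHEAT_CHROMS = tuple(f"{i}{g}" for i in range(1, 8) for g in "ABD")
CHROM_LENGTH = 800_000_000  # bp, uniform for simplicity
BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n_cultivars: int, n_markers: int, causal: CausalSpec,
                       structure_groups: int = 14, seed: int = 0,
                       fst: float = 0.12, inbred: bool = True) -> GenotypeMatrix:
    """Structured inbred SNP panel with LD blocks around the causal loci.

    Cultivars carry origin (DE/other) and decade-of-release labels forming
    ``structure_groups`` groups; per-group allele frequencies drift around
    the panel frequency (Balding-Nichols beta model, differentiation
    ``fst``), producing mild population structure for the PCA covariates.

    Markers within ``causal.ld_block_width`` of a causal locus are noisy
    copies of the causal column with per-marker allele-flip rates tuned so
    their expected r-squared with the focal marker exceeds 0.7 (exact copies
    at distance zero).  Causal minor-allele frequencies may follow a
    per-decade ramp in German cultivars (``maf_by_decade``), emulating
    introduction and indirect selection of favourable alleles.
    """
    if n_cultivars <= 0 or n_markers <= 0:
        raise ValueError("counts must be positive")
    n_causal_cols = len(causal.loci) * (1 + causal.markers_per_block)
    if n_markers < n_causal_cols:
        raise ValueError("n_markers smaller than causal loci plus their blocks")
    rng = _rng(seed, 1)

    # cultivar metadata: origin x decade structure groups
    n_dec = max(1, structure_groups // 2)
    decades = [1960 + 10 * i for i in range(n_dec)]
    cultivars = pd.Index([f"cv{i:04d}" for i in range(n_cultivars)], name="cultivar")
    origin = np.where(rng.random(n_cultivars) < 0.75, "DE", "other")
    decade = rng.choice(decades, size=n_cultivars)
    meta = pd.DataFrame({"origin": origin, "decade": decade,
                         "group": [f"{o}-{d}" for o, d in zip(origin, decade)]},
                        index=cultivars)
    group_ids, group_idx = np.unique(meta["group"], return_inverse=True)

    # background markers
    n_bg = n_markers - n_causal_cols
    p0 = rng.uniform(0.05, 0.5, size=n_bg)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    group_freq = rng.beta(a[None, :], b[None, :],
                          size=(len(group_ids), n_bg))
    pc = group_freq[group_idx, :]                     # cultivar x marker freq
    if inbred:
        bg = 2.0 * (rng.random((n_cultivars, n_bg)) < pc)
    else:
        bg = rng.binomial(2, pc).astype(float)

    chrom_bg = rng.choice(WHEAT_CHROMS, size=n_bg)
    pos_bg = rng.integers(1, CHROM_LENGTH, size=n_bg)

    # causal loci and their LD blocks
    cols, names, chroms, poss = [], [], [], []
    block_members: dict[str, list[str]] = {}
    for locus in causal.loci:
        freq = np.full(n_cultivars, locus.maf)
        if locus.maf_by_decade is not None:
            for i, cv in enumerate(cultivars):
                if meta.loc[cv, "origin"] == "DE":
                    freq[i] = locus.maf_by_decade.get(int(meta.loc[cv, "decade"]),
                                                      locus.maf)
        if inbred:
            # carrier counts pinned to round(freq * n) per frequency stratum
            # so realized causal MAFs sit at their planted values
            allele = np.zeros(n_cultivars)
            for f in np.unique(freq):
                idx = np.where(freq == f)[0]
                k = int(round(f * len(idx)))
                carriers = rng.permutation(idx)[:k]
                allele[carriers] = 1.0
            dose = 2.0 * allele
        else:
            dose = rng.binomial(2, freq).astype(float)
            allele = dose / 2.0
        cols.append(dose)
        names.append(locus.name)
        chroms.append(locus.chrom)
        poss.append(locus.pos)
        block_members[locus.name] = [locus.name]
        half = causal.ld_block_width // 2
        offsets = np.linspace(-half, half, causal.markers_per_block + 2)[1:-1]
        p_locus = float(np.mean(allele))
        for j, off in enumerate(offsets):
            dist = abs(off) / half
            r2_target = 1.0 - (1.0 - causal.block_r2_target) * dist
            e = _flip_rate_for_r2(p_locus, r2_target)
            flip = rng.random(n_cultivars) < e
            nb_allele = np.where(flip, 1.0 - allele, allele)
            cols.append(2.0 * nb_allele if inbred else
                        np.clip(dose + 2 * (nb_allele - allele), 0, 2))
            name = f"{locus.name}_b{j}"
            names.append(name)
            chroms.append(locus.chrom)
            poss.append(int(locus.pos + off))
            block_members[locus.name].append(name)

    all_doses = np.column_stack([bg] + [c[:, None] for c in cols])
    all_names = [f"M{i:05d}" for i in range(n_bg)] + names
    all_chroms = np.concatenate([chrom_bg, np.array(chroms)])
    all_pos = np.concatenate([pos_bg, np.array(poss, dtype=int)])
    base_idx = rng.integers(0, 4, size=(len(all_names), 2))
    base_idx[:, 1] = (base_idx[:, 0] + 1 + rng.integers(0, 3, size=len(all_names))) % 4
    marker_map = pd.DataFrame({"chrom": all_chroms, "pos": all_pos,
                               "major": BASES[base_idx[:, 0]],
                               "minor": BASES[base_idx[:, 1]]},
                              index=pd.Index(all_names, name="marker"))
    order = np.lexsort((marker_map["pos"].values,
                        marker_map["chrom"].values))
    marker_map = marker_map.iloc[order]
    doses = pd.DataFrame(all_doses[:, order], index=cultivars,
                         columns=marker_map.index)
    geno = GenotypeMatrix(doses, marker_map, meta)
    geno.causal_blocks = {k: tuple(v) for k, v in block_members.items()}
    return geno


def _flip_rate_for_r2(p: float, target_r2: float) -> float:
    """Allele-flip rate giving expected r^2 = target with the focal marker.

    For a copy of a Bernoulli(p) allele flipped with probability e, the
    squared correlation is (p(1-p)(1-2e))^2 / (p(1-p) q(1-q)) with
    q = p(1-e) + (1-p)e; solved for e by bisection (the naive (1-2e)^2
    approximation badly overestimates r^2 at low allele frequencies).
    """
    if target_r2 >= 1.0 or p in (0.0, 1.0):
        return 0.0

    def r2(e):
        q = p * (1 - e) + (1 - p) * e
        return (p * (1 - p)) ** 2 * (1 - 2 * e) ** 2 / (p * (1 - p) * q * (1 - q))

    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = (lo + hi) / 2
        if r2(mid) > target_r2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def favourable_dose(geno: GenotypeMatrix, locus) -> pd.Series:
    """Favourable-allele dose (0..2) at a causal locus for every cultivar."""
    d = geno.doses[locus.name]
    return d if locus.favourable == "minor" else 2.0 - d


# ---------------------------------------------------------------------------
# reflectance inversion
# ---------------------------------------------------------------------------

def bands_from_targets(psri, ndvi, ndre=None, blue=0.06, nir_ratio=1.05):
    """Invert the index formulas: choose band reflectances hitting the targets.

    With blue fixed and the 842/740 nm ratio fixed at ``nir_ratio``, the
    system PSRI = red/blue - nir740, NDVI = (nir842-red)/(nir842+red) (and
    optionally NDRE for the 717 nm band) has a unique solution.  Vectorised;
    no bound checking (see :func:`render_band_medians` for the checked,
    scalar entry point).
    """
    psri = np.asarray(psri, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    blue = np.broadcast_to(np.asarray(blue, dtype=float), psri.shape).copy() \
        if psri.ndim else np.asarray(blue, dtype=float)
    c = nir_ratio * (1.0 - ndvi) / (1.0 + ndvi)
    nir740 = psri * blue / (c - blue)
    red = c * nir740
    nir842 = nir_ratio * nir740
    bands = {475: blue, 668: red, 740: nir740, 842: nir842}
    if ndre is not None:
        ndre = np.asarray(ndre, dtype=float)
        bands[717] = nir842 * (1.0 - ndre) / (1.0 + ndre)
    return bands


def render_band_medians(psri_target, ndvi_target, ndre_target=None,
                        blue=None, nir_ratio=1.05, seed=None):
    """Scalar band solver with physical bound checks.

    Returns a band dict {wavelength nm: reflectance in (0, 1]} such that the
    index formulas recover the targets to machine precision.  Unattainable
    targets raise ValueError naming the violated band bound.
    """
    if blue is None:
        rng = _rng(0 if seed is None else seed, 7)
        blue = float(np.clip(rng.normal(0.06, 0.006), 0.04, 0.10))
    if not (0 < blue <= 1):
        raise ValueError(f"475 nm band out of (0, 1]: {blue}")
    if not (-1 < ndvi_target < 1):
        raise ValueError("NDVI target must lie in (-1, 1)")
    bands = bands_from_targets(psri_target, ndvi_target, ndre_target,
                               blue=blue, nir_ratio=nir_ratio)
    names = {475: "475 nm (blue)", 668: "668 nm (red)", 717: "717 nm (red edge)",
             740: "740 nm (near-IR)", 842: "842 nm (near-IR)"}
    out = {}
    for wl, v in bands.items():
        v = float(v)
        if not (0 < v <= 1):
            raise ValueError(f"target combination unattainable: {names[wl]} "
                             f"band would be {v:.4f}, outside (0, 1]")
        out[wl] = v
    return out


# ---------------------------------------------------------------------------
# temperatures
# ---------------------------------------------------------------------------

def simulate_temperatures(start_date, end_date, seed: int = 0,
                          mean: float = 10.5, amplitude: float = 8.5,
                          diurnal_range: float = 8.0, noise_sd: float = 2.0,
                          ar: float = 0.7) -> pd.DataFrame:
    """Daily (tmin, tmax) series: seasonal sinusoid plus AR(1) noise.

    The seasonal daily mean is ``mean - amplitude*cos(2*pi*(doy-15)/365.25)``
    (coldest mid-January); the diurnal range is strictly positive so
    tmin <= tmax always holds.  Deterministic under a fixed seed.
    """
    start = pd.Timestamp(start_date).date()
    end = pd.Timestamp(end_date).date()
    if start >= end:
        raise ValueError("start_date must precede end_date")
    rng = _rng(seed, 11)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = mean - amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    eps = np.zeros(len(dates))
    innov = rng.normal(0.0, noise_sd * math.sqrt(max(1e-12, 1 - ar ** 2)),
                       size=len(dates))
    for i in range(len(dates)):
        eps[i] = (ar * eps[i - 1] if i else 0.0) + innov[i]
    daily_mean = seasonal + eps
    half_range = np.maximum(0.25, rng.normal(diurnal_range, 1.5,
                                             size=len(dates))) / 2.0
    return pd.DataFrame({"date": dates.date, "tmin": daily_mean - half_range,
                         "tmax": daily_mean + half_range})


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def noiseless_psri(gdd, onset, rate, params: SenescenceParams):
    """Logistic senescence trajectory with optional mid-season plateau."""
    gdd = np.asarray(gdd, dtype=float)
    if params.plateau_gdd > 0:
        gdd = np.where(gdd > onset, np.maximum(onset, gdd - params.plateau_gdd), gdd)
    s = expit(np.asarray(rate) * (gdd - np.asarray(onset)))
    return params.baseline + (params.asymptote - params.baseline) * s


@dataclass
class SimulatedTrial:
    """Full synthetic trial: observations, yields, weather and ground truth."""

    observations: pd.DataFrame
    yields: pd.DataFrame
    temperatures: pd.DataFrame
    gdd: pd.Series                 # imaging date -> cumulative GDD
    design: TrialDesign
    truth: dict


def simulate_trial(design: TrialDesign, genotypes: GenotypeMatrix,
                   causal: CausalSpec, params: SenescenceParams = SenescenceParams(),
                   seed: int = 0, temps: pd.DataFrame | None = None) -> SimulatedTrial:
    """Simulate plot observations and yields for a split-plot trial.

    Senescence onset (in GDD) is cultivar-specific, shifted earlier at lower
    N doses and delayed by favourable causal alleles ("low-only" loci act at
    the lowest N dose only).  Yields are linear in the negative area under
    the plot's PSRI curve, with per-N noise calibrated so the PSRI-yield
    correlation magnitudes follow the configured targets (strongest at low
    N).
    """
    cultivars = genotypes.cultivars
    if len(cultivars) < design.n_cultivars:
        raise ConfigurationError("genotypes do not cover all cultivars in design")
    cultivars = cultivars[:design.n_cultivars]
    rng = _rng(seed, 21)

    if temps is None:
        temps = simulate_temperatures(_dt.date(design.imaging_dates[0].year, 1, 1),
                                      design.imaging_dates[-1], seed=seed)
    gdd = thermal.gdd_table(
        temps, design.imaging_dates,
        thermal.GddConfig(start=_dt.date(design.imaging_dates[0].year, 1, 1)))

    n_c = len(cultivars)
    onset_c = params.onset_gdd + rng.normal(0.0, params.onset_sd, size=n_c)
    rate_c = np.maximum(0.004, rng.normal(params.rate, params.rate_sd, size=n_c))
    shift_all = np.zeros(n_c)
    shift_low = np.zeros(n_c)
    fav = {}
    for locus in causal.loci:
        f = favourable_dose(genotypes, locus).loc[cultivars].to_numpy() / 2.0
        fav[locus.name] = f
        if locus.n_specificity == "all":
            shift_all += locus.onset_shift_gdd * f
        else:
            shift_low += locus.onset_shift_gdd * f
    onset = {}
    for n in design.n_levels:
        delta = params.n_onset_shift.get(n, 0.0)
        onset[n] = onset_c + shift_all + delta + (shift_low if n == design.low_n else 0.0)

    gdd_values = gdd.loc[list(design.imaging_dates)].to_numpy()
    rows = []
    plot_psri = {}
    # blue reflectance low enough that positive-PSRI green canopies stay
    # physically attainable under the NDVI coupling below
    blues = np.clip(rng.normal(0.045, 0.004,
                               size=(len(design.n_levels), design.n_blocks, n_c)),
                    0.035, 0.055)
    for li, n in enumerate(design.n_levels):
        for bi, block in enumerate(range(1, design.n_blocks + 1)):
            traj = noiseless_psri(gdd_values[None, :], onset[n][:, None],
                                  rate_c[:, None], params)
            noisy = traj + rng.normal(0.0, params.noise_sd, size=traj.shape)
            noisy = np.maximum(noisy, 0.02)   # keep PSRI (and bands) positive
            s = np.clip((noisy - params.baseline)
                        / (params.asymptote - params.baseline), 0.0, 1.0)
            ndvi = 0.88 - 0.55 * s
            ndre = 0.48 - 0.33 * s
            blue = blues[li, bi][:, None]
            bands = bands_from_targets(noisy, ndvi, ndre, blue=np.broadcast_to(
                blue, noisy.shape), nir_ratio=1.05)
            for di, date in enumerate(design.imaging_dates):
                for ci, cv in enumerate(cultivars):
                    rows.append({
                        "plot_id": f"N{n}_B{block}_{cv}",
                        "cultivar": cv, "n_level": n, "block": block,
                        "date": date, "gdd": gdd_values[di],
                        "psri": noisy[ci, di], "ndvi": ndvi[ci, di],
                        "ndre": ndre[ci, di],
                        "band_475": bands[475][ci, di],
                        "band_668": bands[668][ci, di],
                        "band_717": bands[717][ci, di],
                        "band_740": bands[740][ci, di],
                        "band_842": bands[842][ci, di],
                    })
            plot_psri[(n, block)] = noisy
    observations = pd.DataFrame(rows)

    # yields: negative linear coupling to area under the PSRI curve,
    # calibrated per N level to the target correlation magnitude
    yield_rows = []
    base_yield = {n: 380.0 + 1.7 * n for n in design.n_levels}  # g/m2
    rng_y = _rng(seed, 22)
    for n in design.n_levels:
        per_block = [np.trapezoid(plot_psri[(n, b)], gdd_values, axis=1)
                     for b in range(1, design.n_blocks + 1)]
        aucs = np.concatenate(per_block)
        sd_auc = float(np.std(aucs))
        slope = 60.0 / sd_auc if sd_auc > 0 else 0.0
        r_t = params.yield_corr.get(n, -0.7)
        # calibrate plot noise so the cultivar-mean (block-averaged)
        # PSRI-yield correlation hits the target r_t
        sd_mean = float(np.std(np.mean(per_block, axis=0)))
        noise_sd = (abs(slope) * sd_mean
                    * math.sqrt(max(1e-9, 1.0 / r_t ** 2 - 1.0))
                    * math.sqrt(design.n_blocks))
        i = 0
        for block in range(1, design.n_blocks + 1):
            for ci, cv in enumerate(cultivars):
                grain = (base_yield[n] - slope * (aucs[i] - aucs.mean())
                         + rng_y.normal(0.0, noise_sd))
                grain = max(50.0, grain)
                hi = float(np.clip(rng_y.normal(0.45, 0.03), 0.30, 0.60))
                yield_rows.append({
                    "plot_id": f"N{n}_B{block}_{cv}", "cultivar": cv,
                    "n_level": n, "block": block,
                    "grain_yield": grain,
                    "straw_yield": grain * (1.0 / hi - 1.0),
                    "soil_available_n": n / 10.0,   # kg N/ha -> g N/m2
                })
                i += 1
    yields = pd.DataFrame(yield_rows)

    truth = {
        "onset": onset, "fav_dose": fav,
        "blocks": getattr(genotypes, "causal_blocks", {}),
        "analytic": planted_marker_truth(design, genotypes, causal, params,
                                         onset_c, rate_c, gdd),
    }
    return SimulatedTrial(observations=observations, yields=yields,
                          temperatures=temps, gdd=gdd, design=design, truth=truth)


def planted_marker_truth(design, genotypes, causal, params, onset_c, rate_c,
                         gdd) -> pd.DataFrame:
    """By-construction marker effects and PVE on the transformed scale.

    Computes noiseless genotype effects (transformed PSRI pooled over the
    central senescence dates, across N levels and at low N only), regresses
    them jointly on the favourable doses of all planted loci, and converts
    each effect to a PVE with the 2*maf*(1-maf)*beta^2/Var(y) convention.
    These are the generator's own analytic values the estimated scan results
    can be compared against.
    """
    cultivars = genotypes.cultivars[:design.n_cultivars]
    central = [d for d in design.imaging_dates if d in CENTRAL_DATES] \
        or list(design.imaging_dates)[1:3]
    gdd_c = gdd.loc[central].to_numpy()
    n_c = len(cultivars)
    shift_all = np.zeros(n_c)
    shift_low = np.zeros(n_c)
    fav_mat = {}
    for locus in causal.loci:
        f = favourable_dose(genotypes, locus).loc[cultivars].to_numpy() / 2.0
        fav_mat[locus.name] = 2.0 * f     # favourable dose 0..2
        target = shift_all if locus.n_specificity == "all" else shift_low
        target += locus.onset_shift_gdd * f
    rows = []
    for scope in ("across", "low"):
        y = np.zeros(n_c)
        levels = design.n_levels if scope == "across" else (design.low_n,)
        for n in levels:
            delta = params.n_onset_shift.get(n, 0.0)
            onset = onset_c + shift_all + delta + \
                (shift_low if n == design.low_n else 0.0)
            traj = noiseless_psri(gdd_c[None, :], onset[:, None],
                                  rate_c[:, None], params)
            y += transform_psri(traj).mean(axis=1)
        y /= len(levels)
        X = np.column_stack([np.ones(n_c)] +
                            [fav_mat[l.name] for l in causal.loci])
        beta = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        var_y = float(np.var(y))
        for locus, b in zip(causal.loci, beta):
            maf = float(min(fav_mat[locus.name].mean() / 2.0,
                            1 - fav_mat[locus.name].mean() / 2.0))
            pve = 100.0 * 2.0 * maf * (1 - maf) * b ** 2 / var_y if var_y > 0 else 0.0
            rows.append({"scope": scope, "locus": locus.name,
                         "beta_favourable": float(b), "maf": maf,
                         "pve": min(100.0, pve), "var_y": var_y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def render_plot_raster(plot_values: pd.DataFrame, pixel_size: float = 0.25,
                       plot_width: float = 3.0, plot_length: float = 7.0,
                       gap: float = 0.5, noise_sd: float = 0.0, seed: int = 0,
                       origin=(350000.0, 5610000.0)):
    """Rasterise per-plot band medians onto a gridded field layout.

    ``plot_values``: DataFrame indexed by plot_id with one column per band
    (columns are band keys passed through unchanged).  Returns
    (rasters: band -> ndarray, transform, polygons: plot_id -> Polygon).
    Polygons cover the central 1.6 x 4.0 m observation area of each plot
    (6.4 m2).  A negative ``gap`` would overlap plots and raises a layout
    error.  With ``noise_sd`` zero the median of the pixels inside each
    polygon equals the requested value exactly.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if gap < 0:
        raise LayoutError("negative plot gap would overlap plot polygons")
    rng = _rng(seed, 31)
    plot_ids = list(plot_values.index)
    n = len(plot_ids)
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    step_x = plot_width + gap
    step_y = plot_length + gap
    width_m = ncols * step_x + gap
    height_m = nrows * step_y + gap
    shape_ = (int(math.ceil(height_m / pixel_size)),
              int(math.ceil(width_m / pixel_size)))
    ox, oy = origin
    transform = GridTransform(origin_x=ox, origin_y=oy, pixel_size=pixel_size)
    xs, ys = transform.pixel_centers(shape_)
    rasters = {band: np.full(shape_, np.nan) for band in plot_values.columns}
    polygons = {}
    cw, cl = 1.6, 4.0   # central observation area
    for k, pid in enumerate(plot_ids):
        r, c = divmod(k, ncols)
        x_lo = ox + gap + c * step_x
        y_hi = oy - gap - r * step_y
        ci = np.where((xs > x_lo) & (xs < x_lo + plot_width))[0]
        ri = np.where((ys < y_hi) & (ys > y_hi - plot_length))[0]
        for band in plot_values.columns:
            val = float(plot_values.loc[pid, band])
            block_vals = np.full((len(ri), len(ci)), val)
            if noise_sd > 0:
                block_vals = block_vals + rng.normal(0, noise_sd, block_vals.shape)
            rasters[band][np.ix_(ri, ci)] = block_vals
        cx = x_lo + plot_width / 2
        cy = y_hi - plot_length / 2
        polygons[pid] = box(cx - cw / 2, cy - cl / 2, cx + cw / 2, cy + cl / 2)
    return rasters, transform, polygons
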