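"""End-to-end orchestration: simulate -> extract -> gdd -> fit -> GWAS -> haplotypes.

`run_pipeline` executes the whole stay-green analysis on a synthetic trial
and returns every intermediate object plus a summary of headline numbers.
Each stage consumes only the outputs of earlier stages (band reflectances,
not the generator's index values, feed the index computation), so the run
exercises the same path field data would take.  With an output directory
the stage tables are written as CSV with a provenance header (stage, seed,
config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas, haplotypes, imaging, phenostats, synth
from .errors import ConfigurationError
from .types import CENTRAL_DATES, CausalSpec, SenescenceParams, TrialDesign

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "n_cultivars": 221,
    "n_markers": 3000,
    "structure_groups": 14,
    "camera": "dual",
    "transform": "sqrt10",
    "gwas": {"pcs": 3, "alpha": 0.05, "model": "multilocus",
             "maf_min": 0.03, "missing_max": 0.05},
    "haplotypes": {"r2_min": 0.7, "min_members": 5, "k_max": 6},
    "raster_demo": False,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config)
    for key in ("geno_path", "obs_path"):
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise ConfigurationError(f"configured path does not exist: {cfg[key]}")
    if cfg["camera"] not in ("dual", "mx", "dual-10-band", "mx-5-band"):
        raise ConfigurationError(f"unknown camera {cfg['camera']!r}")
    if cfg["transform"] != "sqrt10":
        raise ConfigurationError("only the sqrt(x+10) transform is supported")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True,
                                     default=str).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, stage: str, seed: int, chash: str):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} seed={seed} config_hash={chash}\n")
        df.to_csv(fh, index=False)


def select_stacking_loci(scan_across, scan_low, geno,
                         r2_exclude: float = 0.7) -> list[str]:
    """Pick the three stacking loci.

    The third (low-N-specific) locus is the low-N pseudo-QTN with the
    largest excess of low-N over across-N PVE — the most N-specific signal;
    the first two are the strongest remaining across-N pseudo-QTNs not in
    LD with it.
    """
    low_qtns = list(scan_low.pseudo_qtns or [])
    across_qtns = list(scan_across.pseudo_qtns or [])
    third = []
    if low_qtns:
        def specificity(m):
            pve_low = float(scan_low.table.loc[m, "pve"])
            # across-N signal attributable to this locus: its own across PVE
            # or that of any across pseudo-QTN in LD with it
            pve_across = float(scan_across.table.loc[m, "pve"]) \
                if m in scan_across.table.index else 0.0
            for a in across_qtns:
                if a == m or gwas._r2(geno, m, a) > r2_exclude:
                    pve_across = max(pve_across,
                                     float(scan_across.table.loc[a, "pve"]))
            return pve_low - pve_across
        best = max(low_qtns, key=specificity)
        if specificity(best) > 0:
            third = [best]
    across = [m for m in across_qtns
              if all(gwas._r2(geno, m, t) <= r2_exclude for t in third)]
    across = sorted(across, key=lambda m: -scan_across.table.loc[m, "pve"])[:2]
    return across + third


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run the full synthetic stay-green analysis; see module docstring."""
    cfg = validate_config(config or {})
    seed = int(cfg["seed"])
    chash = _config_hash(cfg)
    out = Path(outdir) if outdir is not None else None
    camera = imaging.camera_from_name(cfg["camera"])

    # --- simulate ------------------------------------------------------
    causal = cfg.get("causal") or CausalSpec.default()
    params = cfg.get("senescence") or SenescenceParams()
    design = TrialDesign(n_cultivars=cfg["n_cultivars"])
    geno = synth.simulate_genotypes(cfg["n_cultivars"], cfg["n_markers"], causal,
                                    structure_groups=cfg["structure_groups"],
                                    seed=seed)
    trial = synth.simulate_trial(design, geno, causal, params, seed=seed)
    obs = trial.observations.copy()

    # --- imaging: indices recomputed from the band reflectances ---------
    bands = {wl: obs[f"band_{wl}"].to_numpy() for wl in (475, 668, 717, 740, 842)}
    obs["psri_x"] = imaging.compute_index(bands, "PSRI", camera)
    obs["ndvi_x"] = imaging.compute_index(bands, "NDVI", camera)
    obs["ndre_x"] = imaging.compute_index(bands, "NDRE", camera)

    raster_check = None
    if cfg.get("raster_demo"):
        date0 = design.imaging_dates[1]
        sub = obs[obs["date"] == date0].set_index("plot_id").iloc[:40]
        rasters, transform, polys = synth.render_plot_raster(
            sub[["band_475", "band_668", "band_740"]], pixel_size=0.25,
            seed=seed)
        med = imaging.extract_plot_medians(rasters["band_668"], transform, polys,
                                           min_coverage_px=50)
        raster_check = med.merge(sub[["band_668"]], left_on="plot_id",
                                 right_index=True)

    # --- phenostats ------------------------------------------------------
    obs["value"] = phenostats.transform_psri(obs["psri_x"])
    central = [d for d in design.imaging_dates if d in CENTRAL_DATES]
    fit = phenostats.fit_split_plot(obs, response="value", pooled_dates=central)
    low = design.low_n
    fit_low = phenostats.fit_split_plot(
        obs[obs["n_level"] == low], response="value", pooled_dates=central)
    effects_across = fit.genotype_effects["pooled"]
    effects_low = fit_low.genotype_effects["pooled"]
    sg_set, sg_tie = phenostats.stay_green_set(effects_across)

    # --- trait correlations ---------------------------------------------
    cultivar_psri = (obs[obs["date"].isin(central)]
                     .groupby(["cultivar", "n_level"], observed=True)["psri_x"].mean()
                     .reset_index())
    cultivar_yield = (trial.yields
                      .groupby(["cultivar", "n_level"], observed=True)
                      .agg(grain_yield=("grain_yield", "mean"),
                           straw_yield=("straw_yield", "mean"),
                           soil_n=("soil_available_n", "first"))
                      .reset_index())
    traits = cultivar_psri.merge(cultivar_yield, on=["cultivar", "n_level"])
    traits["nue"] = traits["grain_yield"] / traits["soil_n"]
    traits["harvest_index"] = traits["grain_yield"] / (
        traits["grain_yield"] + traits["straw_yield"])
    yield_corr = {}
    for n, sub in traits.groupby("n_level"):
        yield_corr[int(n)] = float(np.corrcoef(sub["psri_x"],
                                               sub["grain_yield"])[0, 1])

    # --- GWAS -------------------------------------------------------------
    gcfg = cfg["gwas"]
    filtered, filter_report = gwas.filter_markers(
        geno, maf_min=gcfg["maf_min"], missing_max=gcfg["missing_max"])
    complete, _ = gwas.impute_missing(filtered)
    pcs, pc_var = gwas.pca_markers(complete, k=gcfg["pcs"])
    scan_fn = gwas.multilocus_scan if gcfg["model"] == "multilocus" \
        else gwas.single_marker_scan
    scan_across = scan_fn(effects_across, complete, pcs, alpha=gcfg["alpha"])
    scan_low = scan_fn(effects_low, complete, pcs, alpha=gcfg["alpha"])

    # --- haplotypes --------------------------------------------------------
    hcfg = cfg["haplotypes"]
    focal_loci = cfg.get("focal_loci") or select_stacking_loci(
        scan_across, scan_low, complete, r2_exclude=hcfg["r2_min"])
    calls = {}
    flags = pd.DataFrame(index=geno.cultivars)
    for i, focal in enumerate(focal_loci):
        members, _ = haplotypes.collect_block(focal, complete,
                                              r2_min=hcfg["r2_min"])
        call = haplotypes.cluster_haplotypes(
            complete, focal, members, k_max=hcfg["k_max"],
            min_members=hcfg["min_members"], seed=seed)
        call = haplotypes.name_haplotypes(call, complete)
        # the low-N-specific stacking locus (third) is judged on low-N
        # effects; across-N loci on pooled effects
        eff = effects_low if (len(focal_loci) == 3 and i == 2) else effects_across
        call = haplotypes.flag_favourable(call, eff)
        calls[focal] = call
        fav_cl = {c for c, f in call.favourable.items() if f}
        flags[focal] = call.assignments.isin(fav_cl)

    stacking = haplotypes.stacking_classes(flags, locus_order=focal_loci) \
        if len(focal_loci) else pd.Series(dtype=object)
    carrier_pct = np.nan
    if len(focal_loci) >= 2:
        carrier_pct = haplotypes.carrier_fraction(sg_set, flags,
                                                  loci=focal_loci[:2])
    stack_test = None
    if len(focal_loci) == 3:
        psri_low = (obs[(obs["n_level"] == low) & (obs["date"] == central[-1])]
                    .groupby("cultivar", observed=True)["psri_x"].mean())
        wanted = stacking[stacking.isin(["F-F-F", "F-F-U"])]
        if wanted.nunique() == 2 and wanted.value_counts().min() >= 2:
            stack_test = haplotypes.haplotype_effect_test(
                psri_low.reindex(wanted.index), wanted)

    trend_table, trend_stats = (pd.DataFrame(), {})
    if len(focal_loci) == 3:
        trend_table, trend_stats = haplotypes.allele_frequency_trend(
            complete, focal_loci[2], allele="minor", origin="DE")

    summary = {
        "reliability_pooled": fit.reliability.get("pooled", np.nan),
        "reliability_by_date": {str(k): v for k, v in fit.reliability.items()},
        "epsilon": fit.epsilon,
        "yield_corr_by_n": yield_corr,
        "n_stay_green": len(sg_set),
        "pc_variance_fractions": pc_var.to_dict(),
        "pseudo_qtns_across": list(scan_across.pseudo_qtns or []),
        "pseudo_qtns_low": list(scan_low.pseudo_qtns or []),
        "stacking_counts": stacking.value_counts().to_dict(),
        "carrier_fraction_pct": carrier_pct,
        "stack_test_p": None if stack_test is None else stack_test.p,
        "trend": trend_stats,
        "filter_report": filter_report,
    }

    if out is not None:
        _write(obs, out / "observations.csv", "extract", seed, chash)
        _write(trial.yields, out / "yields.csv", "simulate", seed, chash)
        _write(trial.temperatures, out / "temperatures.csv", "simulate", seed, chash)
        _write(trial.gdd.rename_axis("date").reset_index(), out / "gdd.csv",
               "gdd", seed, chash)
        _write(fit.genotype_effects.rename_axis("cultivar").reset_index(),
               out / "genotype_effects.csv", "fitmodel", seed, chash)
        _write(fit.anova, out / "anova.csv", "fitmodel", seed, chash)
        _write(scan_across.table.reset_index(), out / "gwas_across.csv",
               "gwas", seed, chash)
        _write(scan_low.table.reset_index(), out / "gwas_low_n.csv",
               "gwas", seed, chash)
        _write(stacking.rename_axis("cultivar").reset_index(),
               out / "stacking.csv", "haplotypes", seed, chash)
        if len(trend_table):
            _write(trend_table, out / "allele_frequency_trend.csv",
                   "haplotypes", seed, chash)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, default=str))

    return {"config": cfg, "design": design, "causal": causal, "geno": geno,
            "trial": trial, "observations": obs, "fit": fit, "fit_low": fit_low,
            "effects_across": effects_across, "effects_low": effects_low,
            "stay_green_set": sg_set, "traits": traits, "pcs": pcs,
            "scan_across": scan_across, "scan_low": scan_low,
            "focal_loci": focal_loci, "calls": calls, "flags": flags,
            "stacking": stacking, "stack_test": stack_test,
            "trend_table": trend_table, "raster_check": raster_check,
            "summary": summary}
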