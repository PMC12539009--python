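#!/usr/bin/env python
"""Split-plot mixed-model analysis of the transformed senescence index.

Fits sqrt(PSRI + 10) with N level as main plot, cultivars as sub-plots and
imaging dates as repeated measures; reports variance components and
reliability per date, Greenhouse-Geisser-corrected F-tests, per-cultivar
genotype effects (pooled over the central senescence phase), the stay-green
top-25% set, and trait correlations of PSRI with grain yield, NUE, harvest
index and straw yield per N level.

Reads:  results/plot_indices.csv, results/yields.csv
Writes: results/variance_components.csv, anova.csv, genotype_effects.csv,
        stay_green_set.csv, trait_correlations.csv
"""

from pathlib import Path

import pandas as pd

from staygreen import phenostats as ps

OUT = Path(__file__).resolve().parent.parent / "results"
CENTRAL = ["2020-06-09", "2020-06-24"]


def main():
    obs = pd.read_csv(OUT / "plot_indices.csv")
    obs["value"] = ps.transform_psri(obs["psri"])
    fit = ps.fit_split_plot(obs, pooled_dates=CENTRAL)

    comp = pd.DataFrame([
        {"date": d, "v_c": vc.v_c, "v_cxn": vc.v_cxn, "v_r": vc.v_r,
         "n": vc.n, "r": vc.r, "reliability": fit.reliability[d]}
        for d, vc in fit.components.items()])
    comp.to_csv(OUT / "variance_components.csv", index=False)
    fit.anova.to_csv(OUT / "anova.csv", index=False)
    fit.genotype_effects.rename_axis("cultivar").reset_index().to_csv(
        OUT / "genotype_effects.csv", index=False)

    sg, tie = ps.stay_green_set(fit.genotype_effects["pooled"])
    pd.DataFrame({"cultivar": sg}).to_csv(OUT / "stay_green_set.csv",
                                          index=False)

    yields = pd.read_csv(OUT / "yields.csv")
    cultivar_psri = (obs[obs["date"].isin(CENTRAL)]
                     .groupby(["cultivar", "n_level"])["psri"].mean())
    traits = (yields.groupby(["cultivar", "n_level"])
              .agg(grain_yield=("grain_yield", "mean"),
                   straw_yield=("straw_yield", "mean"),
                   soil_n=("soil_available_n", "first")))
    traits["psri"] = cultivar_psri
    traits["nue"] = traits["grain_yield"] / traits["soil_n"]
    traits["harvest_index"] = traits["grain_yield"] / (
        traits["grain_yield"] + traits["straw_yield"])
    traits = traits.reset_index()
    corr = ps.trait_correlations(
        traits[["psri", "grain_yield", "nue", "harvest_index", "straw_yield"]],
        group=traits["n_level"])
    corr.to_csv(OUT / "trait_correlations.csv", index=False)

    print("variance components and reliability per date:")
    print(comp.round(4).to_string(index=False))
    print(f"\nGreenhouse-Geisser epsilon: {fit.epsilon:.3f}")
    print(fit.anova[["term", "F", "p", "error_stratum"]].round(4)
          .to_string(index=False))
    print(f"\nstay-green set: {len(sg)} cultivars (lowest pooled PSRI effects)")
    gy = corr[(corr["trait_a"] == "psri") & (corr["trait_b"] == "grain_yield")]
    print("\nPSRI-grain yield correlation by group (NUE shares it exactly):")
    print(gy[["group", "n", "r", "p"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
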