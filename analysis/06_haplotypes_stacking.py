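#!/usr/bin/env python
"""LD-block haplotypes at the focal GWAS loci, stacking and allele trends.

Around each focal pseudo-QTN the haplotype block extends over adjacent
markers with r^2 > 0.7; cultivars are clustered by k-means (clusters need
>= 5 members) and coded M/m + base (+v).  Favourable clusters (significantly
lower PSRI effects) define carrier flags, from which come the stacking
classes (U-U-U ... F-F-F), the carrier fraction among stay-green cultivars,
the triple- vs double-stack comparison at low N, and the decade trend of
the favourable low-N minor allele in the German panel.

Reads:  results/genotypes.hmp.csv, pseudo_qtns.csv, genotype_effects.csv,
        stay_green_set.csv, plot_indices.csv, cultivar_metadata.csv
Writes: results/haplotype_calls.csv, stacking_classes.csv,
        allele_frequency_trend.csv
"""

import sys
from pathlib import Path

import pandas as pd

from staygreen import gwas, haplotypes as hap, phenostats as ps, pipeline
from staygreen.types import GenotypeMatrix

OUT = Path(__file__).resolve().parent.parent / "results"
CENTRAL = ["2020-06-09", "2020-06-24"]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    meta = pd.read_csv(OUT / "cultivar_metadata.csv").set_index("cultivar")
    geno = GenotypeMatrix.from_hapmap_csv(OUT / "genotypes.hmp.csv", meta)
    complete, _ = gwas.impute_missing(geno)
    eff_across = pd.read_csv(OUT / "genotype_effects.csv") \
        .set_index("cultivar")["pooled"]
    obs = pd.read_csv(OUT / "plot_indices.csv")
    low = obs["n_level"].min()
    obs["value"] = ps.transform_psri(obs["psri"])
    eff_low = ps.fit_split_plot(obs[obs["n_level"] == low],
                                pooled_dates=CENTRAL) \
        .genotype_effects["pooled"]

    qtns = pd.read_csv(OUT / "pseudo_qtns.csv")
    # same selection logic as the library pipeline: two strongest across-N
    # loci plus the most N-specific low-N locus
    focal = []
    low_q = qtns[qtns["scope"] == "low"]
    across_q = qtns[qtns["scope"] == "across"]
    if len(low_q):
        def spec(row):
            own = across_q[across_q["marker"] == row["marker"]]["pve"]
            pve_a = float(own.iloc[0]) if len(own) else 0.0
            for a in across_q["marker"]:
                if hap.ld_r2(complete.doses[row["marker"]],
                             complete.doses[a]) > 0.7:
                    pve_a = max(pve_a, float(
                        across_q.set_index("marker").loc[a, "pve"]))
            return row["pve"] - pve_a
        low_q = low_q.assign(spec=low_q.apply(spec, axis=1))
        best = low_q.sort_values("spec").iloc[-1]
        third = [best["marker"]] if best["spec"] > 0 else []
    else:
        third = []
    keep = [m for m in across_q.sort_values("pve", ascending=False)["marker"]
            if all(hap.ld_r2(complete.doses[m], complete.doses[t]) <= 0.7
                   for t in third)][:2]
    focal = keep + third
    print("focal loci:", focal)

    rows = []
    flags = pd.DataFrame(index=complete.cultivars)
    for i, marker in enumerate(focal):
        members, span = hap.collect_block(marker, complete)
        call = hap.cluster_haplotypes(complete, marker, members, seed=SEED)
        call = hap.name_haplotypes(call, complete)
        eff = eff_low if (len(focal) == 3 and i == 2) else eff_across
        call = hap.flag_favourable(call, eff)
        fav_cl = {c for c, f in call.favourable.items() if f}
        flags[marker] = call.assignments.isin(fav_cl)
        for cl, code in call.codes.items():
            rows.append({"focal": marker, "cluster": cl, "code": code,
                         "members": call.sizes[cl],
                         "favourable": call.favourable[cl],
                         "span_mbp": f"{span[0]:.2f}-{span[1]:.2f}"})
        test = hap.haplotype_effect_test(eff, call.assignments.map(call.codes))
        print(f"{marker}: clusters {call.codes}, test={test.test_used}, "
              f"p={test.p:.2e}, letters={test.letters}")
    pd.DataFrame(rows).to_csv(OUT / "haplotype_calls.csv", index=False)

    stacking = hap.stacking_classes(flags, locus_order=focal)
    stacking.rename_axis("cultivar").reset_index().to_csv(
        OUT / "stacking_classes.csv", index=False)
    print("\nstacking class counts:", stacking.value_counts().to_dict())

    sg = pd.Index(pd.read_csv(OUT / "stay_green_set.csv")["cultivar"])
    carrier = hap.carrier_fraction(sg, flags, loci=focal[:2])
    print(f"stay-green cultivars carrying both across-N favourable "
          f"haplotypes: {carrier:.1f}%")

    if len(focal) == 3:
        last = sorted(obs["date"].unique())[-2]
        psri_low = (obs[(obs["n_level"] == low) & (obs["date"] == last)]
                    .groupby("cultivar")["psri"].mean())
        pair = stacking[stacking.isin(["F-F-F", "F-F-U"])]
        rep = hap.haplotype_effect_test(psri_low.reindex(pair.index), pair)
        print(f"F-F-F vs F-F-U PSRI at low N ({last}): {rep.test_used}, "
              f"p={rep.p:.2e}")
        trend, stats_ = hap.allele_frequency_trend(complete, focal[2],
                                                   origin="DE")
        trend.to_csv(OUT / "allele_frequency_trend.csv", index=False)
        print("\nfavourable minor-allele frequency by decade (DE):")
        print(trend.to_string(index=False))
        if stats_:
            print(f"Mann-Kendall-type trend: tau={stats_['tau']:.2f}, "
                  f"p={stats_['p']:.3f}")


if __name__ == "__main__":
    main()
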