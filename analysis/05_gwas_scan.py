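#!/usr/bin/env python
"""Multi-locus GWAS of the genotype effects, across N levels and at low N.

Markers are filtered (MAF >= 3%, missing <= 5%), mean-imputed, and the
first three marker principal components serve as structure covariates.  The
iterative-conditioning scan selects pseudo-QTNs at the Bonferroni
threshold; p-values are BH-adjusted and effects summarised as PVE.

Reads:  results/genotypes.hmp.csv, cultivar_metadata.csv,
        genotype_effects.csv, plot_indices.csv
Writes: results/gwas_across.csv, gwas_low_n.csv, manhattan_across.csv,
        pseudo_qtns.csv
"""

from pathlib import Path

import pandas as pd

from staygreen import gwas, phenostats as ps
from staygreen.types import GenotypeMatrix

OUT = Path(__file__).resolve().parent.parent / "results"
CENTRAL = ["2020-06-09", "2020-06-24"]


def main():
    meta = pd.read_csv(OUT / "cultivar_metadata.csv").set_index("cultivar")
    geno = GenotypeMatrix.from_hapmap_csv(OUT / "genotypes.hmp.csv", meta)
    effects = pd.read_csv(OUT / "genotype_effects.csv").set_index("cultivar")

    obs = pd.read_csv(OUT / "plot_indices.csv")
    obs["value"] = ps.transform_psri(obs["psri"])
    low = obs["n_level"].min()
    fit_low = ps.fit_split_plot(obs[obs["n_level"] == low],
                                pooled_dates=CENTRAL)

    filtered, report = gwas.filter_markers(geno)
    complete, n_imp = gwas.impute_missing(filtered)
    pcs, pc_var = gwas.pca_markers(complete, k=3)
    print(f"filter report: {report}; imputed {n_imp} calls")
    print("PC variance fractions:", pc_var.round(4).to_dict())

    scan_across = gwas.multilocus_scan(effects["pooled"], complete, pcs)
    scan_low = gwas.multilocus_scan(fit_low.genotype_effects["pooled"],
                                    complete, pcs)
    scan_across.table.reset_index().to_csv(OUT / "gwas_across.csv", index=False)
    scan_low.table.reset_index().to_csv(OUT / "gwas_low_n.csv", index=False)
    gwas.manhattan_table(scan_across, complete.marker_map).to_csv(
        OUT / "manhattan_across.csv", index=False)

    rows = []
    for scope, scan in [("across", scan_across), ("low", scan_low)]:
        for m in scan.pseudo_qtns:
            r = scan.table.loc[m]
            rows.append({"scope": scope, "marker": m, "effect": r["effect"],
                         "p": r["p"], "p_bh": r["p_bh"], "pve": r["pve"]})
    qtns = pd.DataFrame(rows)
    qtns.to_csv(OUT / "pseudo_qtns.csv", index=False)
    print("\npseudo-QTNs (Bonferroni-passing conditioning markers):")
    print(qtns.round(5).to_string(index=False))


if __name__ == "__main__":
    main()
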