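#!/usr/bin/env python
"""Steps 2-3: chromosome-specific GLS scan and Wald refits of the hits.

Scans every filtered SNP under the selected null covariance with
leave-one-chromosome-out kinship, classifies associations against the
Bonferroni (4.94) and suggestive (4.0) thresholds, refits each hit by full
REML for per-trait effects / CIs / variance explained, and compares hits to
the planted QTL.  Compact tables go to results/; the full scan to scratch/.
"""

import json

import numpy as np
import pandas as pd

from mtgwas.genotypes import compute_maf, filter_snps, impute_mode, loco_grms, read_matrix_tsv, vanraden_grm
from mtgwas.multitrait import reml_null
from mtgwas.scan import bonferroni_threshold, classify_associations, gls_scan, refit_snp

from _paths import RESULTS, SCRATCH

QTL_WINDOW_BP = 300_000


def main() -> None:
    G = read_matrix_tsv(SCRATCH / "genotypes.tsv", SCRATCH / "snp_map.tsv")
    G = impute_mode(filter_snps(G, maf_min=0.025, missing_max=0.20))
    Y = pd.read_csv(SCRATCH / "blues_standardized.csv", index_col="line")
    K = vanraden_grm(G)
    selected = json.loads((RESULTS / "03_null_model.json").read_text())["selected"]
    null = reml_null(Y, K, selected)

    thr = bonferroni_threshold()
    scan = gls_scan(Y, G, null, loco_grms(G))
    scan = classify_associations(scan, threshold_sig=thr, threshold_sug=4.0)
    scan.to_csv(SCRATCH / "scan_full.tsv", sep="\t", index=False)

    hits = scan.loc[scan["classification"] != "none"]
    info = compute_maf(G).set_index("snp")
    col = {s: j for j, s in enumerate(G.snp_map["snp"])}
    rows = []
    for _, h in hits.iterrows():
        res = refit_snp(Y, G.calls[:, col[h["snp"]]], K, selected,
                        snp_id=h["snp"], classification=h["classification"],
                        null_fit=null, maf=float(info.at[h["snp"], "maf"]))
        for trait, r in res.effects.iterrows():
            rows.append({"snp": h["snp"], "chrom": h["chrom"], "pos": h["pos"],
                         "minus_log10_p": h["minus_log10_p"],
                         "classification": h["classification"],
                         "trait": trait, **r})
    effects = pd.DataFrame(rows)
    effects.to_csv(RESULTS / "04_snp_effects.tsv", sep="\t", index=False,
                   float_format="%.5f")

    qtl = pd.read_csv(SCRATCH / "qtl_truth.csv", dtype={"chrom": str})
    sig = hits.loc[hits["classification"] == "significant"]
    n_rec = sum(int(((sig["chrom"].astype(str) == str(q["chrom"]))
                     & ((sig["pos"] - q["pos"]).abs() <= QTL_WINDOW_BP)).any())
                for _, q in qtl.iterrows())
    summary = {
        "threshold_significant": round(thr, 2),
        "threshold_suggestive": 4.0,
        "n_snps_tested": int(len(scan)),
        "n_significant": int((scan["classification"] == "significant").sum()),
        "n_suggestive": int((scan["classification"] == "suggestive").sum()),
        "qtl_recovered": n_rec,
        "qtl_planted": int(len(qtl)),
    }
    (RESULTS / "04_scan_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    if len(effects):
        fav = effects.groupby("snp")["favorable_allele"].agg(
            lambda s: s.value_counts().idxmax())
        print(f"favorable allele minor for {(fav == 'minor').sum()} of "
              f"{len(fav)} associated SNPs")


if __name__ == "__main__":
    main()
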