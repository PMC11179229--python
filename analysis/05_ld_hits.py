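#!/usr/bin/env python
"""LD characterization of the associated SNPs.

Squared genotypic correlations with two-sided Fisher exact significance for
all associated SNPs against their 2,000-kb physical neighborhoods plus all
same-chromosome pairs of associated SNPs.
"""

import pandas as pd

from mtgwas.genotypes import filter_snps, impute_mode, read_matrix_tsv
from mtgwas.ld import ld_neighborhood

from _paths import RESULTS, SCRATCH


def main() -> None:
    G = read_matrix_tsv(SCRATCH / "genotypes.tsv", SCRATCH / "snp_map.tsv")
    G = impute_mode(filter_snps(G, maf_min=0.025, missing_max=0.20))
    scan = pd.read_csv(SCRATCH / "scan_full.tsv", sep="\t")
    hits = scan.loc[scan["classification"] != "none", "snp"].tolist()
    if not hits:
        print("no associated SNPs; nothing to do")
        return
    table = ld_neighborhood(G, hits, window_bp=2_000_000)
    focal = table.loc[table["snp_b"].isin(hits)]
    focal.to_csv(RESULTS / "05_ld_hits.tsv", sep="\t", index=False,
                 float_format="%.4g")
    table.to_csv(SCRATCH / "ld_neighborhood_full.tsv", sep="\t", index=False)
    print(f"{len(table)} neighborhood pairs; "
          f"{len(focal)} pairs among associated SNPs written to results/")
    linked = focal.loc[focal["dist_bp"] < 200_000]
    if len(linked):
        print("closely linked associated pairs (dist < 200 kb):")
        print(linked.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
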