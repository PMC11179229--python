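#!/usr/bin/env python
"""Step 1 of the association scan: no-marker multi-trait null model.

Standardizes the stage-1 BLUEs, fits the Kronecker-covariance model under
FA1, FA2 and unstructured trait covariance, and selects the structure by
AIC.  Writes the AIC table and the selected fit to results/.
"""

import json

import pandas as pd

from mtgwas.genotypes import filter_snps, impute_mode, read_matrix_tsv, vanraden_grm, write_kinship_tsv
from mtgwas.multitrait import reml_null, select_structure
from mtgwas.trials import standardize_traits

from _paths import RESULTS, SCRATCH


def main() -> None:
    G = read_matrix_tsv(SCRATCH / "genotypes.tsv", SCRATCH / "snp_map.tsv")
    G = impute_mode(filter_snps(G, maf_min=0.025, missing_max=0.20))
    K = vanraden_grm(G)
    write_kinship_tsv(K, SCRATCH / "kinship_full.tsv")

    blues = pd.read_csv(SCRATCH / "blues.csv", index_col="line")
    Y = standardize_traits(blues.reindex(G.line_ids))
    Y.to_csv(SCRATCH / "blues_standardized.csv", index_label="line")

    fits = [reml_null(Y, K, s) for s in ("FA1", "FA2", "UNS")]
    best = select_structure(fits)
    out = {f.structure: {"loglik": f.loglik, "k": f.k, "aic": f.aic}
           for f in fits}
    out["selected"] = best.structure
    out["sigma_T"] = best.sigma_T.tolist()
    out["sigma_R"] = best.sigma_R.tolist()
    out["traits"] = best.trait_names
    (RESULTS / "03_null_model.json").write_text(json.dumps(out, indent=2))

    print("structure   k   loglik        AIC")
    for f in fits:
        mark = " <- selected" if f.structure == best.structure else ""
        print(f"{f.structure:9s} {f.k:3d}  {f.loglik:10.2f}  {f.aic:10.2f}{mark}")


if __name__ == "__main__":
    main()
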