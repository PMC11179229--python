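"""Linkage disequilibrium between SNPs of an inbred panel.

With only homozygous {0, 2} codes the genotype table of a SNP pair is the
haplotype table, so r^2 is the squared Pearson correlation of the codes and
the significance of the association is a two-sided Fisher exact test on the
2x2 genotype-class table.  Missing calls are handled by pairwise-complete
deletion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["ld_r2", "ld_fisher_p", "ld_neighborhood"]


def _pairwise_complete(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must cover the same lines")
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    return g1[ok], g2[ok]


def ld_r2(g1, g2) -> float:
    """Squared genotypic correlation over pairwise-complete lines.

    Returns ``nan`` when either vector is constant after pairwise-complete
    filtering (r^2 undefined).
    """
    a, b = _pairwise_complete(g1, g2)
    if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_fisher_p(g1, g2) -> float:
    """Two-sided Fisher exact p on the 2x2 table of genotype classes.

    Table cells count lines by (g1 class, g2 class) with classes 0 and 2;
    two-sided by summing hypergeometric tables with probability not above
    the observed one (the standard convention, via scipy).
    """
    a, b = _pairwise_complete(g1, g2)
    if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    table = np.array(
        [
            [np.sum((a == 0) & (b == 0)), np.sum((a == 0) & (b == 2))],
            [np.sum((a == 2) & (b == 0)), np.sum((a == 2) & (b == 2))],
        ]
    )
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ld_neighborhood(
    G: GenotypeMatrix,
    focal_snps: list[str],
    window_bp: int = 2_000_000,
) -> pd.DataFrame:
    """LD of focal SNPs with their physical neighborhoods.

    Returns every (focal, other) pair with ``|pos_a - pos_b| <= window_bp``
    on the same chromosome, plus every focal-focal pair sharing a chromosome
    regardless of distance.  Columns: ``snp_a, snp_b, chrom, dist_bp, r2,
    fisher_p`` (snp_a is the focal SNP; focal-focal pairs appear once).
    """
    smap = G.snp_map
    index = {s: j for j, s in enumerate(smap["snp"])}
    missing = [s for s in focal_snps if s not in index]
    if missing:
        raise ValueError(f"focal SNPs not in the map: {missing}")
    focal_set = set(focal_snps)
    rows = []
    seen: set[tuple[str, str]] = set()
    for s in focal_snps:
        j = index[s]
        chrom = str(smap.at[j, "chrom"])
        pos = int(smap.at[j, "pos"])
        same_chrom = np.flatnonzero(smap["chrom"].astype(str).to_numpy() == chrom)
        for k in same_chrom:
            if k == j:
                continue
            other = smap.at[int(k), "snp"]
            dist = abs(int(smap.at[int(k), "pos"]) - pos)
            in_window = dist <= window_bp
            both_focal = other in focal_set
            if not in_window and not both_focal:
                continue
            key = tuple(sorted((s, other)))
            if both_focal and key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "snp_a": s,
                    "snp_b": other,
                    "chrom": chrom,
                    "dist_bp": dist,
                    "r2": ld_r2(G.calls[:, j], G.calls[:, int(k)]),
                    "fisher_p": ld_fisher_p(G.calls[:, j], G.calls[:, int(k)]),
                }
            )
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "chrom", "dist_bp", "r2", "fisher_p"])
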