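"""Genotype containers, SNP filters, imputation and genomic relationship matrices.

Genotypes of fully inbred lines are coded 0 (homozygous major allele) and 2
(homozygous minor allele); missing calls are ``numpy.nan``.  Heterozygous
calls do not occur in an inbred panel and are rejected (or optionally set
missing) on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "compute_maf",
    "filter_snps",
    "impute_mode",
    "vanraden_grm",
    "loco_grm",
    "read_vcf",
    "write_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_kinship_tsv",
    "write_kinship_tsv",
]


@dataclass
class GenotypeMatrix:
    """Lines x SNPs genotype matrix with a physical SNP map.

    Parameters
    ----------
    calls
        Float array of shape ``(n_lines, n_snps)`` with values in
        ``{0.0, 2.0, nan}``.
    line_ids
        Unique line identifiers, one per row.
    snp_map
        DataFrame with columns ``snp`` (identifier), ``chrom`` (string label)
        and ``pos`` (1-based bp), sorted by (chrom, pos), one row per column
        of ``calls``.
    """

    calls: np.ndarray
    line_ids: list[str]
    snp_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (lines x SNPs)")
        if self.calls.shape[0] != len(self.line_ids):
            raise ValueError("line_ids length does not match calls rows")
        if self.calls.shape[1] != len(self.snp_map):
            raise ValueError("snp_map length does not match calls columns")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        ok = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 2.0)
        if not ok.all():
            raise ValueError("genotype calls must be in {0, 2, missing}")
        self.snp_map = self.snp_map.reset_index(drop=True)
        # chromosomes must form contiguous runs with positions sorted within;
        # chromosome labels are strings, so lexicographic order is not imposed
        chrom = self.snp_map["chrom"].astype(str).to_numpy()
        runs = chrom[np.r_[True, chrom[1:] != chrom[:-1]]] if len(chrom) else chrom
        if len(set(runs)) != len(runs):
            raise ValueError("snp_map chromosomes must be contiguous")
        pos = self.snp_map["pos"].to_numpy()
        for c in set(runs):
            pc = pos[chrom == c]
            if np.any(np.diff(pc) < 0):
                raise ValueError(f"snp_map positions not sorted on chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.snp_map["chrom"].astype(str)))

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order."""
        return GenotypeMatrix(
            self.calls[:, index],
            list(self.line_ids),
            self.snp_map.iloc[np.asarray(index)].reset_index(drop=True),
        )


@dataclass
class KinshipMatrix:
    """Symmetric line-by-line genomic relationship matrix."""

    values: np.ndarray
    line_ids: list[str]
    excluded_chromosome: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def is_psd(self, tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        return bool(w.min() >= -tol)


def compute_maf(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP minor-allele frequency and missing-call rate.

    The allele frequency is ``p = mean(calls)/2`` over non-missing calls and
    ``maf = min(p, 1 - p)``.  SNPs with every call missing get ``maf = nan``.
    """
    calls = G.calls
    n_obs = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = np.nan
    out = G.snp_map.copy()
    out["maf"] = maf
    out["missing_rate"] = 1.0 - n_obs / calls.shape[0]
    return out


def filter_snps(
    G: GenotypeMatrix, maf_min: float = 0.025, missing_max: float = 0.20
) -> GenotypeMatrix:
    """Drop SNPs with ``maf < maf_min`` or ``missing_rate > missing_max``.

    Thresholds are strict on the removal side: a SNP at exactly ``maf_min``
    is retained and one at exactly ``missing_max`` missingness is retained.
    SNPs with no observed calls are always removed.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    info = compute_maf(G)
    keep = (
        (info["maf"].to_numpy() >= maf_min)
        & (info["missing_rate"].to_numpy() <= missing_max)
        & ~np.isnan(info["maf"].to_numpy())
    )
    n_removed = int((~keep).sum())
    logger.info(
        "filter_snps: removed %d of %d SNPs (maf_min=%g, missing_max=%g)",
        n_removed, G.n_snps, maf_min, missing_max,
    )
    if keep.sum() == 0:
        logger.warning("filter_snps: no SNPs retained")
    return G.take_snps(np.flatnonzero(keep))


def impute_mode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the SNP's most frequent non-missing code.

    Ties between the 0 and 2 codes break to the major code 0.  Deterministic.
    Raises if any SNP is entirely missing.
    """
    calls = G.calls.copy()
    miss = np.isnan(calls)
    if not miss.any():
        return G
    n0 = np.sum(calls == 0.0, axis=0)
    n2 = np.sum(calls == 2.0, axis=0)
    if np.any((n0 + n2) == 0):
        raise ValueError("cannot impute: SNP with all calls missing")
    mode = np.where(n2 > n0, 2.0, 0.0)  # tie -> major code 0
    calls[miss] = np.broadcast_to(mode, calls.shape)[miss]
    return GenotypeMatrix(calls, list(G.line_ids), G.snp_map.copy())


def _vanraden(calls: np.ndarray) -> np.ndarray:
    p = calls.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if poly.sum() < 1 or denom <= 0.0:
        raise ValueError("kinship undefined: no polymorphic SNPs")
    W = calls[:, poly] - 2.0 * p[poly]
    return (W @ W.T) / denom


def vanraden_grm(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix K = WW' / (2 * sum p_j (1-p_j)).

    ``W`` is the allele-frequency-centered call matrix; frequencies are
    computed from the (imputed) panel itself.  Monomorphic SNPs contribute
    nothing and are excluded from both numerator and denominator.  Requires
    imputed (no-missing) input.
    """
    if np.isnan(G.calls).any():
        raise ValueError("vanraden_grm requires imputed genotypes (no missing)")
    return KinshipMatrix(_vanraden(G.calls), list(G.line_ids))


def loco_grm(G: GenotypeMatrix, chromosome: str) -> KinshipMatrix:
    """Leave-one-chromosome-out VanRaden kinship.

    SNPs on ``chromosome`` are excluded before computing the relationship
    matrix, so that a scan on that chromosome is not corrected by the very
    markers being tested.
    """
    if np.isnan(G.calls).any():
        raise ValueError("loco_grm requires imputed genotypes (no missing)")
    chrom = G.snp_map["chrom"].astype(str).to_numpy()
    keep = chrom != str(chromosome)
    if keep.all():
        logger.warning("loco_grm: chromosome %r has no SNPs in the map", chromosome)
    if not keep.any():
        raise ValueError("loco_grm: no SNPs left after excluding the chromosome")
    K = KinshipMatrix(_vanraden(G.calls[:, keep]), list(G.line_ids))
    K.excluded_chromosome = str(chromosome)
    return K


def loco_grms(G: GenotypeMatrix) -> dict[str, KinshipMatrix]:
    """LOCO kinship for every chromosome in the map."""
    if len(G.chromosomes) < 2:
        raise ValueError("LOCO kinship needs at least two chromosomes")
    return {c: loco_grm(G, c) for c in G.chromosomes}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path, het_action: str = "error") -> GenotypeMatrix:
    """Read biallelic SNP genotypes of inbred lines from a VCF file.

    0/0 maps to code 0 and 1/1 to code 2 relative to the REF/ALT listing;
    after reading, the minor allele is defined per SNP from the panel itself
    by :func:`compute_maf`.  ``het_action`` controls heterozygous calls:
    ``"error"`` (default) or ``"missing"``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 present in practice
        return _read_vcf_text(path, het_action)
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, snp, chrom, pos = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown?,3=hom alt
        code = np.full(g.shape, np.nan)
        code[g == 0] = 0.0
        code[g == 3] = 2.0
        if np.any(g == 1):
            if het_action == "error":
                raise ValueError(
                    f"heterozygous call at {var.CHROM}:{var.POS}; inbred panel expected"
                )
            # het_action == "missing": leave as nan
        snp.append(var.ID or f"S{var.CHROM}_{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        rows.append(code)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(line_ids), 0))
    smap = pd.DataFrame({"snp": snp, "chrom": chrom, "pos": pos})
    order = smap.sort_values(["chrom", "pos"]).index.to_numpy()
    return GenotypeMatrix(calls[:, order], line_ids, smap.iloc[order])


def _read_vcf_text(path, het_action: str) -> GenotypeMatrix:
    """Minimal text fallback parser (sites-only, GT first FORMAT field)."""
    line_ids: list[str] = []
    rows, snp, chrom, pos = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                line_ids = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            if "," in f[4]:
                continue
            code = np.full(len(line_ids), np.nan)
            for i, cell in enumerate(f[9:]):
                gt = cell.split(":")[0].replace("|", "/")
                if gt in ("0/0",):
                    code[i] = 0.0
                elif gt in ("1/1",):
                    code[i] = 2.0
                elif gt in ("./.", "."):
                    pass
                else:
                    if het_action == "error":
                        raise ValueError(f"heterozygous call at {f[0]}:{f[1]}")
            snp.append(f[2] if f[2] != "." else f"S{f[0]}_{f[1]}")
            chrom.append(f[0])
            pos.append(int(f[1]))
            rows.append(code)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(line_ids), 0))
    smap = pd.DataFrame({"snp": snp, "chrom": chrom, "pos": pos})
    order = smap.sort_values(["chrom", "pos"]).index.to_numpy()
    return GenotypeMatrix(calls[:, order], line_ids, smap.iloc[order])


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal VCF with homozygous diploid calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in G.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.line_ids)
            + "\n"
        )
        for j, row in G.snp_map.iterrows():
            calls = G.calls[:, j]
            gts = np.where(
                np.isnan(calls), "./.", np.where(calls == 0.0, "0/0", "1/1")
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_matrix_tsv(G: GenotypeMatrix, path, map_path=None) -> None:
    """Write the call matrix as TSV (lines x SNPs) plus an optional map sidecar."""
    df = pd.DataFrame(G.calls, index=G.line_ids, columns=G.snp_map["snp"])
    df.to_csv(path, sep="\t", index_label="line")
    if map_path is not None:
        G.snp_map.to_csv(map_path, sep="\t", index=False)


def read_matrix_tsv(path, map_path) -> GenotypeMatrix:
    """Read a lines x SNPs TSV matrix with a sidecar SNP map file."""
    df = pd.read_csv(path, sep="\t", index_col="line")
    smap = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    calls = df.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(df.columns)}
    order = smap.sort_values(["chrom", "pos"]).reset_index(drop=True)
    idx = [cols[s] for s in order["snp"]]
    return GenotypeMatrix(calls[:, idx], [str(i) for i in df.index], order)


def write_kinship_tsv(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids).to_csv(
        path, sep="\t", index_label="line"
    )


def read_kinship_tsv(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line")
    return KinshipMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])
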