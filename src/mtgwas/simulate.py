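"""Synthetic sorghum-style association panel and designed-trial generator.

The generator emulates a diverse inbred mapping panel: ~272 fully inbred
lines genotyped on 10 chromosomes with a tunable linkage-disequilibrium
extent (~150 kb), a small number of pleiotropic QTL, a factor-analytic
between-trait genetic covariance, and plot-level phenotypes from the three
stage-1 designs (lattice with replicates and incomplete blocks plus checks;
randomized complete blocks; augmented blocks with repeated checks).

LD is produced by founder-mosaic copying: each simulated chromosome is a
mosaic of founder haplotypes with exponentially distributed segment lengths.
For segment-length mean ``L`` the genotypic correlation between two sites a
distance ``d`` apart decays as ``exp(-d/L)`` times the founder-pool
correlation, so the r^2 correlogram decays as ``exp(-2d/L)``.  The
``ld_segment_bp`` parameter is therefore interpreted as the *target r^2
e-folding distance* and the internal breakpoint rate is ``1/(2*ld_segment_bp)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, vanraden_grm

__all__ = [
    "SimConfig",
    "DesignSpec",
    "StudyData",
    "simulate_genotypes",
    "simulate_genetic_values",
    "simulate_trial",
    "simulate_study",
    "default_study_config",
    "compact_study_config",
    "STUDY_TRAITS",
]


@dataclass
class DesignSpec:
    """Field/phenotyping design for one simulated experiment.

    kind
        ``"lattice"`` — replicates of incomplete blocks, fixed checks in every
        block; ``"rcbd"`` — complete blocks (block == replicate); ``"augmented"``
        — unreplicated test lines in blocks that each carry the repeated checks.
    """

    kind: str = "rcbd"
    n_reps: int = 3
    n_blocks: int = 14          # augmented: blocks; lattice: blocks per replicate
    block_size: int = 11        # lattice: entries per incomplete block (incl. checks)
    checks: tuple[str, ...] = ()
    sigma_rep: float = 0.0
    sigma_block: float = 0.5
    sigma_e: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("lattice", "rcbd", "augmented"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        for v in (self.sigma_rep, self.sigma_block, self.sigma_e):
            if v < 0:
                raise ValueError("variance components must be >= 0")


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    ``qtl_list`` holds ``(snp_index, effect_vector)`` pairs: the per-trait
    additive effects of the {0,2}-coded genotype at that SNP.  ``sigma_T_true``
    is the polygenic between-trait genetic covariance and ``sigma_R_true`` the
    per-trait residual (non-genetic) variances added on top of the genetic
    values when line-level trait values are drawn directly.
    """

    n_lines: int = 272
    n_chrom: int = 10
    chrom_length_bp: int = 60_000_000
    snps_per_chrom: int = 500
    n_founders: int = 24
    ld_segment_bp: float = 150_000.0
    maf_min: float = 0.05
    qtl_list: list[tuple[int, np.ndarray]] = field(default_factory=list)
    sigma_T_true: np.ndarray | None = None
    sigma_R_true: np.ndarray | None = None
    design: DesignSpec = field(default_factory=DesignSpec)
    missing_geno_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_T_true is not None:
            S = np.asarray(self.sigma_T_true, dtype=float)
            if not np.allclose(S, S.T):
                raise ValueError("sigma_T_true must be symmetric")
            if np.linalg.eigvalsh(S).min() < -1e-8:
                raise ValueError("sigma_T_true must be PSD")
            self.sigma_T_true = S
        if self.sigma_R_true is not None:
            r = np.asarray(self.sigma_R_true, dtype=float)
            if (r < 0).any():
                raise ValueError("sigma_R_true must be >= 0")
            self.sigma_R_true = r

    @property
    def n_traits(self) -> int:
        if self.sigma_T_true is not None:
            return self.sigma_T_true.shape[0]
        if self.qtl_list:
            return len(np.atleast_1d(self.qtl_list[0][1]))
        return 1


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # one global seed; independent substreams per purpose (crc32 is stable
    # across processes, unlike the builtin str hash)
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def _sample_positions(
    rng: np.random.Generator, length_bp: int, n: int
) -> np.ndarray:
    """Distinct sorted 1-based positions without materializing the full range."""
    if n > length_bp:
        raise ValueError("more SNPs than base pairs")
    pos: np.ndarray = np.unique(rng.integers(0, length_bp, size=int(n * 1.3) + 8))
    while pos.size < n:
        extra = rng.integers(0, length_bp, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    pos = rng.permutation(pos)[:n]
    return np.sort(pos) + 1


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate an inbred panel as founder-haplotype mosaics.

    Founder alleles are iid Bernoulli(1/2) per site; each line copies founder
    segments whose lengths are exponential with mean ``2 * ld_segment_bp``
    (see module docstring).  SNPs with panel MAF below ``cfg.maf_min`` are
    dropped.  Optional missing calls are injected uniformly at random.
    """
    if cfg.n_lines < 1:
        raise ValueError("degenerate panel: n_lines must be >= 1")
    if cfg.n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if cfg.snps_per_chrom < 1:
        raise ValueError("snps_per_chrom must be >= 1")
    rng = _rng(cfg, "genotypes")
    seg_mean = 2.0 * float(cfg.ld_segment_bp)
    all_calls, snp, chrom, pos = [], [], [], []
    for c in range(1, cfg.n_chrom + 1):
        positions = _sample_positions(rng, cfg.chrom_length_bp, cfg.snps_per_chrom)
        founders = rng.integers(0, 2, size=(cfg.n_founders, cfg.snps_per_chrom))
        hap = np.empty((cfg.n_lines, cfg.snps_per_chrom), dtype=np.int64)
        for i in range(cfg.n_lines):
            # mosaic walk: breakpoints at exponential spacings along the chromosome
            if np.isinf(seg_mean):
                hap[i, :] = rng.integers(cfg.n_founders)
                continue
            n_seg = int(cfg.chrom_length_bp / seg_mean * 2) + 12
            breaks = np.cumsum(rng.exponential(seg_mean, size=n_seg))
            while breaks[-1] < cfg.chrom_length_bp:
                more = breaks[-1] + np.cumsum(rng.exponential(seg_mean, size=n_seg))
                breaks = np.concatenate([breaks, more])
            fs = rng.integers(0, cfg.n_founders, size=len(breaks) + 1)
            hap[i] = fs[np.searchsorted(breaks, positions)]
        calls = 2.0 * founders[hap, np.arange(cfg.snps_per_chrom)]
        all_calls.append(calls)
        chrom.extend([str(c)] * cfg.snps_per_chrom)
        pos.extend(positions.tolist())
        snp.extend([f"S{c}_{p}" for p in positions])
    calls = np.concatenate(all_calls, axis=1)
    if np.all(calls == calls[0, :]):
        raise ValueError("degenerate panel: all founders identical at every site")
    smap = pd.DataFrame({"snp": snp, "chrom": chrom, "pos": pos})
    # MAF screen on the realized panel
    p = calls.mean(axis=0) / 2.0
    keep = np.minimum(p, 1 - p) >= cfg.maf_min
    calls, smap = calls[:, keep], smap.loc[keep].reset_index(drop=True)
    if cfg.missing_geno_rate > 0:
        miss = _rng(cfg, "geno-missing").random(calls.shape) < cfg.missing_geno_rate
        calls = calls.astype(float)
        calls[miss] = np.nan
    line_ids = [f"L{i:04d}" for i in range(cfg.n_lines)]
    return GenotypeMatrix(calls.astype(float), line_ids, smap)


def simulate_genetic_values(G: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """True genetic values: QTL effects plus a correlated polygenic background.

    Returns an ``n_lines x n_traits`` matrix ``X A + U`` where ``X`` are the
    centered QTL genotype columns, ``A`` the per-trait effect vectors, and
    ``vec(U)`` is drawn with covariance ``K_x_Sigma_T`` using the panel's own
    VanRaden kinship (small ridge added for factorization).
    """
    T = cfg.n_traits
    n = G.n_lines
    values = np.zeros((n, T))
    for snp_idx, alpha in cfg.qtl_list:
        if not 0 <= snp_idx < G.n_snps:
            raise ValueError("qtl snp index outside SNP map")
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        if alpha.shape[0] != T:
            raise ValueError("QTL effect vector length must equal the trait count")
        x = G.calls[:, snp_idx].copy()
        x[np.isnan(x)] = np.nanmean(x)
        values += np.outer(x - x.mean(), alpha)
    if cfg.sigma_T_true is not None and np.any(cfg.sigma_T_true != 0):
        rng = _rng(cfg, "polygenic")
        K = vanraden_grm(G if not np.isnan(G.calls).any() else _mean_impute(G)).values
        Lk = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        wT, VT = np.linalg.eigh(cfg.sigma_T_true)
        Lt = VT @ np.diag(np.sqrt(np.clip(wT, 0, None)))
        U = Lk @ rng.standard_normal((n, T)) @ Lt.T
        values += U - U.mean(axis=0)
    return values


def _mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    from .genotypes import impute_mode

    return impute_mode(G)


def simulate_trial(
    values: pd.Series | np.ndarray,
    design: DesignSpec,
    line_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    trait: str = "trait",
    check_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Plot-level records ``y = mu + rep + block + check/line + e`` for one trait.

    ``values`` are the simulated true line values (Series indexed by line id,
    or an array with ``line_ids``).  Returns a DataFrame with columns
    ``line, rep, block, is_check, trait, value``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(values, pd.Series):
        line_ids = [str(i) for i in values.index]
        vals = values.to_numpy(dtype=float)
    else:
        vals = np.asarray(values, dtype=float).ravel()
        if line_ids is None:
            line_ids = [f"L{i:04d}" for i in range(len(vals))]
        line_ids = [str(i) for i in line_ids]
    value_of = dict(zip(line_ids, vals))
    if check_values is None:
        check_values = {c: 0.0 for c in design.checks}
    value_of.update(check_values)

    rows: list[tuple[str, str, str, bool]] = []  # line, rep, block, is_check
    if design.kind == "rcbd":
        for j in range(1, design.n_reps + 1):
            for lid in line_ids:
                rows.append((lid, f"rep{j}", f"rep{j}", False))
    elif design.kind == "lattice":
        n_checks = len(design.checks)
        per_block = design.block_size - n_checks
        if per_block < 1:
            raise ValueError("block_size must exceed the number of checks")
        capacity = per_block * design.n_blocks
        if len(line_ids) > capacity:
            raise ValueError(
                f"more lines ({len(line_ids)}) than design capacity ({capacity})"
            )
        for j in range(1, design.n_reps + 1):
            order = rng.permutation(len(line_ids))
            for b in range(design.n_blocks):
                blk = f"rep{j}:b{b + 1}"
                for lid in design.checks:
                    rows.append((lid, f"rep{j}", blk, True))
                for k in order[b * per_block : (b + 1) * per_block]:
                    rows.append((line_ids[k], f"rep{j}", blk, False))
    else:  # augmented
        if design.n_blocks < 1:
            raise ValueError("augmented design needs >= 1 block")
        if len(design.checks) < 1:
            raise ValueError("augmented design needs >= 1 check")
        order = rng.permutation(len(line_ids))
        splits = np.array_split(order, design.n_blocks)
        for b, members in enumerate(splits, start=1):
            blk = f"b{b}"
            for lid in design.checks:
                rows.append((lid, "rep1", blk, True))
            for k in members:
                rows.append((line_ids[k], "rep1", blk, False))

    df = pd.DataFrame(rows, columns=["line", "rep", "block", "is_check"])
    rep_eff = {
        r: rng.normal(0.0, design.sigma_rep) if design.sigma_rep > 0 else 0.0
        for r in df["rep"].unique()
    }
    blk_eff = {
        b: rng.normal(0.0, design.sigma_block) if design.sigma_block > 0 else 0.0
        for b in df["block"].unique()
    }
    noise = (
        rng.normal(0.0, design.sigma_e, size=len(df)) if design.sigma_e > 0 else 0.0
    )
    df["trait"] = trait
    df["value"] = (
        df["line"].map(value_of).to_numpy(dtype=float)
        + df["rep"].map(rep_eff).to_numpy(dtype=float)
        + df["block"].map(blk_eff).to_numpy(dtype=float)
        + noise
    )
    if design.missing_rate > 0:
        drop = rng.random(len(df)) < design.missing_rate
        df = df.loc[~drop].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------

#: Trait panel of the emulated study: grain yield from a replicated lattice
#: in a low-P field; 2D root morphology (surface area, diameter) and seedling
#: performance (shoot dry weight, shoot P content) from an RCBD in low-P
#: hydroponics; 3D architecture (centroid, median roots, convex hull) from an
#: augmented design.  The two right-skewed 3D volume/count traits are carried
#: on the observation scale and log-transformed in stage 1.
STUDY_TRAITS = ("GY", "SA", "RD", "SDW", "SPCnt", "Cent", "MedR", "CH")
_LOG_TRAITS = ("MedR", "CH")


def _study_sigma_T() -> np.ndarray:
    """Genetic covariance for the eight traits: a two-factor structure.

    Factor 1 is a broad root-vigor axis (root morphology/architecture and
    seedling performance load together, grain yield weakly); factor 2
    separates root diameter (negatively related to shoot traits).  The
    implied genetic correlations are moderate (~0.4-0.6 among architecture
    traits, strong SDW-SPCnt, weak GY-root links).
    """
    #            GY    SA    RD    SDW  SPCnt  Cent  MedR   CH
    lam1 = np.array([0.25, 0.65, 0.30, 0.70, 0.75, 0.55, 0.60, 0.60])
    lam2 = np.array([0.00, 0.20, -0.55, 0.35, 0.25, -0.10, 0.15, 0.10])
    psi = np.array([0.80, 0.35, 0.40, 0.25, 0.25, 0.55, 0.45, 0.45])
    S = np.outer(lam1, lam1) + np.outer(lam2, lam2) + np.diag(psi)
    return S


def _study_designs() -> dict[str, DesignSpec]:
    lattice = DesignSpec(kind="lattice", n_reps=3, n_blocks=31, block_size=11,
                         checks=("ATF13", "ATF14"), sigma_rep=0.3,
                         sigma_block=0.45, sigma_e=0.65)
    rcbd = DesignSpec(kind="rcbd", n_reps=3, sigma_block=0.4, sigma_e=0.7)
    augmented = DesignSpec(kind="augmented", n_blocks=14,
                           checks=("ATF8", "ATF10"), sigma_block=0.45,
                           sigma_e=0.8)
    return {
        "GY": lattice,
        "SA": rcbd, "RD": rcbd, "SDW": rcbd, "SPCnt": rcbd,
        "Cent": augmented, "MedR": augmented, "CH": augmented,
    }


def default_study_config(seed: int = 0, n_qtl: int = 5,
                         snps_per_chrom: int = 500) -> SimConfig:
    """Study-scale configuration: 272 lines, 10 chromosomes, 150-kb LD,
    eight correlated traits and a handful of pleiotropic QTL.

    QTL columns are chosen deterministically from the seed, spread over
    distinct chromosomes, with effects on overlapping trait subsets (shared
    favorable alleles, as in a pleiotropic root-vigor architecture).
    """
    cfg = SimConfig(
        n_lines=272,
        n_chrom=10,
        chrom_length_bp=60_000_000,
        snps_per_chrom=snps_per_chrom,
        ld_segment_bp=150_000.0,
        maf_min=0.05,
        sigma_T_true=_study_sigma_T(),
        seed=seed,
        qtl_list=[],  # filled against the realized map by simulate_study
    )
    cfg._n_qtl = n_qtl  # QTL count rides along until the map is realized
    return cfg


@dataclass
class StudyData:
    """A complete simulated study: panel, truth and plot-level phenotypes."""

    cfg: SimConfig
    genotypes: "GenotypeMatrix"
    genetic_values: pd.DataFrame             # line x trait, latent scale
    trials: dict[str, tuple[pd.DataFrame, DesignSpec, bool]]
    qtl: pd.DataFrame                        # snp, chrom, pos plus effect_<trait>


def _plant_qtls(G, cfg: SimConfig, n_qtl: int, trait_names,
                rng: np.random.Generator, effect_size: float = 0.45):
    """Pick QTL columns on distinct chromosomes with common MAF and assign
    pleiotropic effect vectors touching 2-4 correlated traits each."""
    T = len(trait_names)
    p = G.calls.mean(axis=0) / 2.0
    chrom = G.snp_map["chrom"].astype(str).to_numpy()
    chroms = list(dict.fromkeys(chrom))
    pick_chroms = [chroms[i % len(chroms)] for i in range(n_qtl)]
    qtl_list = []
    sizes = [3, 3, 2, 4, 3]  # pleiotropy degree cycles over QTLs
    for q, c in enumerate(pick_chroms):
        cand = np.flatnonzero((chrom == c) & (np.minimum(p, 1 - p) >= 0.2))
        if len(cand) == 0:
            cand = np.flatnonzero(chrom == c)
        j = int(rng.choice(cand))
        alpha = np.zeros(T)
        # overlapping consecutive trait subsets so every trait is touched
        size = min(sizes[q % len(sizes)], T)
        for k in range(size):
            alpha[(2 * q + k) % T] = effect_size * (0.8 + 0.4 * rng.random())
        qtl_list.append((j, alpha))
    return qtl_list


def simulate_study(
    cfg: SimConfig | None = None,
    seed: int | None = None,
    trait_names: tuple[str, ...] = STUDY_TRAITS,
    designs: dict[str, DesignSpec] | None = None,
    n_qtl: int = 5,
) -> StudyData:
    """Simulate the whole designed study emulated by this package.

    Genotypes are drawn first; QTL columns are then planted against the
    realized SNP map, genetic values generated with the factor-structured
    trait covariance, and plot-level trials simulated per trait under its
    design.  Log-scale traits are exponentiated so the stage-1 analysis sees
    them on the observation scale.
    """
    if cfg is None:
        cfg = default_study_config(seed=0 if seed is None else seed, n_qtl=n_qtl)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if designs is None:
        designs = _study_designs()
    T = len(trait_names)
    if cfg.sigma_T_true is None or cfg.sigma_T_true.shape[0] != T:
        raise ValueError("sigma_T_true must match the trait panel")

    G = simulate_genotypes(cfg)
    rng = _rng(cfg, "study")
    n_qtl = getattr(cfg, "_n_qtl", n_qtl) or n_qtl
    if not cfg.qtl_list and n_qtl:
        cfg = replace(cfg, qtl_list=_plant_qtls(G, cfg, n_qtl, trait_names, rng))
    vals = simulate_genetic_values(G, cfg)
    values = pd.DataFrame(vals, index=G.line_ids, columns=list(trait_names))

    trials: dict[str, tuple[pd.DataFrame, DesignSpec, bool]] = {}
    for t, trait in enumerate(trait_names):
        design = designs[trait]
        rec = simulate_trial(values[trait], design, rng=rng, trait=trait)
        log_it = trait in _LOG_TRAITS
        if log_it:
            rec = rec.assign(value=np.exp(rec["value"]))
        trials[trait] = (rec, design, log_it)

    qtl_rows = []
    for j, alpha in cfg.qtl_list:
        row = dict(G.snp_map.iloc[j])
        for t, trait in enumerate(trait_names):
            row[f"effect_{trait}"] = alpha[t] if t < len(alpha) else 0.0
        qtl_rows.append(row)
    return StudyData(cfg=cfg, genotypes=G, genetic_values=values,
                     trials=trials, qtl=pd.DataFrame(qtl_rows))


def compact_study_config(
    seed: int = 0,
    n_lines: int = 200,
    n_chrom: int = 4,
    snps_per_chrom: int = 500,
    n_traits: int = 4,
    n_qtl: int = 3,
) -> SimConfig:
    """Desk-scale study preset: a 200-line, 2,000-SNP, four-trait panel with
    three planted pleiotropic QTL (used by the examples and the test suite).

    Traits and designs are the leading subset of the full study panel.
    """
    S = _study_sigma_T()[:n_traits, :n_traits]
    cfg = SimConfig(
        n_lines=n_lines, n_chrom=n_chrom, chrom_length_bp=60_000_000,
        snps_per_chrom=snps_per_chrom, sigma_T_true=S, seed=seed,
    )
    cfg._n_qtl = n_qtl
    return cfg
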