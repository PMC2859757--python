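"""Synthetic multi-chromosome genotype panels with controllable LD.

The generator is a two-layer haplotype-copying model:

1. *Founder haplotypes.*  Each chromosome carries a pool of founder
   haplotypes whose alleles are drawn through a latent Gaussian AR(1)
   copula: allele frequencies follow the requested MAF spectrum, and the
   latent correlation between loci decays as exp(-d / founder_corr_length_bp),
   standing in for ancestral recombination.  This gives strong local LD
   regardless of the pool size, so the pool can be large enough to express
   rare allele frequencies.
2. *Gametes.*  Each gamete copies founder templates along the chromosome,
   switching to a uniformly chosen template at recombination breakpoints
   (Poisson with rate ``recomb_rate_per_bp``), which adds distance decay on
   top of the founder structure.  Diploids are two independent gametes;
   on an all-male X chromosome a single gamete is doubled (hemizygous
   convention).

A configured fraction of SNPs is emitted without map data (statuses
ambiguous / un_scaffold / unaligned); un_scaffold SNPs are grouped into
scaffolds built from contiguous runs with a random orientation.  The truth
table records the real location of every SNP, so the generator backs every
audit with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, ScaffoldTable, SnpRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "expected_r2_profile",
    "inject_translocation",
    "inject_duplicated_segment",
    "make_perfect_proxy_panel",
]

#: MAF classes: common (0.05, 0.5], low (0.01, 0.05], rare (0.001, 0.01]
_MAF_CLASSES = ((0.05, 0.5), (0.01, 0.05), (0.001, 0.01))
# split of non-scaffold unpositioned SNPs into ambiguous vs unaligned
_AMBIGUOUS_SHARE = 0.65


@dataclass(frozen=True)
class SimConfig:
    """Panel-generator settings; ``seed`` fully determines the output."""

    n_chromosomes: int = 5
    snps_per_chromosome: int = 400
    chromosome_length_bp: int = 25_000_000
    n_founder_haplotypes: int = 100
    n_individuals: int = 300
    recomb_rate_per_bp: float = 1e-8
    founder_corr_length_bp: float = 1_500_000.0
    maf_spectrum: tuple[float, float, float] = (0.75, 0.15, 0.10)
    missing_rate: float = 0.02
    fraction_unpositioned: float = 0.08
    fraction_on_scaffolds: float = 0.33
    x_chromosome: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_rate", "fraction_unpositioned", "fraction_on_scaffolds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.maf_spectrum) - 1.0) > 1e-9 or min(self.maf_spectrum) < 0:
            raise ValueError("maf_spectrum must be non-negative weights summing to 1")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1 or self.n_individuals < 1:
            raise ValueError("counts must be positive")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")


@dataclass
class SimTruth:
    """Ground truth: real location and status provenance of every SNP."""

    frame: pd.DataFrame  # snp_id, chromosome, position_bp, status, scaffold_id
    orientations: dict[str, str] = field(default_factory=dict)

    def true_location(self, snp_id: str) -> tuple[str, int]:
        row = self.frame.loc[self.frame.snp_id == snp_id].iloc[0]
        return str(row.chromosome), int(row.position_bp)


def _draw_freqs(rng: np.random.Generator, m: int, weights) -> np.ndarray:
    cls = rng.choice(len(_MAF_CLASSES), size=m, p=np.asarray(weights, dtype=float))
    lo = np.array([c[0] for c in _MAF_CLASSES])[cls]
    hi = np.array([c[1] for c in _MAF_CLASSES])[cls]
    return lo + rng.random(m) * (hi - lo)


def _founder_haplotypes(rng, k: int, positions: np.ndarray, freqs: np.ndarray, corr_len: float):
    """Latent Gaussian AR(1) founders: P(allele=1 at locus j) = freqs[j]."""
    from scipy.stats import norm

    m = len(positions)
    x = np.empty((k, m))
    x[:, 0] = rng.standard_normal(k)
    d = np.diff(positions).astype(float)
    rho = np.exp(-d / corr_len) if corr_len > 0 else np.zeros_like(d)
    for j in range(1, m):
        x[:, j] = rho[j - 1] * x[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * rng.standard_normal(k)
    z = norm.ppf(freqs)
    return (x < z[None, :]).astype(np.int8)


def _copy_gametes(rng, founders: np.ndarray, positions: np.ndarray, n_gametes: int, rate: float):
    k, m = founders.shape
    templ = np.empty((n_gametes, m), dtype=np.int32)
    templ[:, 0] = rng.integers(k, size=n_gametes)
    d = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-rate * d)
    for j in range(1, m):
        switch = rng.random(n_gametes) < p_switch[j - 1]
        templ[:, j] = np.where(switch, rng.integers(k, size=n_gametes), templ[:, j - 1])
    return founders[templ, np.arange(m)[None, :]]


def _positions(rng, m: int, length: int) -> np.ndarray:
    pool = np.unique(rng.integers(1, length + 1, size=max(2 * m, m + 100)))
    while len(pool) < m:
        pool = np.unique(np.concatenate([pool, rng.integers(1, length + 1, size=m)]))
    pick = rng.permutation(len(pool))[:m]
    return np.sort(pool[pick])


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, ScaffoldTable, SimTruth]:
    """Generate a panel, its scaffold table and the ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_individuals

    chrom_names = [str(c + 1) for c in range(cfg.n_chromosomes)]
    if cfg.x_chromosome:
        chrom_names[-1] = "X"

    cols, col_chrom, col_pos, x_flags = [], [], [], []
    for chrom in chrom_names:
        m = cfg.snps_per_chromosome
        positions = _positions(rng, m, cfg.chromosome_length_bp)
        freqs = _draw_freqs(rng, m, cfg.maf_spectrum)
        founders = _founder_haplotypes(
            rng, cfg.n_founder_haplotypes, positions, freqs, cfg.founder_corr_length_bp
        )
        if chrom == "X":
            hap = _copy_gametes(rng, founders, positions, n_ind, cfg.recomb_rate_per_bp)
            dosage = (2 * hap).astype(np.int8)
        else:
            hap = _copy_gametes(rng, founders, positions, 2 * n_ind, cfg.recomb_rate_per_bp)
            dosage = (hap[0::2] + hap[1::2]).astype(np.int8)
        cols.append(dosage)
        col_chrom.extend([chrom] * m)
        col_pos.extend(positions.tolist())
        x_flags.extend([chrom == "X"] * m)

    dosage = np.concatenate(cols, axis=1)
    n_snps = dosage.shape[1]
    snp_ids = [f"snp_{c}_{p}" for c, p in zip(col_chrom, col_pos)]
    missing = rng.random(dosage.shape) < cfg.missing_rate

    # choose which SNPs lose their map data
    n_unpos = int(round(cfg.fraction_unpositioned * n_snps))
    n_scaf = int(round(cfg.fraction_on_scaffolds * n_unpos))
    status = np.array(["mapped"] * n_snps, dtype=object)
    scaffold_of = np.array([None] * n_snps, dtype=object)
    offset_of = np.array([None] * n_snps, dtype=object)

    table = ScaffoldTable()
    orientations: dict[str, str] = {}
    taken = np.zeros(n_snps, dtype=bool)
    scaf_members: list[np.ndarray] = []
    placed = 0
    guard = 0
    while placed < n_scaf and guard < 50 * (n_scaf + 1):
        guard += 1
        run = int(rng.integers(1, 6))
        run = min(run, n_scaf - placed)
        start = int(rng.integers(0, n_snps - run))
        idx = np.arange(start, start + run)
        if taken[idx].any() or len({col_chrom[i] for i in idx}) != 1:
            continue
        taken[idx] = True
        scaf_members.append(idx)
        placed += run
    for s_num, idx in enumerate(scaf_members):
        sid = f"scaffold_{s_num:04d}"
        pos = np.array([col_pos[i] for i in idx])
        margin = int(rng.integers(1_000, 10_000))
        length = int(pos.max() - pos.min()) + 2 * margin
        orient = "forward" if rng.random() < 0.5 else "reverse"
        orientations[sid] = orient
        for i in idx:
            if orient == "forward":
                off = int(col_pos[i] - pos.min()) + margin
            else:
                off = int(pos.max() - col_pos[i]) + margin
            status[i] = "un_scaffold"
            scaffold_of[i] = sid
            offset_of[i] = off
            table.add(sid, length, snp_ids[i], off)

    free = np.flatnonzero(~taken)
    n_rest = n_unpos - int(taken.sum())
    rest = rng.choice(free, size=max(n_rest, 0), replace=False)
    n_amb = int(round(_AMBIGUOUS_SHARE * len(rest)))
    for i in rest[:n_amb]:
        status[i] = "ambiguous"
    for i in rest[n_amb:]:
        status[i] = "unaligned"

    records = []
    for j in range(n_snps):
        st = status[j]
        records.append(
            SnpRecord(
                snp_id=snp_ids[j],
                status=st,
                chromosome=col_chrom[j] if st == "mapped" else None,
                position_bp=col_pos[j] if st == "mapped" else None,
                scaffold_id=scaffold_of[j],
                scaffold_offset_bp=offset_of[j],
            )
        )
    matrix = GenotypeMatrix(
        [f"ind_{i:04d}" for i in range(n_ind)],
        records,
        dosage,
        missing,
        np.array(x_flags, dtype=bool),
    )
    truth = SimTruth(
        frame=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chromosome": col_chrom,
                "position_bp": col_pos,
                "status": status,
                "scaffold_id": scaffold_of,
            }
        ),
        orientations=orientations,
    )
    return matrix, table, truth


def expected_r2_profile(
    cfg: SimConfig, distances, n_reps: int = 400, internal_seed: int = 987_654_321
) -> list[float]:
    """Monte-Carlo mean r² vs bp distance under the generator (fixed seed).

    Intended for calibrating configs so that LD decays within a chromosome.
    """
    from .ld import _em_kernel

    cfg.validate()
    out = []
    for d in distances:
        rng = np.random.default_rng((internal_seed, int(d)))
        k = cfg.n_founder_haplotypes
        rho = (
            np.exp(-float(d) / cfg.founder_corr_length_bp)
            if cfg.founder_corr_length_bp > 0
            else 0.0
        )
        p_switch = 1.0 - np.exp(-cfg.recomb_rate_per_bp * float(d))
        from scipy.stats import norm

        freqs = _draw_freqs(rng, 2 * n_reps, cfg.maf_spectrum).reshape(n_reps, 2)
        if d == 0:
            freqs[:, 1] = freqs[:, 0]  # distance 0 is the same locus duplicated
        x1 = rng.standard_normal((n_reps, k))
        x2 = rho * x1 + np.sqrt(1 - rho**2) * rng.standard_normal((n_reps, k))
        a1 = x1 < norm.ppf(freqs[:, 0])[:, None]
        a2 = x2 < norm.ppf(freqs[:, 1])[:, None]
        n_gam = 2 * cfg.n_individuals
        t1 = rng.integers(k, size=(n_reps, n_gam))
        switch = rng.random((n_reps, n_gam)) < p_switch
        t2 = np.where(switch, rng.integers(k, size=(n_reps, n_gam)), t1)
        r = np.arange(n_reps)[:, None]
        h1 = a1[r, t1]
        h2 = a2[r, t2]
        d1 = h1[:, 0::2] + h1[:, 1::2]
        d2 = h2[:, 0::2] + h2[:, 1::2]
        code = (d1 * 3 + d2).astype(np.int64)
        tables = np.zeros((n_reps, 9), dtype=np.float64)
        np.add.at(tables, (r, code), 1.0)
        res = _em_kernel(tables.reshape(n_reps, 3, 3))
        vals = res["r2"][res["valid"]]
        out.append(float(np.mean(vals)) if len(vals) else float("nan"))
    return out


# ---------------------------------------------------------------------- #
# constructed fixtures for audits
# ---------------------------------------------------------------------- #

def inject_translocation(
    matrix: GenotypeMatrix,
    truth: SimTruth,
    source_chrom: str,
    target_chrom: str,
    n_snps: int = 5,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Mislabel ``n_snps`` SNPs truly on ``target_chrom`` as a contiguous
    block on ``source_chrom``, emulating a misassembled segment.

    The chosen SNPs are spread widely across ``target_chrom`` (so they are
    nearly unlinked to one another) and re-mapped to consecutive positions
    inside the widest gap of ``source_chrom``.  Truth is left untouched;
    a masked-repositioning audit should recover them as one discordant
    block source_chrom -> target_chrom.
    """
    rng = rng or np.random.default_rng(0)
    tgt = [r for r in matrix.snps if r.is_mapped and r.chromosome == target_chrom]
    src = [r for r in matrix.snps if r.is_mapped and r.chromosome == source_chrom]
    if len(tgt) < 5 * n_snps or len(src) < 2:
        raise ValueError("not enough mapped SNPs to inject a translocation")
    tgt.sort(key=lambda r: r.position_bp)
    picks = [tgt[int(q * (len(tgt) - 1))] for q in np.linspace(0.12, 0.88, n_snps)]

    src_pos = sorted(r.position_bp for r in src)
    gaps = np.diff(src_pos)
    g = int(np.argmax(gaps))
    lo, hi = src_pos[g], src_pos[g + 1]
    new_pos = np.linspace(lo, hi, n_snps + 2)[1:-1].astype(int)
    for rec, p in zip(picks, new_pos):
        rec.chromosome = source_chrom
        rec.position_bp = int(p)
    return [r.snp_id for r in picks]


def inject_duplicated_segment(
    matrix: GenotypeMatrix,
    source_chrom: str,
    dest_chrom: str,
    n_snps: int = 10,
    flip_rate: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """Copy the genotypes of a contiguous segment of ``source_chrom`` over a
    same-sized segment of ``dest_chrom`` plus call noise (``flip_rate``),
    emulating a diverged duplicated segment present on two chromosomes.

    Queries in the source segment then see strong LD on both chromosomes,
    the copy slightly attenuated — the situation the low-MAF 2/3 safeguard
    exists to catch: without it the genuine chromosome usually wins both
    rankings and the SNP is placed despite the competing evidence; with it
    the runner-up's r²_max (within 2/3 of the winner's) vetoes the call.
    A perfectly exact copy would instead produce rank conflicts, which are
    refused even without the safeguard.
    """
    rng = rng or np.random.default_rng(0)
    src = sorted(
        (r for r in matrix.snps if r.is_mapped and r.chromosome == source_chrom),
        key=lambda r: r.position_bp,
    )
    dst = sorted(
        (r for r in matrix.snps if r.is_mapped and r.chromosome == dest_chrom),
        key=lambda r: r.position_bp,
    )
    if len(src) < n_snps or len(dst) < n_snps:
        raise ValueError("not enough mapped SNPs for segment duplication")
    s0 = (len(src) - n_snps) // 2
    d0 = (len(dst) - n_snps) // 2
    src_ids = [r.snp_id for r in src[s0 : s0 + n_snps]]
    dst_ids = [r.snp_id for r in dst[d0 : d0 + n_snps]]
    si = matrix.indices(src_ids)
    di = matrix.indices(dst_ids)
    matrix.dosage[:, di] = matrix.dosage[:, si]
    matrix.missing[:, di] = matrix.missing[:, si]
    flips = rng.random((matrix.n_samples, n_snps)) < flip_rate
    noise = rng.integers(0, 3, size=(matrix.n_samples, n_snps)).astype(np.int8)
    block = matrix.dosage[:, di]
    block[flips] = noise[flips]
    matrix.dosage[:, di] = block
    matrix.refresh_stats()
    return src_ids, dst_ids


def make_perfect_proxy_panel(
    seed: int = 0,
    n_chromosomes: int = 2,
    snps_per_chromosome: int = 120,
    n_individuals: int = 220,
    n_copies: int = 4,
) -> tuple[GenotypeMatrix, SimTruth]:
    """A panel in which every mapped SNP exists in ``n_copies`` identical
    copies at the same map position.

    Any masked copy retains >= n_copies-1 unmasked exact duplicates among
    the anchors, so a masked-repositioning audit must achieve efficiency
    and accuracy of exactly 100% with 0 positional error.  Columns that are
    rare (MAF <= 0.05) or perfectly correlated with another column are
    dropped first so the expectation is exact.
    """
    cfg = SimConfig(
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        chromosome_length_bp=20_000_000,
        n_individuals=n_individuals,
        maf_spectrum=(1.0, 0.0, 0.0),
        missing_rate=0.0,
        fraction_unpositioned=0.0,
        fraction_on_scaffolds=0.0,
        seed=seed,
    )
    base, _, _ = simulate_panel(cfg)

    keep: list[int] = []
    d = base.dosage.astype(np.float64)
    for j, rec in enumerate(base.snps):
        if not (rec.maf > 0.05):
            continue
        dup = False
        for i in keep:
            c = np.corrcoef(d[:, i], d[:, j])[0, 1]
            if abs(c) > 1 - 1e-12:
                dup = True
                break
        if not dup:
            keep.append(j)
    records, cols = [], []
    for j in keep:
        rec = base.snps[j]
        for c in range(n_copies):
            records.append(
                SnpRecord(
                    snp_id=f"{rec.snp_id}_c{c}",
                    status="mapped",
                    chromosome=rec.chromosome,
                    position_bp=rec.position_bp,
                )
            )
            cols.append(base.dosage[:, j])
    matrix = GenotypeMatrix(base.samples, records, np.column_stack(cols))
    truth = SimTruth(
        frame=pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in records],
                "chromosome": [r.chromosome for r in records],
                "position_bp": [r.position_bp for r in records],
                "status": ["mapped"] * len(records),
                "scaffold_id": [None] * len(records),
            }
        )
    )
    return matrix, truth
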