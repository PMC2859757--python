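"""Shared data model: SNP records, genotype panels and scaffold tables.

A panel holds unphased diploid genotypes coded as allele dosage {0, 1, 2}
with an explicit missing mask.  Per-SNP minor-allele frequency and call
counts are always recomputed from the dosage matrix, never trusted from
input metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SnpStatus",
    "SnpRecord",
    "GenotypeMatrix",
    "ScaffoldTable",
    "compute_maf",
    "PanelError",
]

#: the four map-status categories: a unique assembly location, multiple
#: candidate locations, a location on an unordered ("Un") scaffold, or no
#: assembly hit at all.
SnpStatus = ("mapped", "ambiguous", "un_scaffold", "unaligned")


class PanelError(ValueError):
    """Raised for structurally invalid panel input."""


@dataclass
class SnpRecord:
    """Identity and map metadata for one SNP.

    ``status='mapped'`` requires both a chromosome and a 1-based bp
    position; ``status='un_scaffold'`` requires a scaffold id.
    """

    snp_id: str
    status: str = "mapped"
    chromosome: str | None = None
    position_bp: int | None = None
    scaffold_id: str | None = None
    scaffold_offset_bp: int | None = None
    maf: float = float("nan")
    n_called: int = 0

    def __post_init__(self) -> None:
        if self.status not in SnpStatus:
            raise PanelError(f"{self.snp_id}: unknown status {self.status!r}")
        if self.status == "mapped":
            if self.chromosome is None or self.position_bp is None:
                raise PanelError(
                    f"{self.snp_id}: status 'mapped' requires chromosome and position_bp"
                )
            if int(self.position_bp) < 1:
                raise PanelError(f"{self.snp_id}: position_bp must be >= 1 (1-based)")
        elif self.chromosome is not None and self.position_bp is not None:
            # an unpositioned SNP must not silently carry a full map location
            raise PanelError(
                f"{self.snp_id}: status {self.status!r} but chromosome and position both set"
            )
        if self.status == "un_scaffold" and self.scaffold_id is None:
            raise PanelError(f"{self.snp_id}: status 'un_scaffold' requires scaffold_id")

    @property
    def is_mapped(self) -> bool:
        return self.status == "mapped"


class GenotypeMatrix:
    """N individuals x M SNPs dosage matrix with a parallel missing mask.

    Parameters
    ----------
    samples:
        Sample identifiers, length N.
    snps:
        One :class:`SnpRecord` per column, length M.
    dosage:
        Integer array (N, M) with entries in {0, 1, 2}; entries under
        ``missing`` are ignored by every downstream computation.
    missing:
        Boolean array (N, M), True where the call is missing.
    x_flag:
        Boolean array (M,) marking X-chromosome loci.  For X-flagged SNPs
        the panel is assumed to be an all-male (hemizygous) cohort:
        heterozygous calls are set to missing and the remaining calls are
        treated as ordinary diploid homozygotes.
    """

    def __init__(
        self,
        samples: Sequence[str],
        snps: Sequence[SnpRecord],
        dosage: np.ndarray,
        missing: np.ndarray | None = None,
        x_flag: np.ndarray | None = None,
    ) -> None:
        dosage = np.asarray(dosage)
        n, m = dosage.shape
        if len(samples) != n:
            raise PanelError(f"{len(samples)} sample ids for {n} dosage rows")
        if len(snps) != m:
            raise PanelError(f"map lists {len(snps)} SNPs, matrix has {m} columns")
        if missing is None:
            missing = np.zeros((n, m), dtype=bool)
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != dosage.shape:
            raise PanelError("missing mask shape does not match dosage")
        bad = ~np.isin(dosage, (0, 1, 2)) & ~missing
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"non-{{0,1,2}} dosage code {dosage[i, j]!r} at sample row {i}, "
                f"SNP column {j} ({snps[j].snp_id})"
            )
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise PanelError(f"duplicate snp_id(s): {', '.join(dup[:5])}")

        self.samples = list(samples)
        self.snps = list(snps)
        self.dosage = dosage.astype(np.int8, copy=True)
        self.missing = missing.copy()
        self.x_flag = (
            np.zeros(m, dtype=bool) if x_flag is None else np.asarray(x_flag, dtype=bool).copy()
        )
        self.dosage[self.missing] = 0
        self._index = {s.snp_id: j for j, s in enumerate(self.snps)}
        self.apply_x_convention()
        self.refresh_stats()

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def column_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def indices(self, snp_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.column_index(s) for s in snp_ids], dtype=np.intp)

    def record(self, snp_id: str) -> SnpRecord:
        return self.snps[self.column_index(snp_id)]

    def mapped_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps if s.is_mapped]

    def unmapped_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps if not s.is_mapped]

    # -- maintenance ---------------------------------------------------
    def apply_x_convention(self) -> None:
        """Set heterozygous calls on X-flagged loci to missing (male cohort)."""
        if not self.x_flag.any():
            return
        cols = np.flatnonzero(self.x_flag)
        het = self.dosage[:, cols] == 1
        sub = self.missing[:, cols]
        sub |= het
        self.missing[:, cols] = sub
        d = self.dosage[:, cols]
        d[het] = 0
        self.dosage[:, cols] = d

    def refresh_stats(self) -> None:
        """Recompute per-SNP maf and n_called from the dosage matrix."""
        called = ~self.missing
        n_called = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_called)
        maf = np.minimum(p, 1.0 - p)
        for j, rec in enumerate(self.snps):
            rec.n_called = int(n_called[j])
            rec.maf = float(maf[j]) if n_called[j] > 0 else float("nan")


def compute_maf(dosage: np.ndarray, missing: np.ndarray | None = None) -> float:
    """Minor-allele frequency of one dosage column, from non-missing calls only.

    Returns ``min(p, 1-p)`` with ``p = sum(dosage) / (2 * n_called)``.
    Invariant under allele relabelling (d -> 2-d).  Raises on an all-missing
    column.
    """
    dosage = np.asarray(dosage, dtype=float)
    if missing is None:
        missing = np.zeros(dosage.shape, dtype=bool)
    called = ~np.asarray(missing, dtype=bool)
    n = int(called.sum())
    if n == 0:
        raise PanelError("MAF undefined: all calls missing")
    p = dosage[called].sum() / (2.0 * n)
    return float(min(p, 1.0 - p))


@dataclass
class ScaffoldTable:
    """Unordered scaffolds: id -> length plus member SNPs with offsets."""

    lengths: dict[str, int] = field(default_factory=dict)
    members: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def add(self, scaffold_id: str, length_bp: int, snp_id: str, offset_bp: int) -> None:
        self.lengths.setdefault(scaffold_id, int(length_bp))
        self.members.setdefault(scaffold_id, []).append((snp_id, int(offset_bp)))

    def scaffold_ids(self) -> list[str]:
        return sorted(self.members)

    def validate(self, matrix: GenotypeMatrix) -> None:
        for sid, mem in self.members.items():
            length = self.lengths.get(sid)
            for snp_id, off in mem:
                if snp_id not in matrix._index:
                    raise PanelError(f"scaffold {sid}: member {snp_id} not in panel")
                if length is not None and off >= length:
                    raise PanelError(
                        f"scaffold {sid}: offset {off} >= length {length} for {snp_id}"
                    )
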