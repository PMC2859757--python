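"""Readers and writers for genotype panels, SNP maps and scaffold tables.

Supported genotype formats:

* ``dosage_tsv`` — header row of snp_ids, first column the sample id, cells
  in {0, 1, 2} with ``NA`` or ``-9`` for missing.  Paired with a map TSV
  whose columns are ``snp_id  status  chromosome  position_bp
  [scaffold_id  scaffold_offset_bp]``.
* ``ped_map`` — whitespace-delimited PLINK text files: a .ped with six
  leading pedigree columns followed by allele pairs (A/C/G/T, ``0 0`` for
  missing) and a .map with columns chrom, snp_id, cM (ignored), bp.

All outputs are UTF-8 TSV.  Coordinates are 1-based bp throughout.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, PanelError, ScaffoldTable, SnpRecord

__all__ = [
    "read_panel",
    "read_snp_map",
    "read_scaffold_table",
    "write_panel",
    "write_snp_map",
    "write_scaffold_table",
    "write_dosage_tsv",
    "write_ped_map",
]

_MISSING_TOKENS = {"NA", "na", "-9", ""}


def read_panel(genotype_path, map_path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Load a genotype panel plus its SNP map into a validated matrix.

    The map must cover every SNP column of the genotype file, in order or
    matched by id.  Per-SNP maf and n_called are recomputed at load time.
    """
    genotype_path, map_path = Path(genotype_path), Path(map_path)
    if format == "dosage_tsv":
        samples, snp_ids, dosage, missing = _read_dosage_tsv(genotype_path)
        records = read_snp_map(map_path)
    elif format == "ped_map":
        records = _read_plink_map(map_path)
        samples, dosage, missing = _read_ped(genotype_path, n_snps=len(records))
        snp_ids = [r.snp_id for r in records]
    else:
        raise ValueError(f"unknown format {format!r}")

    by_id = {r.snp_id: r for r in records}
    if len(by_id) != len(records):
        raise PanelError("duplicate snp_id in map")
    if set(snp_ids) != set(by_id):
        missing_ids = sorted(set(snp_ids) ^ set(by_id))
        raise PanelError(
            f"map and genotype matrix disagree: {len(snp_ids)} columns vs "
            f"{len(records)} map rows (first mismatches: {missing_ids[:5]})"
        )
    ordered = [by_id[s] for s in snp_ids]
    x_flag = np.array(
        [r.is_mapped and str(r.chromosome).upper() == "X" for r in ordered], dtype=bool
    )
    return GenotypeMatrix(samples, ordered, dosage, missing, x_flag)


def _read_dosage_tsv(path: Path):
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise PanelError(f"{path}: empty file")
    snp_ids = rows[0][1:]
    samples, dos, mis = [], [], []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(snp_ids) + 1:
            raise PanelError(f"{path}:{i}: expected {len(snp_ids) + 1} fields, got {len(row)}")
        samples.append(row[0])
        d_row, m_row = [], []
        for j, cell in enumerate(row[1:]):
            if cell in _MISSING_TOKENS:
                d_row.append(0)
                m_row.append(True)
            elif cell in ("0", "1", "2"):
                d_row.append(int(cell))
                m_row.append(False)
            else:
                raise PanelError(
                    f"{path}: bad dosage code {cell!r} at sample row {i - 1}, "
                    f"SNP column {j + 1} ({snp_ids[j]})"
                )
        dos.append(d_row)
        mis.append(m_row)
    return samples, snp_ids, np.array(dos, dtype=np.int8), np.array(mis, dtype=bool)


def read_snp_map(path) -> list[SnpRecord]:
    """Read the canonical map TSV (snp_id, status, chromosome, position_bp, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"snp_id", "status"}
    if not required.issubset(df.columns):
        raise PanelError(f"{path}: map needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        get = lambda col: getattr(row, col, "") if col in df.columns else ""
        chrom = get("chromosome") or None
        pos = get("position_bp")
        sid = get("scaffold_id") or None
        off = get("scaffold_offset_bp")
        records.append(
            SnpRecord(
                snp_id=row.snp_id,
                status=row.status,
                chromosome=chrom,
                position_bp=int(pos) if pos not in ("", "NA") else None,
                scaffold_id=sid,
                scaffold_offset_bp=int(off) if off not in ("", "NA") else None,
            )
        )
    return records


def _read_plink_map(path: Path) -> list[SnpRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelError(f"{path}:{ln}: expected 4 columns (chrom id cM bp)")
            chrom, snp_id, _cm, bp = parts[:4]
            bp = int(bp)
            if chrom in ("0", "") or bp <= 0:
                records.append(SnpRecord(snp_id=snp_id, status="unaligned"))
            else:
                records.append(
                    SnpRecord(snp_id=snp_id, status="mapped", chromosome=chrom, position_bp=bp)
                )
    return records


def _read_ped(path: Path, n_snps: int):
    samples, dos, mis = [], [], []
    # dosage counts copies of the alphabetically-first allele observed at the
    # locus; a monomorphic column reads as all-0 (label orientation is not
    # recoverable from a ped file)
    allele_sets: list[set[str]] = [set() for _ in range(n_snps)]
    raw = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PanelError(
                    f"{path}:{ln}: expected {6 + 2 * n_snps} fields for {n_snps} SNPs, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
            raw.append(pairs)
            for j, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        allele_sets[j].add(al)
    counted = [min(s) if len(s) == 2 else None for s in allele_sets]
    for pairs in raw:
        d_row, m_row = [], []
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                d_row.append(0)
                m_row.append(True)
            else:
                c = counted[j]
                d_row.append(0 if c is None else (a == c) + (b == c))
                m_row.append(False)
        dos.append(d_row)
        mis.append(m_row)
    return samples, np.array(dos, dtype=np.int8), np.array(mis, dtype=bool)


def read_scaffold_table(path) -> ScaffoldTable:
    """Read a scaffold TSV (scaffold_id, length_bp, snp_id, offset_bp)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = ScaffoldTable()
    for row in df.itertuples(index=False):
        table.add(row.scaffold_id, int(row.length_bp), row.snp_id, int(row.offset_bp))
    return table


# ---------------------------------------------------------------------- #
# writers
# ---------------------------------------------------------------------- #

def write_dosage_tsv(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id"] + [s.snp_id for s in matrix.snps])
        for i, sample in enumerate(matrix.samples):
            row = [
                "NA" if matrix.missing[i, j] else str(int(matrix.dosage[i, j]))
                for j in range(matrix.n_snps)
            ]
            w.writerow([sample] + row)


def write_snp_map(snps, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["snp_id", "status", "chromosome", "position_bp", "scaffold_id", "scaffold_offset_bp"]
        )
        for r in snps:
            w.writerow(
                [
                    r.snp_id,
                    r.status,
                    r.chromosome or "",
                    "" if r.position_bp is None else r.position_bp,
                    r.scaffold_id or "",
                    "" if r.scaffold_offset_bp is None else r.scaffold_offset_bp,
                ]
            )


def write_ped_map(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text files; the counted allele is written as 'A', the other as 'C'."""
    with open(map_path, "w") as fh:
        for r in matrix.snps:
            chrom = r.chromosome if r.is_mapped else "0"
            bp = r.position_bp if r.is_mapped else 0
            fh.write(f"{chrom}\t{r.snp_id}\t0\t{bp}\n")
    code = {0: "C C", 1: "A C", 2: "A A"}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            cells = [
                "0 0" if matrix.missing[i, j] else code[int(matrix.dosage[i, j])]
                for j in range(matrix.n_snps)
            ]
            fh.write("\t".join([sample, sample, "0", "0", "0", "-9"] + cells) + "\n")


def write_panel(matrix: GenotypeMatrix, genotype_path, map_path, format: str = "dosage_tsv") -> None:
    if format == "dosage_tsv":
        write_dosage_tsv(matrix, genotype_path)
        write_snp_map(matrix.snps, map_path)
    elif format == "ped_map":
        write_ped_map(matrix, genotype_path, map_path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_scaffold_table(table: ScaffoldTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["scaffold_id", "length_bp", "snp_id", "offset_bp"])
        for sid in table.scaffold_ids():
            for snp_id, off in table.members[sid]:
                w.writerow([sid, table.lengths[sid], snp_id, off])
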