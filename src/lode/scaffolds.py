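"""Lift SNP assignments to scaffold placement and orientation.

A scaffold is placed on a chromosome when at least one of its member SNPs
was assigned and all assigned members agree; disagreement across two or
more chromosomes flags a conflict (a candidate chimeric scaffold).  When
two or more members with distinct within-scaffold offsets received
distinct chromosome positions, the sign of the rank correlation between
offsets and assigned positions orients the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assign import Assignment
from .panel import ScaffoldTable

__all__ = ["ScaffoldPlacement", "place_scaffolds", "orient_scaffold", "summarize_placements"]


@dataclass
class ScaffoldPlacement:
    scaffold_id: str
    outcome: str  # 'placed' | 'conflict' | 'unplaced'
    chromosome: str | None = None
    position_bp: int | None = None  # median of members' assigned positions
    anchor_positions: list[tuple[str, int, int]] = field(default_factory=list)
    orientation: str = "undetermined"
    chromosomes_hit: list[str] = field(default_factory=list)
    note: str = ""


def orient_scaffold(p: ScaffoldPlacement) -> str:
    """forward / reverse / undetermined from the offset-vs-position rank correlation."""
    if p.outcome != "placed" or len(p.anchor_positions) < 2:
        return "undetermined"
    offs = np.array([a[1] for a in p.anchor_positions], dtype=float)
    pos = np.array([a[2] for a in p.anchor_positions], dtype=float)
    if len(set(offs)) < 2 or len(set(pos)) < 2:
        return "undetermined"
    rho = stats.spearmanr(offs, pos).statistic
    if np.isnan(rho) or rho == 0:
        return "undetermined"
    return "forward" if rho > 0 else "reverse"


def place_scaffolds(assignments: list[Assignment], table: ScaffoldTable) -> list[ScaffoldPlacement]:
    """Place every scaffold of the table from its members' assignments."""
    by_snp = {a.snp_id: a for a in assignments}
    out = []
    for sid in table.scaffold_ids():
        members = table.members[sid]
        genotyped = [(snp, off, by_snp[snp]) for snp, off in members if snp in by_snp]
        hits = [(snp, off, a) for snp, off, a in genotyped if a.assigned]
        chroms = sorted({a.chromosome for _, _, a in hits})
        if not genotyped:
            out.append(
                ScaffoldPlacement(sid, "unplaced", note="no genotyped member SNPs")
            )
        elif not hits:
            out.append(ScaffoldPlacement(sid, "unplaced", note="no member assigned"))
        elif len(chroms) == 1:
            p = ScaffoldPlacement(
                sid,
                "placed",
                chromosome=chroms[0],
                anchor_positions=[(snp, off, a.position_bp) for snp, off, a in hits],
                chromosomes_hit=chroms,
            )
            p.position_bp = int(np.median([a.position_bp for _, _, a in hits]))
            p.orientation = orient_scaffold(p)
            out.append(p)
        else:
            out.append(
                ScaffoldPlacement(
                    sid,
                    "conflict",
                    anchor_positions=[(snp, off, a.position_bp) for snp, off, a in hits],
                    chromosomes_hit=chroms,
                    note="assigned members span multiple chromosomes",
                )
            )
    return out


def summarize_placements(
    placements: list[ScaffoldPlacement], table: ScaffoldTable
) -> pd.DataFrame:
    """Per-chromosome scaffold counts and total scaffold length (bp)."""
    rows: dict[str, dict] = {}
    for p in placements:
        if p.outcome != "placed":
            continue
        row = rows.setdefault(
            p.chromosome, {"chromosome": p.chromosome, "n_scaffolds": 0, "total_bp": 0}
        )
        row["n_scaffolds"] += 1
        row["total_bp"] += int(table.lengths.get(p.scaffold_id, 0))
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["chromosome"]))
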