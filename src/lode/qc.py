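"""Assembly audit by masked repositioning.

Mapped SNPs are masked in batches (every k-th SNP of a chromosome in bp
order, or a random sample per chromosome), re-placed from the LD with the
remaining anchors, and compared with their held-out positions.  The three
headline metrics are

* efficiency — % of masked SNPs that received a location,
* accuracy   — % of assigned SNPs put on their original chromosome,
* precision  — mean |original − assigned| distance (kb, ± standard error)
  over correctly-assigned SNPs.

Runs of consecutive discordant SNPs that all point at one other chromosome
("discordant blocks") flag candidate mis-assembled regions; an Oxford-grid
count matrix summarises source vs assigned chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import LodeAssigner
from .panel import GenotypeMatrix, SnpRecord

__all__ = [
    "MaskingPlan",
    "QcReport",
    "DiscordantBlock",
    "make_plan",
    "run_audit",
    "find_blocks",
    "concordance_grid",
]


@dataclass
class MaskingPlan:
    """Masked snp_ids grouped into batches; each SNP is masked exactly once."""

    scheme: str
    batches: list[list[str]]
    seed: int = 0
    k: int | None = None

    def all_masked(self) -> list[str]:
        return [s for b in self.batches for s in b]


@dataclass
class DiscordantBlock:
    source_chromosome: str
    target_chromosome: str
    snp_ids: list[str]
    source_positions: list[int]
    assigned_positions: list[int]

    def __len__(self) -> int:
        return len(self.snp_ids)


def _chrom_sorted(records: list[SnpRecord]) -> dict[str, list[SnpRecord]]:
    by: dict[str, list[SnpRecord]] = {}
    for r in records:
        by.setdefault(r.chromosome, []).append(r)
    for recs in by.values():
        recs.sort(key=lambda r: (r.position_bp, r.snp_id))
    return by


def make_plan(
    mapped: list[SnpRecord],
    scheme: str = "every_kth",
    k: int = 10,
    counts: int | dict[str, int] | None = None,
    seed: int = 0,
) -> MaskingPlan:
    """Build a masking plan over the mapped SNPs.

    ``every_kth``: within each chromosome (bp order) batch b masks ranks
    k, 2k, ... shifted cyclically, so the k batches partition the panel.
    ``random_per_chromosome``: one batch sampling ``counts`` SNPs per
    chromosome without replacement.
    """
    mapped = [r for r in mapped if r.is_mapped]
    by = _chrom_sorted(mapped)
    if scheme == "every_kth":
        if k < 2:
            raise ValueError("k must be >= 2")
        batches: list[list[str]] = [[] for _ in range(k)]
        for recs in by.values():
            for rank, rec in enumerate(recs, start=1):
                b = (k - rank) % k  # batch 1 (index 0) masks ranks k, 2k, ...
                batches[b].append(rec.snp_id)
        return MaskingPlan(scheme, batches, seed=seed, k=k)
    if scheme == "random_per_chromosome":
        if counts is None:
            raise ValueError("random_per_chromosome needs counts")
        rng = np.random.default_rng(seed)
        batch: list[str] = []
        for chrom in sorted(by):
            recs = by[chrom]
            want = counts if isinstance(counts, int) else counts.get(chrom, 0)
            if want > len(recs):
                warnings.warn(
                    f"chromosome {chrom}: requested {want} of {len(recs)} SNPs; taking all",
                    UserWarning,
                    stacklevel=2,
                )
                want = len(recs)
            pick = rng.choice(len(recs), size=want, replace=False)
            batch.extend(recs[i].snp_id for i in sorted(pick))
        return MaskingPlan(scheme, [batch], seed=seed)
    raise ValueError(f"unknown scheme {scheme!r}")


class QcReport:
    """Audit outcome: one record per tested SNP plus derived metrics."""

    def __init__(self, records: pd.DataFrame):
        self.records = records.reset_index(drop=True)

    # -- aggregate views ----------------------------------------------
    def per_chromosome(self) -> pd.DataFrame:
        """Counts per source chromosome: tested = same + different + not_assigned."""
        df = self.records
        rows = []
        for chrom, grp in df.groupby("chromosome_true", sort=False):
            same = int(((grp.outcome == "assigned") & (grp.chromosome_assigned == chrom)).sum())
            diff = int(((grp.outcome == "assigned") & (grp.chromosome_assigned != chrom)).sum())
            rows.append(
                {
                    "chromosome": chrom,
                    "tested": len(grp),
                    "same_chromosome": same,
                    "different_chromosome": diff,
                    "not_assigned": int((grp.outcome != "assigned").sum()),
                }
            )
        return pd.DataFrame(rows)

    def metrics(self, maf_min: float | None = None, maf_max: float | None = None) -> dict:
        """Efficiency/accuracy/precision, optionally restricted to a MAF band."""
        df = self.records
        if maf_min is not None:
            df = df[df.maf > maf_min]
        if maf_max is not None:
            df = df[df.maf <= maf_max]
        tested = len(df)
        assigned = df[df.outcome == "assigned"]
        same = assigned[assigned.chromosome_assigned == assigned.chromosome_true]
        eff = 100.0 * len(assigned) / tested if tested else float("nan")
        acc = 100.0 * len(same) / len(assigned) if len(assigned) else float("nan")
        err_kb = (same.position_assigned - same.position_true).abs() / 1000.0
        prec = float(err_kb.mean()) if len(same) else float("nan")
        se = float(err_kb.std(ddof=1) / np.sqrt(len(same))) if len(same) > 1 else float("nan")
        return {
            "tested": tested,
            "assigned": len(assigned),
            "same_chromosome": len(same),
            "different_chromosome": len(assigned) - len(same),
            "efficiency_pct": eff,
            "accuracy_pct": acc,
            "precision_mean_kb": prec,
            "precision_se_kb": se,
        }

    @property
    def efficiency(self) -> float:
        return self.metrics()["efficiency_pct"]

    @property
    def accuracy(self) -> float:
        return self.metrics()["accuracy_pct"]

    @property
    def precision_kb(self) -> tuple[float, float]:
        m = self.metrics()
        return m["precision_mean_kb"], m["precision_se_kb"]

    def discordant(self) -> pd.DataFrame:
        df = self.records
        out = df[(df.outcome == "assigned") & (df.chromosome_assigned != df.chromosome_true)]
        return out.reset_index(drop=True)


def run_audit(
    g: GenotypeMatrix,
    plan: MaskingPlan,
    truth: dict[str, tuple[str, int]] | None = None,
    **assigner_params,
) -> QcReport:
    """Re-place every masked SNP batch-by-batch and compare with truth.

    By default the held-out map location of each masked SNP is the truth;
    pass ``truth`` (snp_id -> (chromosome, position_bp)) to audit against an
    external reference instead.
    """
    mapped_ids = g.mapped_ids()
    rows = []
    for b, batch in enumerate(plan.batches):
        masked = set(batch)
        anchors = [s for s in mapped_ids if s not in masked]
        if not anchors:
            raise ValueError(f"batch {b}: no anchors left after masking")
        est = LodeAssigner(**assigner_params).fit(g, anchor_ids=anchors)
        for asn in est.predict(list(batch)):
            rec = g.record(asn.snp_id)
            t_chrom, t_pos = (
                truth[asn.snp_id] if truth is not None else (rec.chromosome, rec.position_bp)
            )
            rows.append(
                {
                    "snp_id": asn.snp_id,
                    "batch": b,
                    "chromosome_true": t_chrom,
                    "position_true": t_pos,
                    "maf": rec.maf,
                    "outcome": asn.outcome,
                    "chromosome_assigned": asn.chromosome,
                    "position_assigned": asn.position_bp,
                    "reason": asn.reason,
                    "r2_max": asn.r2_max,
                    "n_01": asn.n_01,
                }
            )
    return QcReport(pd.DataFrame(rows))


def find_blocks(report: QcReport, min_run: int = 3) -> list[DiscordantBlock]:
    """Maximal runs (>= min_run) of bp-consecutive tested SNPs on one source
    chromosome that were all reassigned to the same other chromosome."""
    df = report.records.sort_values(["chromosome_true", "position_true"])
    blocks: list[DiscordantBlock] = []
    for chrom, grp in df.groupby("chromosome_true", sort=False):
        run: list[pd.Series] = []
        run_target: str | None = None

        def flush():
            nonlocal run, run_target
            if run_target is not None and len(run) >= min_run:
                blocks.append(
                    DiscordantBlock(
                        source_chromosome=str(chrom),
                        target_chromosome=run_target,
                        snp_ids=[r.snp_id for r in run],
                        source_positions=[int(r.position_true) for r in run],
                        assigned_positions=[int(r.position_assigned) for r in run],
                    )
                )
            run, run_target = [], None

        for _, row in grp.iterrows():
            discordant = row.outcome == "assigned" and row.chromosome_assigned != chrom
            if discordant and row.chromosome_assigned == run_target:
                run.append(row)
            elif discordant:
                flush()
                run, run_target = [row], row.chromosome_assigned
            else:
                flush()
        flush()
    return blocks


def _chrom_order(names) -> list[str]:
    def key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    return sorted(set(names), key=key)


def concordance_grid(report: QcReport, plot_path=None) -> pd.DataFrame:
    """Oxford grid: source-chromosome x assigned-chromosome count matrix.

    Row sums equal per-chromosome tested minus not-assigned counts.  In the
    rendered figure an X chromosome is labelled "30", after the bovine
    convention of plotting X as the 30th chromosome.
    """
    df = report.records
    assigned = df[df.outcome == "assigned"]
    order = _chrom_order(df.chromosome_true)
    grid = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for (src, dst), grp in assigned.groupby(["chromosome_true", "chromosome_assigned"]):
        if dst not in grid.columns:
            grid[dst] = 0
        grid.loc[src, dst] = len(grp)
    grid.index.name = "source"
    grid.columns.name = "assigned"
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        label = ["30" if str(c).upper() == "X" else str(c) for c in grid.columns]
        fig, ax = plt.subplots(figsize=(6, 5))
        with np.errstate(divide="ignore"):
            ax.imshow(np.log10(grid.to_numpy() + 1), cmap="viridis")
        ax.set_xticks(range(len(label)), label)
        ax.set_yticks(range(len(label)), label)
        ax.set_xlabel("assigned chromosome")
        ax.set_ylabel("source chromosome")
        ax.set_title("concordance of source vs reassigned chromosome")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return grid
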