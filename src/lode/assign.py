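"""Chromosome assignment and positioning of unpositioned SNPs.

For each query SNP the procedure is:

A) estimate r² with every mapped anchor SNP; keep quality-passing
   estimates (p < alpha, n_obs >= min_obs); per chromosome summarise
   r²_max (strength of LD) and n_0.1 (number of anchors with r² > 0.1).
   Rank chromosomes by r²_max, and — after excluding chromosomes with
   n_0.1 < 3 — by n_0.1.  A chromosome topping both rankings is the
   candidate.  For low-MAF queries (MAF <= 0.05) an extra safeguard
   applies: if the next-highest chromosome's r²_max exceeds 2/3 of the
   candidate's, the SNP is left unassigned.

B) the query inherits the exact bp position of the anchor SNP attaining
   r²_max on the candidate chromosome.

Queries with MAF <= 0.01 are not assigned (the procedure is unreliable for
rare alleles); the floor can be lowered, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ld import LdEstimate, _warn_if_small, ld_matrix
from .panel import GenotypeMatrix, SnpRecord

__all__ = [
    "ChromosomeEvidence",
    "Assignment",
    "LodeAssigner",
    "summarize_evidence",
    "select_candidate",
    "assign_snp",
    "assign_batch",
    "assignments_to_frame",
]

logger = logging.getLogger(__name__)

UNASSIGNED_REASONS = (
    "ok",
    "maf_below_floor",
    "no_quality_ld",
    "rank_conflict",
    "n01_floor",
    "second_chrom_rule",
    "tie",
)


@dataclass
class ChromosomeEvidence:
    """Per-chromosome LD summary for one query SNP."""

    chromosome: str
    r2_max: float
    anchor_snp: str
    anchor_pos_bp: int
    n_01: int


@dataclass
class Assignment:
    """Outcome for one query SNP: a chromosome + bp position, or a reason code."""

    snp_id: str
    outcome: str  # 'assigned' | 'unassigned'
    chromosome: str | None = None
    position_bp: int | None = None
    reason: str = "ok"
    r2_max: float | None = None
    n_01: int | None = None
    runner_up_r2max: float | None = None
    anchor_snp: str | None = None

    @property
    def assigned(self) -> bool:
        return self.outcome == "assigned"


def summarize_evidence(
    estimates: list[LdEstimate],
    snp_map: dict[str, SnpRecord] | list[SnpRecord],
    r2_window: float = 0.1,
) -> list[ChromosomeEvidence]:
    """Collapse one query's LD estimates into per-chromosome evidence.

    Only quality-passing estimates contribute.  ``r2_max`` ties between two
    anchors of the same chromosome go to the smaller bp position.
    """
    if not isinstance(snp_map, dict):
        snp_map = {r.snp_id: r for r in snp_map}
    best: dict[str, ChromosomeEvidence] = {}
    for est in estimates:
        if not est.passes_quality:
            continue
        rec = snp_map[est.snp_b]
        ev = best.get(rec.chromosome)
        if ev is None:
            best[rec.chromosome] = ChromosomeEvidence(
                chromosome=rec.chromosome,
                r2_max=est.r2,
                anchor_snp=rec.snp_id,
                anchor_pos_bp=rec.position_bp,
                n_01=int(est.r2 > r2_window),
            )
            continue
        ev.n_01 += int(est.r2 > r2_window)
        if est.r2 > ev.r2_max or (est.r2 == ev.r2_max and rec.position_bp < ev.anchor_pos_bp):
            ev.r2_max = est.r2
            ev.anchor_snp = rec.snp_id
            ev.anchor_pos_bp = rec.position_bp
    return sorted(best.values(), key=lambda e: e.chromosome)


def select_candidate(
    evidence: list[ChromosomeEvidence],
    maf: float,
    snp_id: str = "",
    maf_floor: float = 0.01,
    maf_safeguard: float = 0.05,
    n01_floor: int = 3,
    second_chrom_frac: float = 2.0 / 3.0,
) -> Assignment:
    """Apply the two-rank candidate rule plus the low-MAF 2/3 safeguard."""
    if not (maf > maf_floor):
        return Assignment(snp_id, "unassigned", reason="maf_below_floor")
    if not evidence:
        return Assignment(snp_id, "unassigned", reason="no_quality_ld")

    top_r2 = max(e.r2_max for e in evidence)
    r2_leaders = [e for e in evidence if e.r2_max == top_r2]
    if len(r2_leaders) > 1:
        return Assignment(snp_id, "unassigned", reason="tie")
    eligible = [e for e in evidence if e.n_01 >= n01_floor]
    if not eligible:
        return Assignment(snp_id, "unassigned", reason="n01_floor")
    top_n01 = max(e.n_01 for e in eligible)
    n01_leaders = [e for e in eligible if e.n_01 == top_n01]
    if len(n01_leaders) > 1:
        return Assignment(snp_id, "unassigned", reason="tie")
    if r2_leaders[0].chromosome != n01_leaders[0].chromosome:
        return Assignment(snp_id, "unassigned", reason="rank_conflict")
    cand = r2_leaders[0]

    runner_up = max(
        (e.r2_max for e in evidence if e.chromosome != cand.chromosome), default=None
    )
    if maf <= maf_safeguard and runner_up is not None:
        if runner_up > second_chrom_frac * cand.r2_max:
            return Assignment(
                snp_id,
                "unassigned",
                reason="second_chrom_rule",
                r2_max=cand.r2_max,
                n_01=cand.n_01,
                runner_up_r2max=runner_up,
            )
    return Assignment(
        snp_id,
        "assigned",
        chromosome=cand.chromosome,
        position_bp=cand.anchor_pos_bp,
        reason="ok",
        r2_max=cand.r2_max,
        n_01=cand.n_01,
        runner_up_r2max=runner_up,
        anchor_snp=cand.anchor_snp,
    )


class LodeAssigner(BaseEstimator):
    """LD-based SNP placement estimator.

    ``fit`` takes a :class:`~lode.panel.GenotypeMatrix` and memorises its
    mapped SNPs as anchors; ``predict`` returns an :class:`Assignment` per
    query SNP.  All thresholds are constructor parameters so the estimator
    composes with sklearn's ``get_params``/``set_params`` machinery.

    Parameters
    ----------
    alpha : float
        Significance level for the LD quality filter.
    min_obs : int
        Minimum individuals with both calls non-missing per pair.
    n01_floor : int
        Chromosomes with fewer than this many anchors at r² > ``r2_window``
        are excluded from the n_0.1 ranking.
    r2_window : float
        The r² threshold defining n_0.1 (strictly greater than).
    second_chrom_frac : float
        Low-MAF safeguard: unassign if runner-up r²_max exceeds this
        fraction of the candidate's.  Applies when MAF <= ``maf_safeguard``.
    maf_floor : float
        Queries with MAF <= this are not assigned.
    maf_safeguard : float
        Upper edge of the MAF band in which the safeguard applies.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_obs: int = 100,
        n01_floor: int = 3,
        r2_window: float = 0.1,
        second_chrom_frac: float = 2.0 / 3.0,
        maf_floor: float = 0.01,
        maf_safeguard: float = 0.05,
        em_tol: float = 1e-8,
        max_iter: int = 1000,
        chunk_size: int = 256,
    ):
        self.alpha = alpha
        self.min_obs = min_obs
        self.n01_floor = n01_floor
        self.r2_window = r2_window
        self.second_chrom_frac = second_chrom_frac
        self.maf_floor = maf_floor
        self.maf_safeguard = maf_safeguard
        self.em_tol = em_tol
        self.max_iter = max_iter
        self.chunk_size = chunk_size

    # -- estimator API -------------------------------------------------
    def fit(self, panel: GenotypeMatrix, anchor_ids: list[str] | None = None):
        """Memorise the anchor set (defaults to all mapped SNPs of the panel)."""
        if self.maf_floor < 0.01:
            warnings.warn(
                "maf_floor below 0.01: placement of rare SNPs is unreliable",
                UserWarning,
                stacklevel=2,
            )
        if anchor_ids is None:
            anchor_ids = panel.mapped_ids()
        anchors = [panel.record(s) for s in anchor_ids]
        if not anchors:
            raise ValueError("panel has zero mapped anchor SNPs")
        for a in anchors:
            if not a.is_mapped:
                raise ValueError(f"anchor {a.snp_id} is not a mapped SNP")
        _warn_if_small(panel)
        self.panel_ = panel
        self.anchor_ids_ = list(anchor_ids)
        self.anchors_ = anchors
        self.anchor_idx_ = panel.indices(anchor_ids)
        return self

    def predict(self, query_ids: list[str] | None = None) -> list[Assignment]:
        """Assign each query SNP (default: every non-mapped SNP of the panel).

        Queries are processed independently; the result is order-invariant.
        """
        if not hasattr(self, "panel_"):
            raise RuntimeError("LodeAssigner is not fitted")
        panel = self.panel_
        if query_ids is None:
            query_ids = panel.unmapped_ids()
        anchor_set = set(self.anchor_ids_)
        for q in query_ids:
            if q in anchor_set:
                raise ValueError(f"query {q} is also an anchor")
        snp_map = {a.snp_id: a for a in self.anchors_}
        out: list[Assignment] = []
        q_idx = panel.indices(query_ids)
        for start in range(0, len(query_ids), self.chunk_size):
            sl = slice(start, start + self.chunk_size)
            ids = query_ids[sl]
            res = ld_matrix(
                panel,
                q_idx[sl],
                self.anchor_idx_,
                alpha=self.alpha,
                min_obs=self.min_obs,
                tol=self.em_tol,
                max_iter=self.max_iter,
            )
            for row, snp_id in enumerate(ids):
                rec = panel.record(snp_id)
                ests = _row_estimates(res, row, snp_id, self.anchors_)
                evidence = summarize_evidence(ests, snp_map, r2_window=self.r2_window)
                out.append(
                    select_candidate(
                        evidence,
                        maf=rec.maf,
                        snp_id=snp_id,
                        maf_floor=self.maf_floor,
                        maf_safeguard=self.maf_safeguard,
                        n01_floor=self.n01_floor,
                        second_chrom_frac=self.second_chrom_frac,
                    )
                )
            logger.info("assigned %d/%d queries", min(start + self.chunk_size, len(query_ids)), len(query_ids))
        counts = Counter(a.reason for a in out)
        logger.info("assignment summary: %s", dict(counts))
        return out


def _row_estimates(res, row: int, snp_id: str, anchors: list[SnpRecord]) -> list[LdEstimate]:
    valid = res["valid"][row]
    ests = []
    for k in np.flatnonzero(valid):
        ests.append(
            LdEstimate(
                snp_a=snp_id,
                snp_b=anchors[k].snp_id,
                r2=float(res["r2"][row, k]),
                n_obs=int(res["n_obs"][row, k]),
                p_value=float(res["p_value"][row, k]),
                passes_quality=bool(res["passes"][row, k]),
                em_converged=bool(res["em_converged"][row, k]),
            )
        )
    return ests


# -- thin functional wrappers ------------------------------------------ #

def assign_snp(
    query: SnpRecord, g: GenotypeMatrix, anchors: list[SnpRecord], **params
) -> Assignment:
    """Assign a single query SNP against an explicit anchor list."""
    est = LodeAssigner(**params).fit(g, anchor_ids=[a.snp_id for a in anchors])
    return est.predict([query.snp_id])[0]


def assign_batch(queries: list[SnpRecord], g: GenotypeMatrix, **params) -> list[Assignment]:
    """Assign a batch of query SNPs against all mapped SNPs of the panel."""
    est = LodeAssigner(**params).fit(g)
    return est.predict([q.snp_id for q in queries])


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    """Tabulate assignments (one row per query SNP) for TSV output."""
    return pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in assignments],
            "outcome": [a.outcome for a in assignments],
            "chromosome": [a.chromosome for a in assignments],
            "position_bp": [a.position_bp for a in assignments],
            "reason": [a.reason for a in assignments],
            "r2_max": [a.r2_max for a in assignments],
            "n_01": [a.n_01 for a in assignments],
            "runner_up_r2max": [a.runner_up_r2max for a in assignments],
            "anchor_snp": [a.anchor_snp for a in assignments],
        }
    )
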