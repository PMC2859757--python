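import numpy as np
import pytest

from lode.assign import (
    LodeAssigner,
    assign_batch,
    assign_snp,
    select_candidate,
    summarize_evidence,
)
from lode.assign import ChromosomeEvidence as Ev
from lode.ld import LdEstimate
from lode.panel import GenotypeMatrix, SnpRecord

from .conftest import tiny_panel


def _est(b, r2, passes=True, n=200, p=1e-6):
    return LdEstimate("q", b, r2, n, p if passes else 0.5, passes)


def _map(*records):
    return {r.snp_id: r for r in records}


ANCHORS = [
    SnpRecord("a1", chromosome="1", position_bp=100),
    SnpRecord("a2", chromosome="1", position_bp=200),
    SnpRecord("a3", chromosome="1", position_bp=300),
    SnpRecord("b1", chromosome="2", position_bp=150),
]


class TestSummarizeEvidence:
    def test_all_failing_estimates_yield_nothing(self):
        ests = [_est("a1", 0.5, passes=False), _est("b1", 0.9, passes=False)]
        assert summarize_evidence(ests, _map(*ANCHORS)) == []

    def test_r2max_and_n01_hand_count(self):
        ests = [_est("a1", 0.3), _est("a2", 0.15), _est("a3", 0.05)]
        (ev,) = summarize_evidence(ests, _map(*ANCHORS))
        assert ev.r2_max == 0.3 and ev.anchor_snp == "a1" and ev.n_01 == 2

    def test_single_estimate_chromosome_counts_one(self):
        ests = [_est("a1", 0.3), _est("b1", 0.9)]
        by = {e.chromosome: e for e in summarize_evidence(ests, _map(*ANCHORS))}
        assert by["2"].n_01 == 1 and by["2"].r2_max == 0.9

    def test_anchor_tie_goes_to_smaller_bp(self):
        ests = [_est("a2", 0.4), _est("a1", 0.4)]
        (ev,) = summarize_evidence(ests, _map(*ANCHORS))
        assert ev.anchor_snp == "a1" and ev.anchor_pos_bp == 100


class TestSelectCandidate:
    def test_single_chromosome_is_assigned_at_anchor_position(self):
        ev = [Ev("5", 0.8, "a", 1_234_567, 5)]
        a = select_candidate(ev, maf=0.3)
        assert a.assigned and a.chromosome == "5" and a.position_bp == 1_234_567

    def test_chromosome_below_n01_floor_still_blocks_via_r2max(self):
        # B has higher r2max but only 2 anchors in LD: excluded from the
        # n_0.1 ranking, yet it still tops the r2max ranking -> conflict,
        # so the SNP is conservatively left unassigned
        ev = [Ev("A", 0.6, "a", 10, 10), Ev("B", 0.7, "b", 20, 2)]
        a = select_candidate(ev, maf=0.3)
        assert not a.assigned and a.reason == "rank_conflict"

    def test_top_of_both_rankings_is_assigned(self):
        ev = [Ev("A", 0.7, "a", 10, 10), Ev("B", 0.6, "b", 20, 2)]
        a = select_candidate(ev, maf=0.3)
        assert a.assigned and a.chromosome == "A"

    @pytest.mark.parametrize(
        "runner_up,expect_assigned",
        [(0.41, False), (0.39, True)],  # 2/3 x 0.6 = 0.4 boundary
    )
    def test_two_thirds_rule_boundary(self, runner_up, expect_assigned):
        ev = [Ev("A", 0.6, "a", 10, 8), Ev("B", runner_up, "b", 20, 1)]
        a = select_candidate(ev, maf=0.04)
        assert a.assigned is expect_assigned
        if not expect_assigned:
            assert a.reason == "second_chrom_rule"

    def test_safeguard_not_applied_above_maf_band(self):
        ev = [Ev("A", 0.6, "a", 10, 8), Ev("B", 0.41, "b", 20, 1)]
        assert select_candidate(ev, maf=0.3).assigned

    def test_maf_floor(self):
        ev = [Ev("A", 0.9, "a", 10, 9)]
        assert select_candidate(ev, maf=0.01).reason == "maf_below_floor"
        assert select_candidate([], maf=0.2).reason == "no_quality_ld"

    def test_no_chromosome_reaches_n01_floor(self):
        ev = [Ev("A", 0.6, "a", 10, 2), Ev("B", 0.3, "b", 20, 1)]
        assert select_candidate(ev, maf=0.3).reason == "n01_floor"

    def test_exact_rank_ties_are_not_assigned(self):
        ev = [Ev("A", 0.6, "a", 10, 5), Ev("B", 0.6, "b", 20, 4)]
        assert select_candidate(ev, maf=0.3).reason == "tie"
        ev = [Ev("A", 0.6, "a", 10, 5), Ev("B", 0.5, "b", 20, 5)]
        assert select_candidate(ev, maf=0.3).reason == "tie"


def _correct_fraction(assignments, truth_frame):
    assigned = [a for a in assignments if a.assigned]
    if not assigned:
        return 0.0
    ok = sum(a.chromosome == truth_frame.loc[a.snp_id, "chromosome"] for a in assigned)
    return ok / len(assigned)


def _ld_panel(seed=0, n=250, m_per_chrom=12, n_chrom=2):
    """Small two-chromosome panel with blocks of correlated SNPs."""
    rng = np.random.default_rng(seed)
    cols, chroms, positions = [], [], []
    for c in range(n_chrom):
        base = rng.integers(0, 2, size=(n, 2)).sum(axis=1)
        for j in range(m_per_chrom):
            col = base.copy()
            flip = rng.random(n) < 0.08 * (j % 4 + 1)
            col[flip] = rng.integers(0, 3, size=int(flip.sum()))
            cols.append(col.tolist())
            chroms.append(str(c + 1))
            positions.append(1_000_000 * (j + 1))
            if j % 4 == 3:
                base = rng.integers(0, 2, size=(n, 2)).sum(axis=1)
    return tiny_panel(cols, chroms=chroms, positions=positions)


class TestAssignSnp:
    def test_duplicate_of_anchor_is_placed_at_its_exact_position(self):
        m = _ld_panel()
        query = m.snps[3]
        anchors = [s for s in m.snps if s.snp_id != query.snp_id]
        a = assign_snp(query, m, anchors, min_obs=50)
        assert a.assigned
        assert a.chromosome == "1"

    def test_unlinked_query_is_not_assigned(self):
        m = _ld_panel(seed=5)
        rng = np.random.default_rng(11)
        free = SnpRecord("free", status="unaligned")
        snps = m.snps + [free]
        dosage = np.column_stack([m.dosage, rng.integers(0, 3, size=m.n_samples)])
        m2 = GenotypeMatrix(m.samples, snps, dosage)
        a = assign_snp(m2.record("free"), m2, [s for s in m2.snps if s.is_mapped], min_obs=50)
        assert not a.assigned
        assert a.reason in ("no_quality_ld", "rank_conflict", "n01_floor")

    def test_allele_label_swap_leaves_assignment_unchanged(self):
        m = _ld_panel(seed=3)
        query = m.snps[5]
        anchors = [s for s in m.snps if s.snp_id != query.snp_id]
        a1 = assign_snp(query, m, anchors, min_obs=50)
        j = m.column_index(query.snp_id)
        m.dosage[:, j] = 2 - m.dosage[:, j]
        m.refresh_stats()
        a2 = assign_snp(query, m, anchors, min_obs=50)
        assert (a1.outcome, a1.chromosome, a1.position_bp, a1.reason) == (
            a2.outcome,
            a2.chromosome,
            a2.position_bp,
            a2.reason,
        )
        assert a1.r2_max == pytest.approx(a2.r2_max, abs=1e-9)


class TestAssignBatch:
    def test_empty_query_list(self):
        m = _ld_panel()
        assert assign_batch([], m) == []

    def test_zero_mapped_anchors_is_fatal(self):
        m = tiny_panel([[0, 1, 2, 1] * 30])
        m.snps[0] = SnpRecord("s0", status="unaligned")
        m2 = GenotypeMatrix(m.samples, m.snps, m.dosage)
        with pytest.raises(ValueError, match="zero mapped"):
            assign_batch([m2.snps[0]], m2)

    def test_batch_equals_serial_application(self):
        m = _ld_panel(seed=9, m_per_chrom=8)
        queries = m.snps[:6]
        anchors = [s for s in m.snps if s.snp_id not in {q.snp_id for q in queries}]
        est = LodeAssigner(min_obs=50).fit(m, anchor_ids=[a.snp_id for a in anchors])
        batch = est.predict([q.snp_id for q in queries])
        serial = [assign_snp(q, m, anchors, min_obs=50) for q in queries]
        for b, s in zip(batch, serial):
            assert (b.outcome, b.chromosome, b.position_bp, b.reason) == (
                s.outcome,
                s.chromosome,
                s.position_bp,
                s.reason,
            )

    def test_quality_set_shrinks_with_stricter_filters(self):
        # stricter alpha (smaller) or higher min_obs can only lose estimates
        from lode.ld import ld_matrix

        m = _ld_panel(seed=21)
        qi, ai = m.indices([m.snps[0].snp_id]), m.indices([s.snp_id for s in m.snps[1:]])
        loose = ld_matrix(m, qi, ai, alpha=0.05, min_obs=50)["passes"]
        tight_alpha = ld_matrix(m, qi, ai, alpha=0.001, min_obs=50)["passes"]
        tight_obs = ld_matrix(m, qi, ai, alpha=0.05, min_obs=200)["passes"]
        assert not (tight_alpha & ~loose).any()
        assert not (tight_obs & ~loose).any()

    def test_query_also_anchor_is_rejected(self):
        m = _ld_panel()
        est = LodeAssigner().fit(m)
        with pytest.raises(ValueError, match="also an anchor"):
            est.predict([m.snps[0].snp_id])

    def test_sklearn_param_interface(self):
        est = LodeAssigner(alpha=0.05)
        assert est.get_params()["alpha"] == 0.05
        est.set_params(min_obs=42)
        assert est.min_obs == 42


class TestPermutedNull:
    def test_true_panel_beats_permuted_genotype_null(self, default_panel):
        # among assigned queries, the fraction on the true chromosome must
        # be at least what shuffled (LD-free) genotypes achieve
        matrix, _, truth = default_panel
        tf = truth.frame.set_index("snp_id")
        queries = [
            s for s in matrix.unmapped_ids() if matrix.record(s).maf > 0.05
        ][:25]
        est = LodeAssigner().fit(matrix)
        real = est.predict(queries)
        frac_real = _correct_fraction(real, tf)

        shuffled = GenotypeMatrix(
            matrix.samples, matrix.snps, matrix.dosage.copy(), matrix.missing.copy()
        )
        rng = np.random.default_rng(13)
        for s in queries:
            j = shuffled.column_index(s)
            perm = rng.permutation(shuffled.n_samples)
            shuffled.dosage[:, j] = shuffled.dosage[perm, j]
            shuffled.missing[:, j] = shuffled.missing[perm, j]
        shuffled.refresh_stats()
        null = LodeAssigner().fit(shuffled).predict(queries)
        frac_null = _correct_fraction(null, tf)
        assert frac_real >= frac_null
        assert frac_real > 0.9  # the real panel genuinely places them

class TestAssignedPositionProperty:
    def test_assigned_position_coincides_with_a_mapped_anchor(self, default_panel):
        matrix, _, truth = default_panel
        est = LodeAssigner().fit(matrix)
        queries = matrix.unmapped_ids()[:40]
        anchor_pos = {
            (r.chromosome, r.position_bp) for r in matrix.snps if r.is_mapped
        }
        for a in est.predict(queries):
            if a.assigned:
                assert (a.chromosome, a.position_bp) in anchor_pos
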