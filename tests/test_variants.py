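"""Consensus building, anchored alignment, variant/DVN calling, CENP-B scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphadom import variants as var
from alphadom.errors import (
    EmptyInputError,
    OutlierCopyError,
    ParameterError,
    UndefinedRateError,
)
from alphadom.model import SequenceRecord, Variant

from conftest import make_alignment


class TestBuildConsensus:
    def test_majority_and_support(self):
        cons = var.build_consensus(["ACGT", "ACGT", "ACTT"])
        assert cons.sequence == "ACGT"
        assert np.allclose(cons.support, [1, 1, 2 / 3, 1])

    def test_tie_breaks_by_fixed_order(self):
        assert var.build_consensus(["AAAA", "CAAA"]).sequence == "AAAA"
        assert var.build_consensus(["TAAA", "GAAA"]).sequence == "GAAA"

    def test_single_copy_rejected(self):
        with pytest.raises(EmptyInputError):
            var.build_consensus(["ACGT"])

    def test_recovers_ancestor_from_diverged_copies(self, rng):
        ancestor = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        copies = []
        for _ in range(30):
            arr = np.array(list(ancestor))
            pos = rng.choice(600, 3, replace=False)  # 0.5% divergence
            for p in pos:
                arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
            copies.append("".join(arr))
        cons = var.build_consensus(copies)
        match = np.mean(np.array(list(cons.sequence)) == np.array(list(ancestor)))
        assert match >= 0.999


class TestAnchorAlign:
    def test_identical_copy_projects_to_consensus(self):
        cons = var.build_consensus(["ACGTACGTAC", "ACGTACGTAC"])
        aln = var.anchor_align(["ACGTACGTAC", "ACGTACGTAC"], cons)
        assert aln.row("copy_001") == cons.sequence
        assert aln.insertions == []

    def test_deletion_becomes_gap_state(self):
        seqs = ["ACGTACGTACGTACGTACGT"] * 3 + ["ACGTACGTAGTACGTACGT"]
        aln = var.anchor_align(seqs)
        assert aln.n_columns == 20
        assert aln.matrix[3].tolist().count("-") == 1

    def test_insertion_recorded_not_projected(self):
        seqs = ["ACGTACGTACGTACGTACGT"] * 3 + ["ACGTACGTACCCCGTACGTACGT"]
        aln = var.anchor_align(seqs)
        assert aln.n_columns == 20
        assert len(aln.insertions) == 1
        cid, col, istr = aln.insertions[0]
        assert cid == "copy_004" and istr == "CCC"

    def test_planted_states_projected_exactly(self, rng):
        records, truth = __import__("alphadom").sim.planted_domain_array(seed=9)
        aln = var.anchor_align(records)
        # every copy equals its own input sequence in consensus coordinates
        for rec, row in zip(records, (r for _, r in aln.rows())):
            assert row == rec.sequence

    def test_outlier_copy_named(self):
        good = ["ACGTACGTACGTACGTACGT"] * 3
        bad = "TTTTTTTTGGGGGGGGCCCC"
        with pytest.raises(OutlierCopyError, match="copy_004"):
            var.anchor_align(good + [bad])


class TestCallVariants:
    def test_identical_alignment_has_no_variants(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGT"])
        assert var.call_variants(aln) == []

    def test_three_mismatches_three_variants(self):
        aln = make_alignment(["ACGTACGT", "ACGTACGT", "TCGAACGA"])
        vs = var.call_variants(aln)
        assert len(vs) == 3
        assert all(v.copy_id == "c3" for v in vs)

    def test_copies_with_n_are_flagged_and_excluded(self):
        aln = make_alignment(["ACGT", "ACGT", "ANGT"])
        assert var.copies_with_n(aln) == ["c3"]
        assert all(v.copy_id != "c3" for v in var.call_variants(aln))


class TestClassifyDvns:
    def test_shared_and_singleton_split_at_one_column(self):
        vs = [Variant("c1", 4, "T"), Variant("c2", 4, "T"), Variant("c3", 4, "G")]
        part = var.classify_dvns(vs)
        assert len(part.dvns) == 1
        assert part.dvns[0].carriers == frozenset({"c1", "c2"})
        assert part.sporadic == [Variant("c3", 4, "G")]
        assert part.dvn_columns == 1

    def test_nothing_shared_means_no_dvn_columns(self):
        vs = [Variant("c1", 0, "T"), Variant("c2", 3, "G")]
        part = var.classify_dvns(vs)
        assert part.dvns == [] and part.dvn_columns == 0

    def test_min_share_below_two_rejected(self):
        with pytest.raises(ParameterError):
            var.classify_dvns([], min_share=1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_partition_complete_and_order_invariant(self, data):
        n = data.draw(st.integers(2, 6), label="n_copies")
        width = data.draw(st.integers(2, 20), label="n_cols")
        cells = data.draw(st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, width - 1),
                      st.sampled_from("ACGT-")), max_size=30), label="variants")
        vs = [Variant(f"c{i}", j, s) for i, j, s in cells]
        seen = {(v.copy_id, v.column) for v in vs}
        vs = [v for v in vs if (v.copy_id, v.column) in seen and
              not seen.discard((v.copy_id, v.column))]  # dedupe cells
        part = var.classify_dvns(vs)
        assert part.n_variants == len(vs)
        # shuffling input order changes nothing
        part2 = var.classify_dvns(list(reversed(vs)))
        assert {(g.column, g.alt_state, g.carriers) for g in part.dvns} == \
               {(g.column, g.alt_state, g.carriers) for g in part2.dvns}
        # raising min_share never increases the DVN group count
        for share in (3, 4, 5):
            assert len(var.classify_dvns(vs, min_share=share).dvns) <= \
                   len(var.classify_dvns(vs, min_share=share - 1).dvns)


class TestSporadicRate:
    def test_identical_alignment_rate_zero(self):
        aln = make_alignment(["ACGT"] * 4)
        part = var.classify_dvns(var.call_variants(aln))
        rate, per_copy = var.sporadic_rate(part, aln)
        assert rate == 0.0 and set(per_copy.values()) == {0.0}

    def test_five_singletons_in_thousand_cells(self, rng):
        rows = []
        base = "".join(rng.choice(list("ACGT"), 100))
        for i in range(10):
            rows.append(base)
        mat = np.array([list(r) for r in rows], dtype="<U1")
        # five singleton substitutions on distinct cells/columns
        for i, j in [(0, 5), (1, 17), (2, 33), (3, 60), (9, 99)]:
            mat[i, j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[i, j]]
        aln = make_alignment(["".join(r) for r in mat])
        part = var.classify_dvns(var.call_variants(aln))
        rate, _ = var.sporadic_rate(part, aln)
        assert rate == pytest.approx(0.5)

    def test_empty_alignment_rate_undefined(self):
        aln = make_alignment(["ACGT"])
        part = var.classify_dvns([])
        aln.matrix = aln.matrix[:0]
        aln.copy_ids = []
        with pytest.raises(UndefinedRateError):
            var.sporadic_rate(part, aln)


class TestScanCenpb:
    BOX = "ATTCGTTGGAAACGGGA"

    def pad(self, core, n=171):
        left = "A" * 40
        return (left + core + "G" * n)[:n]

    def test_exact_box_intact(self):
        calls = var.scan_cenpb([self.pad(self.BOX)])
        assert calls[0].intact and calls[0].n_essential_matches == 9
        assert calls[0].offset == 40

    def test_single_essential_mutation_breaks_box(self):
        broken = self.BOX.replace("CGGG", "CAGG")
        calls = var.scan_cenpb([self.pad(broken)])
        assert not calls[0].intact and calls[0].n_essential_matches == 8
        assert calls[0].present

    def test_planted_counts_recovered(self, rng):
        ess = [i for i, c in enumerate(var.CENPB_CONSENSUS) if c != "N"]
        monomers, expected = [], []
        for n_break in range(4):
            box = list(self.BOX)
            for p in list(rng.choice(ess, size=n_break, replace=False)):
                box[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[box[p]]
            monomers.append(self.pad("".join(box)))
            expected.append(9 - n_break)
        calls = var.scan_cenpb(monomers)
        assert [c.n_essential_matches for c in calls] == expected

    def test_archetype_alternating_monomers_carry_box(self):
        from alphadom import archetype_array

        t = archetype_array(seed=3)
        monomers = [t.ancestor_unit[i * 171:(i + 1) * 171] for i in range(t.k)]
        calls = var.scan_cenpb(monomers)
        assert all(calls[i].intact for i in range(0, t.k, 2))
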