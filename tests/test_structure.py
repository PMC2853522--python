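"""Domain segmentation, barrier/event inference and set comparison."""

import numpy as np
import pytest

from alphadom import sim, structure as st
from alphadom.errors import EmptyInputError, OrderingRequiredError
from alphadom.model import DVNGroup, SequenceRecord, Variant, VariantPartition
from alphadom.variants import anchor_align, call_variants, classify_dvns

from conftest import make_alignment


def part_from(groups, sporadic=()):
    return VariantPartition(
        dvns=[DVNGroup(c, s, frozenset(ids)) for c, s, ids in groups],
        sporadic=list(sporadic))


class TestHaplotypeMatrix:
    def test_carrier_rows(self):
        part = part_from([(0, "T", {"c1", "c2"}), (5, "G", {"c2", "c3"})])
        hm = st.haplotype_matrix(part, ["c1", "c2", "c3"])
        assert hm.matrix.tolist() == [[1, 0], [1, 1], [0, 1]]

    def test_zero_dvn_copy_keeps_all_zero_row(self):
        part = part_from([(0, "T", {"c1", "c2"})])
        hm = st.haplotype_matrix(part, ["c1", "c2", "c3"])
        assert hm.matrix[2].tolist() == [0]

    def test_no_groups_yields_empty_matrix(self):
        hm = st.haplotype_matrix(part_from([]), ["c1", "c2"])
        assert hm.n_groups == 0 and hm.n_copies == 2


class TestSegmentDomains:
    def pipeline_matrix(self, records):
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        return st.haplotype_matrix(part, aln.copy_ids)

    def test_identical_haplotypes_form_one_domain(self):
        part = part_from([(0, "T", {f"c{i}" for i in range(6)})])
        hm = st.haplotype_matrix(part, [f"c{i}" for i in range(6)])
        dmap = st.segment_domains(hm)
        assert [(d.first_copy, d.last_copy) for d in dmap.domains] == [(0, 5)]
        assert dmap.covered() == set(range(6))

    def test_planted_blocks_split_at_boundary(self):
        records, truth = sim.planted_domain_array(seed=11)
        dmap = st.segment_domains(self.pipeline_matrix(records))
        assert sorted((d.first_copy, d.last_copy) for d in dmap.domains) == \
               [(0, truth.boundary - 1), (truth.boundary, len(records) - 1)]

    def test_reversal_mirrors_domains(self):
        records, truth = sim.planted_domain_array(seed=13)
        n = len(records)
        fwd = st.segment_domains(self.pipeline_matrix(records))
        rev = st.segment_domains(self.pipeline_matrix(records[::-1]))
        mirrored = sorted((n - 1 - d.last_copy, n - 1 - d.first_copy)
                          for d in rev.domains)
        assert mirrored == sorted((d.first_copy, d.last_copy) for d in fwd.domains)

    def test_unordered_set_rejected(self):
        part = part_from([(0, "T", {"c1", "c2"})])
        hm = st.haplotype_matrix(part, ["c1", "c2"], ordered=False)
        with pytest.raises(OrderingRequiredError):
            st.segment_domains(hm)

    def test_domain_map_covers_every_copy_exactly_once(self):
        records, _ = sim.planted_domain_array(seed=17, n_barrier=4,
                                              barrier_divergence=0.04)
        hm = self.pipeline_matrix(records)
        dmap, _ = st.detect_barriers(st.segment_domains(hm), hm)
        covered = dmap.covered()
        assert covered == set(range(len(records)))
        n_in_domains = sum(d.size for d in dmap.domains)
        n_in_barriers = sum(b - a + 1 for a, b in dmap.barriers)
        assert n_in_domains + n_in_barriers + len(dmap.unassigned) == len(records)


class TestBarriers:
    def test_planted_divergent_spacer_labelled_barrier(self):
        records, truth = sim.planted_domain_array(seed=19, n_barrier=4)
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        hm = st.haplotype_matrix(part, aln.copy_ids)
        dmap, report = st.detect_barriers(st.segment_domains(hm), hm)
        assert dmap.barriers == [truth.barrier]
        assert any(r["barrier"] for r in report)

    def test_directly_adjacent_domains_have_no_barrier(self):
        records, _ = sim.planted_domain_array(seed=23)
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        hm = st.haplotype_matrix(part, aln.copy_ids)
        dmap, report = st.detect_barriers(st.segment_domains(hm), hm)
        assert dmap.barriers == []


class TestDuplicatePairs:
    def test_planted_pair_in_diverged_background(self):
        records, truth = sim.planted_domain_array(
            seed=29, sporadic=0.008, n_barrier=5, duplicate_pair=True)
        aln = anchor_align(records)
        pairs = st.detect_duplicate_pairs(aln)
        assert [(p.first_copy, p.second_copy) for p in pairs] == \
               [truth.duplicate_pair]
        assert pairs[0].identity == 1.0

    def test_95_percent_identical_copies_yield_nothing(self, rng):
        base = rng.integers(0, 4, 400)
        rows = []
        for _ in range(6):
            v = base.copy()
            pos = rng.choice(400, 20, replace=False)
            v[pos] = (v[pos] + 1) % 4
            rows.append("".join(np.array(list("ACGT"))[v]))
        aln = anchor_align(rows)
        assert st.detect_duplicate_pairs(aln) == []


class TestConversionTracts:
    def setup_case(self, seed, tract_dvns, tract_copies=(5,)):
        records, truth = sim.planted_domain_array(
            seed=seed, penetrance=(0.6, 0.9), tract_dvns=tract_dvns,
            tract_copies=tract_copies)
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        hm = st.haplotype_matrix(part, aln.copy_ids)
        dmap = st.segment_domains(hm)
        return st.detect_conversion_tracts(hm, dmap), records, truth, dmap

    def test_planted_five_dvn_tract_found_with_donor(self):
        tracts, records, truth, dmap = self.setup_case(31, tract_dvns=5)
        mine = [t for t in tracts if t.copy_id == records[5].id]
        assert len(mine) == 1
        assert mine[0].n_dvns >= 4  # sporadic noise may clip one position
        donor = dmap.domains[mine[0].donor_domain]
        assert donor.first_copy >= truth.boundary  # donor lies in domain B

    def test_no_cross_domain_runs_no_tracts(self):
        tracts, _, _, _ = self.setup_case(37, tract_dvns=0, tract_copies=())
        assert tracts == []

    def test_run_below_k_min_not_reported(self):
        tracts, records, _, _ = self.setup_case(41, tract_dvns=2)
        assert [t for t in tracts if t.copy_id == records[5].id] == []


class TestCompareSets:
    def test_self_comparison_has_no_private_dvns(self):
        records, _ = sim.planted_domain_array(seed=43, penetrance=(0.5, 0.9),
                                              sporadic=0.0)
        sc = st.compare_sets(records, records, n_perm=99, seed=0)
        assert sc.private_a == 0 and sc.private_b == 0
        assert sc.shared_dvns == sc.total_dvns
        # each copy's nearest neighbour is its twin in the other set, so
        # intermingling is maximal (well above the random-label level of 1)
        assert sc.intermingling_index > 1.2

    def test_disjoint_sets_cluster_into_pure_clades(self):
        recs_a, _ = sim.planted_domain_array(seed=47, n_b=0, sporadic=0.0)
        recs_b, _ = sim.planted_domain_array(seed=47, n_a=0, sporadic=0.0)
        sc = st.compare_sets(recs_a, recs_b, n_perm=99, seed=0)
        assert sc.shared_dvns == 0
        assert sc.private_a > 0 and sc.private_b > 0
        import skbio

        tree = skbio.TreeNode.read([sc.newick])
        # some internal node splits the taxa exactly into the two sets
        tips = {t.name for t in tree.tips()}
        want = {n for n in tips if n.startswith("A:")}
        splits = [{t.name for t in node.tips()} for node in tree.non_tips()]
        assert any(s == want or tips - s == want for s in splits)

    def test_shared_plus_private_equals_total(self):
        records, _ = sim.planted_domain_array(seed=53)
        sc = st.compare_sets(records[:15], records[15:], n_perm=19, seed=0)
        assert sc.shared_dvns + sc.private_a + sc.private_b == sc.total_dvns


class TestIntermingling:
    def test_disjoint_clusters_raw_zero(self):
        a = np.zeros((8, 10), dtype=np.int8)
        b = np.zeros((8, 10), dtype=np.int8)
        a[:, :5] = 1
        b[:, 5:] = 1
        _idx, raw, _p = st.intermingling_index(a, b, n_perm=49, seed=0)
        assert raw == 0.0

    def test_identical_haplotypes_calibrate_to_one(self):
        mat = np.ones((10, 6), dtype=np.int8)
        idx, raw, _p = st.intermingling_index(mat, mat.copy(), n_perm=49, seed=0)
        assert raw == pytest.approx(10 / 19)
        assert idx == pytest.approx(1.0)

    def test_empty_set_undefined(self):
        with pytest.raises(EmptyInputError):
            st.intermingling_index(np.ones((0, 3), dtype=np.int8),
                                   np.ones((2, 3), dtype=np.int8))
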