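import numpy as np
import pandas as pd
import pytest

from lcrep.assign import (
    RearrangedRecord,
    assign_all,
    assign_germline,
    classify_coverage,
    collapse_duplicates,
)
from lcrep.reference import ReferenceSet
from lcrep.simulate import CohortSpec, back_translate, generate_cohort, simulate_shm


def _record(seq, rid="r", molecule="protein", cohort="AL"):
    return RearrangedRecord(record_id=rid, seq=seq, molecule=molecule,
                            category="AL-PCD", subcategory="AL", cohort=cohort)


class TestAssignGermline:
    def test_identity_rearrangement(self, reference, kv133_kj1):
        a = assign_germline(_record(kv133_kj1), reference)
        assert (a.v_gene, a.j_gene) == ("IGKV1-33", "IGKJ1")
        assert (a.substitutions, a.insertions, a.deletions) == (0, 0, 0)
        assert a.coverage_class == "complete"
        assert a.identity == 1.0

    def test_distal_paralog_reported_as_proximal(self, reference):
        seq = reference.get("IGKV1D-33").aa_seq + reference.get("IGKJ1").aa_seq
        a = assign_germline(_record(seq), reference)
        assert a.v_gene == "IGKV1-33"

    def test_lambda_j_reported_with_merged_label(self, reference):
        seq = reference.get("IGLV6-57").aa_seq + reference.get("IGLJ3").aa_seq
        a = assign_germline(_record(seq), reference)
        assert a.j_gene == "IGLJ2/IGLJ3"

    def test_substitutions_match_hamming_without_indels(self, reference, kv133_kj1):
        rng = np.random.default_rng(8)
        for _ in range(20):
            shm = simulate_shm(kv133_kj1, 0.06, 0.0, 0.0, rng)
            a = assign_germline(_record(shm.seq), reference)
            hamming = sum(x != y for x, y in zip(kv133_kj1, shm.seq))
            assert a.substitutions == hamming
            assert (a.insertions, a.deletions) == (0, 0)

    def test_indel_counts_recovered(self, reference, kv133_kj1):
        # one deletion at position 40, one insertion at position 60
        seq = kv133_kj1[:40] + kv133_kj1[41:]
        seq = seq[:60] + "W" + seq[60:]
        a = assign_germline(_record(seq), reference)
        assert a.v_gene == "IGKV1-33"
        assert a.deletions == 1
        assert a.insertions == 1

    def test_unassignable_below_identity_floor(self, reference):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        a = assign_germline(_record(junk), reference)
        assert a.v_gene is None
        assert a.coverage_class == "excluded"
        assert a.reason == "unassignable"

    def test_reference_permutation_invariance(self, reference, kv133_kj1):
        rng = np.random.default_rng(4)
        shm = simulate_shm(kv133_kj1, 0.08, 0.5, 0.5, rng)
        a1 = assign_germline(_record(shm.seq), reference)
        shuffled_ids = list(reference.genes)
        rng.shuffle(shuffled_ids)
        permuted = ReferenceSet(
            {gid: reference.genes[gid] for gid in shuffled_ids},
            cdr_windows=reference.cdr_windows,
        )
        a2 = assign_germline(_record(shm.seq), permuted)
        assert (a1.v_gene, a1.j_gene, a1.score) == (a2.v_gene, a2.j_gene, a2.score)
        assert (a1.substitutions, a1.insertions, a1.deletions) == (
            a2.substitutions, a2.insertions, a2.deletions)

    def test_true_v_gene_recovery_on_synthetic_cohort(self, reference):
        spec = CohortSpec(
            name="AL", n_sequences=120,
            gene_usage={g.paralog_canonical: 1 / 11 for g in reference.genes.values()
                        if g.segment == "V" and g.gene_id != "IGKV1D-33"},
            j_usage={"IGKJ1": 0.25, "IGKJ2": 0.25, "IGLJ2": 0.25, "IGLJ3": 0.25},
            sub_rate=0.05, seed=21,
        )
        records, _, truth = generate_cohort(spec, reference)
        table = assign_all(records, reference)
        merged = table.merge(truth, left_on="sequence_id", right_on="record_id")
        correct = (merged["v_call"] == merged["true_v_gene"]).mean()
        assert correct >= 0.99

    def test_nucleotide_record_translated_and_assigned(self, reference, kv133_kj1):
        nt = back_translate(kv133_kj1)
        a = assign_germline(_record(nt, molecule="nucleotide"), reference)
        assert (a.v_gene, a.j_gene) == ("IGKV1-33", "IGKJ1")
        assert a.substitutions == 0
        assert a.coverage_class == "complete"

    def test_all_frames_with_stops_marked_non_productive(self, reference):
        # "TAAA" repeats put a TAA stop codon in every reading frame
        nt = "TAAA" * 30
        a = assign_germline(_record(nt, molecule="nucleotide"), reference)
        assert a.coverage_class == "excluded"
        assert a.reason == "non-productive"

    def test_short_record_excluded(self, reference):
        a = assign_germline(_record("ACDEFGHIKL"), reference)
        assert a.reason == "too-short"


class TestClassifyCoverage:
    def test_full_length_no_ambiguity_complete(self, reference, kv133_kj1):
        a = assign_germline(_record(kv133_kj1), reference)
        assert classify_coverage(a, _record(kv133_kj1), reference) == "complete"

    def test_85_contiguous_residues_spanning_cdrs_incomplete(self, reference, kv133_kj1):
        seq = kv133_kj1[25:]  # covers positions 26..110: all CDR windows, 85 residues
        rec = _record(seq)
        a = assign_germline(rec, reference)
        assert a.coverage_class == "incomplete"
        assert a.covered_end - a.covered_start + 1 == 85

    def test_79_contiguous_residues_excluded(self, reference, kv133_kj1):
        seq = kv133_kj1[31:]  # positions 32..110: 79 residues
        a = assign_germline(_record(seq), reference)
        assert a.covered_end - a.covered_start + 1 == 79
        assert a.coverage_class == "excluded"

    def test_missing_cdr_window_excluded(self, reference, kv133_kj1):
        seq = kv133_kj1[:85]  # 85 residues but missing the third CDR window
        a = assign_germline(_record(seq), reference)
        assert a.coverage_class == "excluded"

    def test_ambiguous_residue_blocks_complete(self, reference, kv133_kj1):
        seq = "X" + kv133_kj1[1:]
        a = assign_germline(_record(seq), reference)
        assert a.coverage_class != "complete"

    def test_partition_is_total(self, reference, kv133_kj1):
        rng = np.random.default_rng(17)
        for cut in (0, 10, 30, 50, 90):
            seq = kv133_kj1[cut:]
            a = assign_germline(_record(seq), reference)
            assert a.coverage_class in ("complete", "incomplete", "excluded")


class TestCollapseDuplicates:
    def test_three_identical_collapse_to_one(self):
        records = [_record("ACDEFGHIKL" * 11, rid=f"r{i}") for i in range(3)]
        kept, consensus, log = collapse_duplicates(records)
        assert len(kept) + len(consensus) == 1
        survivor = (kept + consensus)[0]
        assert survivor.seq == "ACDEFGHIKL" * 11
        assert set(log["record_id"]) == {"r0", "r1", "r2"}

    def test_one_one_tie_excluded_as_ambiguous(self):
        base = "ACDEFGHIKL" * 11
        variant = "C" + base[1:]
        kept, consensus, log = collapse_duplicates([_record(base, "a"), _record(variant, "b")])
        assert kept == [] and consensus == []
        assert set(log["disposition"]) == {"excluded"}
        assert set(log["reason"]) == {"ambiguous consensus"}

    def test_majority_consensus_resolves_conflict(self):
        base = "ACDEFGHIKL" * 11
        variant = "C" + base[1:]
        records = [_record(base, "a"), _record(base, "b"), _record(variant, "c")]
        kept, consensus, log = collapse_duplicates(records)
        assert len(kept) + len(consensus) == 1
        assert (kept + consensus)[0].seq == base

    def test_longest_nucleotide_preferred(self):
        long_nt = RearrangedRecord("long", "ACDEFGHIKL" * 11, molecule="nucleotide")
        short_aa = RearrangedRecord("short", ("ACDEFGHIKL" * 11)[:108], molecule="protein")
        kept, consensus, log = collapse_duplicates([short_aa, long_nt])
        assert len(kept) == 1
        assert kept[0].record_id == "long"
        assert log.set_index("record_id").at["short", "disposition"] == "merged"

    def test_distinct_sequences_all_kept(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        records = [
            _record("".join(rng.choice(aas, 110)), rid=f"r{i}") for i in range(20)
        ]
        kept, consensus, log = collapse_duplicates(records)
        assert len(kept) == 20 and not consensus

    def test_every_record_appears_once_in_log(self, reference):
        spec = CohortSpec(
            name="AL", n_sequences=150,
            gene_usage={"IGKV1-33": 0.5, "IGLV6-57": 0.5},
            j_usage={"IGKJ1": 0.5, "IGLJ2": 0.5},
            sub_rate=0.05, duplicate_prob=0.3, seed=3,
        )
        records, _, _ = generate_cohort(spec, reference)
        kept, consensus, log = collapse_duplicates(records)
        assert sorted(log["record_id"]) == sorted(r.record_id for r in records)
        assert log["record_id"].is_unique

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            collapse_duplicates([_record("A" * 100)], identity_threshold=0.5)
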