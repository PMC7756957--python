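"""Exact mapper, junction evidence, calling and cross-library filtering."""

import numpy as np
import pandas as pd
import pytest

from epiphase.config import InsertionParams
from epiphase.insertions import (
    Alignment,
    JunctionEvidence,
    KmerIndex,
    call_insertions,
    collect_evidence,
    family_transposition_table,
    filter_sample_specific,
    map_read,
    map_reads_exact,
    retained,
)
from epiphase.intervals import FeatureRecord, FeatureTable, GenomicInterval
from epiphase.simulate import (
    GenomeSpec,
    InsertionSimSpec,
    build_genome,
    revcomp,
    simulate_insertions_and_reads,
)


@pytest.fixture(scope="module")
def world():
    """Tiny deterministic reference with one annotated TE."""
    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, 5000)].tobytes().decode()
    te_seq = bases[rng.integers(0, 4, 600)].tobytes().decode()
    ref = {"chr1": seq[:2000] + te_seq + seq[2000:]}
    features = FeatureTable(
        [FeatureRecord(GenomicInterval("chr1", 2000, 2600), "te1", "TE", "FamA")]
    )
    return ref, features, te_seq


class TestMapper:
    def test_exact_read_full_alignment(self, world):
        ref, _, _ = world
        read = ref["chr1"][1000:1100]
        aln = map_read("r", read, KmerIndex(ref))
        assert (aln.ref_start, aln.ref_end) == (1000, 1100)
        assert aln.clip_left == "" and aln.clip_right == ""

    def test_reverse_complement_read_mapped(self, world):
        ref, _, _ = world
        aln = map_read("r", revcomp(ref["chr1"][1000:1100]), KmerIndex(ref))
        assert (aln.ref_start, aln.ref_end, aln.strand) == (1000, 1100, "-")

    def test_junction_read_records_clip(self, world):
        ref, _, te_seq = world
        # 50 bp of genome upstream of position 4000 then 50 bp of TE start
        read = ref["chr1"][3950:4000] + te_seq[:50]
        aln = map_read("r", read, KmerIndex(ref))
        # best placement anchors one side; a ~50-bp clip remains (maximal
        # exact extension may absorb a base or two of chance microhomology)
        assert 45 <= max(len(aln.clip_left), len(aln.clip_right)) <= 50

    def test_repeat_tie_broken_deterministically(self):
        rng = np.random.default_rng(3)
        block = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, 400)].tobytes().decode()
        pad = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, 500)].tobytes().decode()
        ref = {"chr1": pad + block + pad[::-1] + block + pad}
        read = block[100:200]
        alns = {map_read("r", read, KmerIndex(ref)).ref_start for _ in range(5)}
        assert alns == {600}  # lowest coordinate of the two identical copies

    def test_read_shorter_than_seed_unmapped(self, world):
        ref, _, _ = world
        assert map_read("r", "ACGTACGT", KmerIndex(ref)) is None


class TestEvidence:
    def test_planted_split_counts_per_side(self, world):
        ref, features, te_seq = world
        x = 4000  # insertion junction in reference coordinates
        r1 = [
            (f"L{i}", ref["chr1"][x - 80 - i : x - i] + te_seq[: 20 + i])
            for i in range(3)
        ]
        r1 += [
            (f"R{i}", te_seq[-(20 + i) :] + ref["chr1"][x : x + 80 - i])
            for i in range(2)
        ]
        a1 = map_reads_exact(r1, ref)
        ev = collect_evidence(a1, {}, features, ref)
        assert len(ev) == 1
        assert (ev[0].left_split, ev[0].right_split) == (3, 2)
        assert ev[0].family == "FamA"

    def test_short_clip_ignored(self, world):
        ref, features, te_seq = world
        x = 4000
        read = ref["chr1"][x - 90 : x] + te_seq[:10]  # clip below min_clip=15
        ev = collect_evidence(map_reads_exact([("r", read)], ref), {}, features, ref)
        assert ev == []

    def test_concordant_library_no_clusters(self, world):
        ref, features, _ = world
        reads = [(f"r{i}", ref["chr1"][i * 50 : i * 50 + 100]) for i in range(40)]
        ev = collect_evidence(map_reads_exact(reads, ref), {}, features, ref)
        assert ev == []


def _ev(chrom, pos, family, left, right):
    return JunctionEvidence(
        chrom=chrom, start=pos, end=pos + 1, family=family,
        left_split=left, right_split=right,
        left_positions=[pos] * max(left, 1), right_positions=[pos] * max(right, 1),
        left_split_positions=[pos] * left, right_split_positions=[pos] * right,
    )


class TestCalling:
    def test_one_sided_cluster_not_called(self):
        ev = _ev("chr1", 500, "FamA", 2, 0)
        ev.right_positions = []
        assert call_insertions([ev], {}, []).empty

    def test_donor_span_exclusion(self):
        calls = call_insertions(
            [_ev("chr1", 2100, "FamA", 2, 2)],
            {"FamA": GenomicInterval("chr1", 2000, 2600)},
            [],
        )
        assert calls["excluded_reason"].iloc[0] == "donor_span"

    def test_centromere_exclusion(self):
        calls = call_insertions(
            [_ev("chr1", 7000, "FamA", 1, 1)],
            {},
            [GenomicInterval("chr1", 6500, 7500)],
        )
        assert calls["excluded_reason"].iloc[0] == "centromeric"

    def test_planted_insertions_called_within_5bp(self, small_genome):
        donor = small_genome.features.tes().ids()[0]
        fam = small_genome.features[donor].superfamily
        r1, r2, truth = simulate_insertions_and_reads(
            small_genome, InsertionSimSpec(donor, n_insertions=5, coverage=30), seed=17
        )
        a1 = map_reads_exact(r1, small_genome.sequences)
        a2 = map_reads_exact(r2, small_genome.sequences)
        ev = collect_evidence(a1, a2, small_genome.features, small_genome.sequences, small_genome.consensus)
        calls = retained(call_insertions(
            ev, {fam: small_genome.features[donor].interval}, small_genome.centromere_mask
        ))
        centers = ((calls["start"] + calls["end"]) // 2).to_numpy()
        for x in truth["position"]:
            assert np.abs(centers - x).min() <= 5

    def test_read_order_permutation_invariance(self, small_genome):
        donor = small_genome.features.tes().ids()[0]
        fam = small_genome.features[donor].superfamily
        r1, r2, _ = simulate_insertions_and_reads(
            small_genome, InsertionSimSpec(donor, n_insertions=2, coverage=15), seed=23
        )
        donor_spans = {fam: small_genome.features[donor].interval}

        def call(rr1, rr2):
            a1 = map_reads_exact(rr1, small_genome.sequences)
            a2 = map_reads_exact(rr2, small_genome.sequences)
            ev = collect_evidence(a1, a2, small_genome.features, small_genome.sequences, small_genome.consensus)
            return call_insertions(ev, donor_spans, small_genome.centromere_mask)

        base = call(r1, r2)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(r1))
        permuted = call([r1[i] for i in order], [r2[i] for i in order])
        cols = ["chrom", "start", "end", "family", "excluded_reason"]
        assert base[cols].sort_values(cols).reset_index(drop=True).equals(
            permuted[cols].sort_values(cols).reset_index(drop=True)
        )


class TestSampleSpecificity:
    def _calls(self, lib, rows):
        return pd.DataFrame(
            [
                {"library": lib, "chrom": "chr1", "start": s, "end": s + 1,
                 "family": fam, "left_split": 1, "right_split": 1,
                 "left_discordant": 0, "right_discordant": 0,
                 "excluded_reason": "none"}
                for s, fam in rows
            ]
        )

    def test_shared_call_dropped_from_both(self):
        out = filter_sample_specific(
            {"l1": self._calls("l1", [(500, "FamA")]),
             "l2": self._calls("l2", [(520, "FamA")])}
        )
        assert (out["l1"]["excluded_reason"] == "multi_library").all()
        assert (out["l2"]["excluded_reason"] == "multi_library").all()

    def test_private_call_retained(self):
        out = filter_sample_specific(
            {"l1": self._calls("l1", [(500, "FamA")]),
             "l2": self._calls("l2", [(5000, "FamA")]),
             "l3": self._calls("l3", [(9000, "FamB")])}
        )
        assert all(len(retained(df)) == 1 for df in out.values())

    def test_shared_ancestral_vs_private_mixture(self):
        shared = (1000, "FamA")
        out = filter_sample_specific(
            {"l1": self._calls("l1", [shared, (3000, "FamA")]),
             "l2": self._calls("l2", [shared, (7000, "FamB")])}
        )
        assert set(retained(out["l1"])["start"]) == {3000}
        assert set(retained(out["l2"])["start"]) == {7000}

    def test_single_library_identity(self):
        calls = {"only": self._calls("only", [(100, "FamA")])}
        assert filter_sample_specific(calls)["only"].equals(calls["only"])


class TestFamilyTable:
    def test_counts_and_design_zeros(self):
        t = TestSampleSpecificity()
        calls = {"l1": t._calls("l1", [(i * 1000 + 100, "FamA") for i in range(5)]),
                 "l2": t._calls("l2", [])}
        mat = family_transposition_table(calls, design_families=["FamA", "FamB"])
        assert mat.loc["FamA", "l1"] == 5
        assert mat.loc["FamB", "l1"] == 0
        assert (mat["l2"] == 0).all()

    def test_empty_calls_all_zero(self):
        t = TestSampleSpecificity()
        calls = {"l1": t._calls("l1", []), "l2": t._calls("l2", [])}
        mat = family_transposition_table(calls, design_families=["FamA"])
        assert (mat.to_numpy() == 0).all()


def test_no_insertion_library_zero_false_calls(small_genome):
    donor = small_genome.features.tes().ids()[0]
    fam = small_genome.features[donor].superfamily
    r1, r2, truth = simulate_insertions_and_reads(
        small_genome, InsertionSimSpec(donor, n_insertions=0, coverage=30), seed=29
    )
    assert truth.empty
    a1 = map_reads_exact(r1, small_genome.sequences)
    a2 = map_reads_exact(r2, small_genome.sequences)
    ev = collect_evidence(a1, a2, small_genome.features, small_genome.sequences, small_genome.consensus)
    calls = call_insertions(ev, {fam: small_genome.features[donor].interval}, small_genome.centromere_mask)
    assert len(retained(calls)) == 0
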