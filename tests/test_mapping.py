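"""Glocal mapper: exactness, oracle equivalence, strand symmetry, SAM I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_glocal

from tsmstools import mapping, simulate
from tsmstools._seq import encode, revcomp

PARAMS = mapping.MappingParams()


@pytest.fixture(scope="module")
def linear_index():
    rng = np.random.default_rng(5)
    ref = "".join(rng.choice(list("ACGT"), 5000))
    refs = simulate.ReferenceSet({"chr": ref})
    return ref, mapping.ReferenceIndex(refs)


def test_exact_read_maps_exactly(linear_index):
    ref, idx = linear_index
    aln = mapping.map_read("r", ref[1000:1030], idx)
    assert (aln.pos, aln.strand, aln.mapq, aln.unique) == (1000, "+", 60, True)
    assert aln.ops == [("MATCH", 30)]


def test_reverse_complement_maps_to_same_locus(linear_index):
    ref, idx = linear_index
    fwd = mapping.map_read("f", ref[2000:2034], idx)
    rev = mapping.map_read("r", revcomp(ref[2000:2034]), idx)
    assert (fwd.pos, fwd.score) == (rev.pos, rev.score)
    assert {fwd.strand, rev.strand} == {"+", "-"}


def test_mismatch_read_recorded_as_x_op(linear_index):
    ref, idx = linear_index
    read = ref[3000:3030]
    read = read[:12] + ("A" if read[12] != "A" else "C") + read[13:]
    aln = mapping.map_read("m", read, idx)
    assert aln.pos == 3000
    assert ("MISMATCH", 1) in aln.ops
    assert aln.score == 30 - 3  # one match lost, one mismatch penalty gained


def test_circular_reference_wraps():
    rng = np.random.default_rng(6)
    ref = "".join(rng.choice(list("ACGT"), 2000))
    refs = simulate.ReferenceSet({"mt": ref}, frozenset({"mt"}))
    idx = mapping.ReferenceIndex(refs)
    aln = mapping.map_read("w", ref[1985:] + ref[:15], idx)
    assert aln.pos == 1985
    assert aln.ops == [("MATCH", 30)]


def test_repeated_sequence_not_unique():
    unit = "ACGTTGCAACGTAGCTAGGATCCATTGCAC"
    ref = unit + "TTTTTTTTTTGGGGGGGGGG" + unit
    refs = simulate.ReferenceSet({"rep": ref})
    aln = mapping.map_read("r", unit, mapping.ReferenceIndex(refs))
    assert aln is None or (not aln.unique and aln.mapq == 0)


def test_vectorized_dp_matches_brute_force_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(80):
        ref = "".join(rng.choice(list("ACGT"), rng.integers(30, 200)))
        read = list(ref[: rng.integers(8, min(40, len(ref)))])
        for _ in range(int(rng.integers(0, 5))):
            i = int(rng.integers(0, len(read)))
            op = int(rng.integers(0, 3))
            if op == 0:
                read[i] = str(rng.choice(list("ACGT")))
            elif op == 1 and len(read) > 6:
                read.pop(i)
            else:
                read.insert(i, str(rng.choice(list("ACGT"))))
        read = "".join(read)
        fast, _ = mapping._glocal_score(encode(read), encode(ref), PARAMS)
        assert fast == brute_force_glocal(read, ref)


@given(
    read=st.text(alphabet="ACGT", min_size=5, max_size=25),
    ref=st.text(alphabet="ACGT", min_size=20, max_size=200),
)
@settings(max_examples=60)
def test_dp_score_oracle_property(read, ref):
    fast, _ = mapping._glocal_score(encode(read), encode(ref), PARAMS)
    assert fast == brute_force_glocal(read, ref)


def test_traceback_score_consistent(linear_index):
    ref, idx = linear_index
    rng = np.random.default_rng(23)
    for _ in range(25):
        p = int(rng.integers(0, 4950))
        read = list(ref[p : p + 32])
        i = int(rng.integers(0, len(read)))
        read[i] = str(rng.choice(list("ACGT")))
        aln = mapping.map_read("t", "".join(read), idx)
        if aln is None:
            continue
        score = {"MATCH": 1, "MISMATCH": -2, "INS": -2, "DEL": -2}
        recomputed = sum(score[op] * n for op, n in aln.ops)
        assert recomputed == aln.score


def test_competitive_filter_drops_decoy_hits(linear_index):
    ref, idx = linear_index
    decoy_refs = simulate.ReferenceSet({"decoy": ref[:2500]})
    decoy_idx = mapping.ReferenceIndex(decoy_refs)
    reads = {
        "shared": ref[100:135],  # present in both target and decoy
        "target_only": ref[4000:4035],
    }
    target = mapping.map_reads(reads, idx)
    decoy = mapping.map_reads(reads, decoy_idx)
    kept = mapping.competitive_filter(target, decoy)
    assert "target_only" in kept
    assert "shared" not in kept


def test_sam_round_trip(tmp_path, linear_index):
    ref, idx = linear_index
    rng = np.random.default_rng(31)
    reads = {}
    for i in range(20):
        p = int(rng.integers(0, 4950))
        s = ref[p : p + 34]
        if i % 2:
            s = revcomp(s)
        reads[f"r{i}"] = s
    alns = mapping.map_reads(reads, idx)
    path = tmp_path / "out.sam"
    mapping.write_sam(alns.values(), reads, {"chr": len(ref)}, path)
    back, seqs, skipped = mapping.read_sam(path)
    assert skipped == 0
    assert len(back) == len(alns)
    by_id = {a.read_id: a for a in back}
    for rid, a in alns.items():
        b = by_id[rid]
        assert (b.ref_id, b.pos, b.strand, b.ops) == (a.ref_id, a.pos, a.strand, a.ops)
        assert seqs[rid] == reads[rid]


def test_planted_reads_recovered(linear_index):
    ref, idx = linear_index
    rng = np.random.default_rng(41)
    n_ok = 0
    for _ in range(100):
        p = int(rng.integers(0, 4960))
        aln = mapping.map_read("p", ref[p : p + 30], idx)
        n_ok += aln is not None and aln.pos == p and aln.strand == "+"
    assert n_ok >= 98  # rare repeats may be non-unique
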