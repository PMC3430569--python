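"""Template preparation: melting, phosphatase, capture, fill-and-lock, reads."""

import numpy as np
import pytest

from tsmstools import prep, simulate
from tsmstools._seq import revcomp


def _frag(template, end3_chem="OH", lost="G", strand="+"):
    return simulate.Fragment(
        origin="endo_nuclear",
        ref_id="endo_nuclear",
        start=0,
        end=len(template),
        strand=strand,
        template_seq=template,
        deam_sites=[],
        end3_chem=end3_chem,
        lost_base_3prime=lost,
    )


def _deterministic_cfg(**kw):
    base = dict(
        p_incomplete_fill=0.0,
        lock_success={"G": 1.0, "C": 1.0, "T": 1.0, "A": 1.0},
        sub_rate=0.0,
        del_rate=0.0,
        ins_rate=0.0,
        artifact_read_rate=0.0,
    )
    base.update(kw)
    return prep.PrepConfig(**base)


# ---------------------------------------------------------------------------
# fill-and-lock
# ---------------------------------------------------------------------------


def test_fill_and_lock_hand_trace():
    # template 5'-GATTCAAA-3': the genomic A-run is consumed by the dTTP
    # fill, the lock engages at the C, and sequencing starts at the
    # penultimate base of the remaining template, read 5'->3' = AATC.
    cfg = _deterministic_cfg()
    lt = prep.fill_and_lock(
        prep.PreparedTemplate(_frag("GATTCAAA"), 90), cfg, np.random.default_rng(0)
    )
    assert lt.lock_index == 4
    assert lt.required_base == "G"
    assert lt.a_run == 3
    assert lt.leading_t == 0
    assert prep._ideal_read(lt) == "AATC"
    minus1, minus2 = prep._truth_context(lt)
    assert minus1 == "G"  # complement of the locked C, read strand
    assert minus2 == "T"  # first filled A of the genomic run, read strand


def test_fill_and_lock_no_a_run():
    # no trailing A: lock at the terminal base, -2 is the lost genomic base
    cfg = _deterministic_cfg()
    lt = prep.fill_and_lock(
        prep.PreparedTemplate(_frag("GATTC", lost="G"), 90),
        cfg,
        np.random.default_rng(0),
    )
    assert lt.lock_index == 4
    assert lt.a_run == 0
    minus1, minus2 = prep._truth_context(lt)
    assert minus1 == "G"
    assert minus2 == "C"  # complement of the lost purine G


def test_fill_and_lock_all_a_template_fails():
    cfg = _deterministic_cfg()
    lt = prep.fill_and_lock(
        prep.PreparedTemplate(_frag("AAAAAA"), 90), cfg, np.random.default_rng(0)
    )
    assert lt is None


def test_incomplete_fill_gives_leading_ts():
    cfg = _deterministic_cfg(p_incomplete_fill=1.0)
    lt = prep.fill_and_lock(
        prep.PreparedTemplate(_frag("GATTCAAA"), 90), cfg, np.random.default_rng(1)
    )
    assert lt.leading_t >= 2
    assert prep._ideal_read(lt).startswith("T" * lt.leading_t)


# ---------------------------------------------------------------------------
# chemistry gates
# ---------------------------------------------------------------------------


def test_phosphatase_converts_phosphate_only():
    frags = [_frag("ACGT", c) for c in ("OH", "PHOSPHATE", "BLOCKED")]
    out = prep.phosphatase_treat(frags)
    assert [f.end3_chem for f in out] == ["OH", "OH", "BLOCKED"]
    assert prep.phosphatase_treat(out) == out  # idempotent


def test_capture_requires_hydroxyl_end():
    cfg = prep.PrepConfig()
    frags = [_frag("ACGTACGT", c) for c in ("OH", "PHOSPHATE", "BLOCKED")]
    captured = prep.polya_tail_and_capture(frags, cfg, np.random.default_rng(0))
    assert all(pt.fragment.end3_chem == "OH" for pt in captured)
    assert len(captured) == 1


def test_melting_midpoint_monotone_in_damage_and_gc():
    cfg = prep.PrepConfig()
    base = _frag("ACGT" * 10)
    damaged = simulate.Fragment(
        **{**base.__dict__, "deam_sites": [0, 4, 8], "template_seq": base.template_seq}
    )
    assert prep.melting_midpoint(damaged, cfg) < prep.melting_midpoint(base, cfg)
    gc_rich = _frag("GCGC" * 10)
    assert prep.melting_midpoint(gc_rich, cfg) > prep.melting_midpoint(base, cfg)


def test_95c_denatures_more_than_80c(endo_fragments):
    frags, _ = endo_fragments
    d80 = prep.denature(frags, prep.PrepConfig(temperature=80), np.random.default_rng(4))
    d95 = prep.denature(frags, prep.PrepConfig(temperature=95), np.random.default_rng(4))
    assert len(d95) > len(d80)


def test_nicking_conserves_sequence():
    frag = _frag("ACGTTGCAACGTAGCTAGGATCCA" * 4, end3_chem="PHOSPHATE", lost="A")
    pieces = prep._nick(frag, 0.2, prep.PrepConfig().nick_end_chem, np.random.default_rng(8))
    assert "".join(p.template_seq for p in pieces) == frag.template_seq
    assert pieces[-1].end3_chem == "PHOSPHATE"
    assert pieces[-1].lost_base_3prime == "A"


def test_phosphatase_increases_reads(endo_fragments):
    frags, _ = endo_fragments
    base = prep.PrepConfig(temperature=80, phosphatase=False)
    phos = prep.PrepConfig(temperature=80, phosphatase=True)
    r0, _ = prep.run_prep(frags, base, seed=21)
    r1, _ = prep.run_prep(frags, phos, seed=21)
    assert len(r1) > len(r0)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def test_stage_counts_are_conserved(prep_reads):
    _, counts = prep_reads
    assert counts["captured"] <= counts["denatured"]
    assert counts["locked"] <= counts["captured"]
    assert counts["denatured"] <= counts["fragments"]


def test_errorless_read_is_template_revcomp():
    cfg = _deterministic_cfg(read_len_cap=100, read_len_mean=100.0)
    template = "GATTCCGTAGGCTTAACAAA"
    lt = prep.fill_and_lock(
        prep.PreparedTemplate(_frag(template), 90), cfg, np.random.default_rng(0)
    )
    read = prep._ideal_read(lt)
    # read = revcomp of the template up to (excluding) the lock site
    assert read == revcomp(template[: lt.lock_index])


def test_reads_capped_at_length_limit(prep_reads):
    reads, _ = prep_reads
    cap = prep.PrepConfig().read_len_cap
    assert all(len(r.seq) <= cap for r in reads)
    assert all(set(r.seq) <= set("ACGT") for r in reads)


def test_spiked_channel_mostly_spike_reads(endo_fragments):
    frags, _ = endo_fragments
    oligos = simulate.make_spike_oligos(10, seed=3)
    cfg = prep.PrepConfig(temperature=80, spike_fraction=0.85)
    reads, _ = prep.run_prep(frags, cfg, seed=5, oligos=oligos)
    spike = sum(r.origin.startswith("spike") for r in reads)
    assert 0.7 < spike / len(reads) < 0.95


def test_fastq_round_trip(tmp_path, prep_reads):
    reads, _ = prep_reads
    path = tmp_path / "reads.fastq"
    prep.write_fastq(reads, path)
    back = prep.read_fastq(path)
    assert back == {r.read_id: r.seq for r in reads}


def test_invalid_temperature_rejected():
    with pytest.raises(ValueError):
        prep.PrepConfig(temperature=70).validate()
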