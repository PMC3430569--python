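"""Fragment simulation: coordinates, damage statistics, end chemistry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tsmstools import simulate
from tsmstools._seq import gc_fraction, revcomp

PURINES = set("AG")


def _slice_for(refs, frag):
    raw = refs.slice(frag.ref_id, frag.start, frag.end)
    return raw if frag.strand == "+" else revcomp(raw)


def test_reference_gc_near_target(small_refs):
    for rid, seq in small_refs.sequences.items():
        assert abs(gc_fraction(seq) - 0.5) < 0.02, rid


def test_mito_reference_is_circular(small_refs):
    assert "endo_mito" in small_refs.circular
    assert "endo_nuclear" not in small_refs.circular


def test_spike_oligos_distinct_and_sized():
    oligos = simulate.make_spike_oligos(30, seed=5)
    seqs = list(oligos.oligos.values())
    assert len(set(seqs)) == 30
    assert all(25 <= len(s) <= 60 for s in seqs)


def test_fragment_matches_reference_slice(small_refs, endo_fragments):
    frags, _ = endo_fragments
    for frag in frags:
        assert frag.genomic_template() == _slice_for(small_refs, frag)


def test_deaminated_sites_are_t_over_c(small_refs, endo_fragments):
    frags, _ = endo_fragments
    n_sites = 0
    for frag in frags:
        genomic = _slice_for(small_refs, frag)
        for i in frag.deam_sites:
            assert genomic[i] == "C"
            assert frag.template_seq[i] == "T"
            n_sites += 1
    assert n_sites > 100  # damage model actually fires


def test_fragment_lengths_bounded(endo_fragments):
    frags, cfg = endo_fragments
    assert all(1 <= len(f) <= cfg.max_frag_length for f in frags)


def test_origin_mixture_respected(small_refs):
    cfg = simulate.FragmentConfig(n_fragments=6_000)
    frags = simulate.draw_fragments(small_refs, cfg, seed=11)
    frac = sum(f.origin == "microbial" for f in frags) / len(frags)
    assert abs(frac - cfg.origin_mixture["microbial"]) < 0.01


def test_lost_base_purine_fraction_matches_closed_form(endo_fragments):
    frags, cfg = endo_fragments
    lam, fp = cfg.depurination_odds, 0.5
    expected = lam * fp / (lam * fp + (1 - fp))
    obs = [f.lost_base_3prime in PURINES for f in frags if f.lost_base_3prime != "N"]
    p_hat = np.mean(obs)
    se = math.sqrt(expected * (1 - expected) / len(obs))
    assert abs(p_hat - expected) < 4 * se


def test_deamination_probability_decays_from_ends():
    cfg = simulate.FragmentConfig()
    probs = [simulate.deamination_probability(d5, 100, cfg) for d5 in range(0, 30)]
    assert all(a >= b for a, b in zip(probs, probs[1:]))
    assert probs[0] == pytest.approx(cfg.p_base + cfg.p_end5, abs=1e-9)


def test_deamination_probability_capped_at_one():
    cfg = simulate.FragmentConfig(p_end5=0.9, p_end3=0.9, p_base=0.5)
    assert simulate.deamination_probability(0, 1, cfg) == 1.0


def test_exogenous_fragments_undamaged_and_long(small_refs):
    cfg = simulate.FragmentConfig(
        n_fragments=500,
        origin_mixture={
            "endo_nuclear": 0.0,
            "endo_mito": 0.0,
            "decoy": 0.0,
            "microbial": 1.0,
        },
    )
    frags = simulate.deaminate_all(simulate.draw_fragments(small_refs, cfg, 3), cfg, 4)
    assert all(not f.deam_sites for f in frags)
    assert all(len(f) >= cfg.exo_min_length for f in frags)
    assert np.mean([len(f) for f in frags]) > 100


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        simulate.FragmentConfig(depurination_odds=0.5).validate()
    with pytest.raises(ValueError):
        simulate.FragmentConfig(
            origin_mixture={"endo_nuclear": 0.5, "microbial": 0.6}
        ).validate()


def test_fasta_round_trip(tmp_path, small_refs):
    path = tmp_path / "refs.fasta"
    simulate.write_fasta(small_refs.sequences, path)
    back = simulate.read_fasta(path)
    assert back == small_refs.sequences


def test_draw_is_reproducible(small_refs):
    cfg = simulate.FragmentConfig(n_fragments=200)
    a = simulate.draw_fragments(small_refs, cfg, seed=9)
    b = simulate.draw_fragments(small_refs, cfg, seed=9)
    assert [(f.ref_id, f.start, f.end, f.strand) for f in a] == [
        (f.ref_id, f.start, f.end, f.strand) for f in b
    ]


@given(
    lam=st.floats(min_value=1.0, max_value=8.0),
    fp=st.floats(min_value=0.2, max_value=0.8),
)
def test_purine_loss_probability_closed_form_bounds(lam, fp):
    p = lam * fp / (lam * fp + (1 - fp))
    assert fp <= p <= 1.0
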