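"""Template preparation and single-molecule read synthesis.

Models the Helicos-style workflow stage by stage:

1. **Denaturation** (80 or 95 degC): a fragment yields a sequenceable single
   strand with probability logistic((T - Tm)/s) where the melting midpoint
   Tm rises with GC and length and falls with deamination load.  Mild (80 degC)
   denaturation therefore favors short, damaged endogenous templates over
   long microbial contaminants; 95 degC additionally nicks surviving strands.
2. **Phosphatase** (optional): restores 3'-OH on 3'-phosphate termini.
3. **Poly-A tailing + oligo-dT capture**: only 3'-OH templates are tailed;
   capture requires a minimum tail length.
4. **Fill-and-lock**: dTTP fills the tail complement *and* any genomic A-run
   at the template 3' terminus; a terminating nucleotide locks at the first
   non-A template base (dGTP is incorporated most efficiently).  Incomplete
   fill occasionally locks early inside the A-run, leaving >= 2 leading T's
   on the read.
5. **Sequencing**: the read is the complement of the template walked 3'->5'
   starting at the penultimate (relative to the lock) base, with indel-heavy
   errors; flow-order artifact reads and spike-oligo reads are injected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import BASES, complement, gc_fraction, revcomp
from .simulate import (
    BLOCKED,
    OH,
    PHOSPHATE,
    Fragment,
    SpikeOligoSet,
    _rng,
    _sample_chem,
)

ARTIFACT = "ARTIFACT"
SPIKE = "spike"


@dataclass
class PrepConfig:
    """Knobs of the template-preparation and sequencing model."""

    temperature: int = 80                 # denaturation temperature, degC
    phosphatase: bool = False
    # melting model: Tm = t0 + t_gc*GC - t_dam*deam_fraction + t_len*log10(len)
    t0: float = 60.0
    t_gc: float = 20.0
    t_dam: float = 100.0
    t_len: float = 8.0
    s: float = 3.0                        # logistic scale, degC
    extra_nick_rate_95: float = 0.01      # per-bond, applied only at 95 degC
    nick_end_chem: Dict[str, float] = field(
        default_factory=lambda: {OH: 0.60, PHOSPHATE: 0.25, BLOCKED: 0.15}
    )
    tail_mean: float = 90.0
    tail_min: int = 0
    capture_min_tail: int = 25
    lock_success: Dict[str, float] = field(
        default_factory=lambda: {"G": 0.90, "C": 0.55, "T": 0.55, "A": 0.55}
    )
    p_incomplete_fill: float = 0.05
    sub_rate: float = 0.005
    del_rate: float = 0.03
    ins_rate: float = 0.015
    read_len_mean: float = 33.0
    read_len_cap: int = 60
    flow_order: str = "CTAG"
    artifact_read_rate: float = 0.01
    spike_fraction: float = 0.0
    spike_chimera_rate: float = 0.02
    seed: int = 0

    def validate(self) -> "PrepConfig":
        if self.temperature not in (80, 95):
            raise ValueError("temperature must be 80 or 95")
        if not self.flow_order or set(self.flow_order) - set(BASES):
            raise ValueError("flow_order must be a non-empty string over ACGT")
        for p in (
            self.extra_nick_rate_95,
            self.p_incomplete_fill,
            self.sub_rate,
            self.del_rate,
            self.ins_rate,
            self.artifact_read_rate,
            self.spike_fraction,
            self.spike_chimera_rate,
            *self.lock_success.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        return self


@dataclass
class PreparedTemplate:
    """A captured, poly-A-tailed template."""

    fragment: Fragment
    tail_len: int


@dataclass
class LockedTemplate:
    """A template with an engaged lock, ready to sequence.

    ``lock_index`` is the template offset of the lock site (first non-A base
    scanning 3'->5'); ``leading_t`` > 0 marks an early lock inside the fill.
    """

    fragment: Fragment
    lock_index: int
    required_base: str
    leading_t: int = 0

    @property
    def a_run(self) -> int:
        return len(self.fragment.template_seq) - 1 - self.lock_index


@dataclass
class ReadRecord:
    """A simulated read with hidden truth labels."""

    read_id: str
    seq: str
    origin: str            # fragment origin, "spike", "spike_chimera" or "ARTIFACT"
    source_id: str         # fragment index / oligo id / "-"
    leading_t: int = 0
    minus1_truth: str = "N"   # complement of lock-site template base (read strand)
    minus2_truth: str = "N"   # read-strand truth base one past the template 3' end
    n_del: int = 0            # deleted template bases within the emitted read span
    n_template: int = 0       # template bases consumed by the emitted read


# ---------------------------------------------------------------------------
# stage 1: denaturation
# ---------------------------------------------------------------------------


def melting_midpoint(fragment: Fragment, cfg: PrepConfig) -> float:
    L = max(1, len(fragment.template_seq))
    return (
        cfg.t0
        + cfg.t_gc * gc_fraction(fragment.genomic_template())
        - cfg.t_dam * fragment.deam_fraction
        + cfg.t_len * np.log10(L)
    )


def denature(
    fragments: Sequence[Fragment], cfg: PrepConfig, seed=None
) -> List[Fragment]:
    """Survival by logistic((T - Tm)/s); 95 degC adds per-bond nicks."""
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    out: List[Fragment] = []
    for frag in fragments:
        tm = melting_midpoint(frag, cfg)
        p = 1.0 / (1.0 + np.exp(-(cfg.temperature - tm) / cfg.s))
        if rng.random() >= p:
            continue
        if cfg.temperature == 95 and cfg.extra_nick_rate_95 > 0:
            out.extend(_nick(frag, cfg.extra_nick_rate_95, cfg.nick_end_chem, rng))
        else:
            out.append(frag)
    return out


def _nick(
    frag: Fragment, rate: float, nick_chem: Dict[str, float], rng
) -> List[Fragment]:
    """Split a template at per-bond nicks; pieces inherit nick-type 3' ends.

    The 3'-most piece keeps the original end chemistry and lost base.
    """
    L = len(frag.template_seq)
    if L < 2:
        return [frag]
    cuts = np.nonzero(rng.random(L - 1) < rate)[0] + 1  # template offsets
    if len(cuts) == 0:
        return [frag]
    bounds = [0, *cuts.tolist(), L]
    genomic = frag.genomic_template()
    deam = set(frag.deam_sites)
    pieces = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 - t0 == 0:
            continue
        if frag.strand == "+":
            g0, g1 = frag.start + t0, frag.start + t1
        else:
            g0, g1 = frag.end - t1, frag.end - t0
        if t1 == L:  # 3'-most piece keeps the original end
            chem, lost = frag.end3_chem, frag.lost_base_3prime
        else:
            chem = _sample_chem(nick_chem, rng)
            lost = genomic[t1]  # nick: adjacent base, nothing actually lost
        pieces.append(
            dataclasses.replace(
                frag,
                start=g0,
                end=g1,
                template_seq=frag.template_seq[t0:t1],
                deam_sites=sorted(d - t0 for d in deam if t0 <= d < t1),
                end3_chem=chem,
                lost_base_3prime=lost,
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# stages 2-4
# ---------------------------------------------------------------------------


def phosphatase_treat(fragments: Iterable[Fragment]) -> List[Fragment]:
    """3'-phosphate -> 3'-OH; OH and blocked ends unchanged.  Idempotent."""
    return [
        dataclasses.replace(f, end3_chem=OH) if f.end3_chem == PHOSPHATE else f
        for f in fragments
    ]


def polya_tail_and_capture(
    fragments: Sequence[Fragment], cfg: PrepConfig, seed=None
) -> List[PreparedTemplate]:
    """Tail 3'-OH templates (Poisson lengths) and keep those with long tails."""
    rng = _rng(cfg.seed if seed is None else seed)
    out = []
    for f in fragments:
        if f.end3_chem != OH:
            continue
        tail = max(cfg.tail_min, int(rng.poisson(cfg.tail_mean)))
        if tail >= cfg.capture_min_tail:
            out.append(PreparedTemplate(f, tail))
    return out


def fill_and_lock(
    prepared: PreparedTemplate, cfg: PrepConfig, seed=None
) -> Optional[LockedTemplate]:
    """Fill the tail + genomic 3' A-run with dTTP, lock at the first non-A base.

    Returns None on lock failure or an all-A template.  The required lock
    nucleotide is the complement of the lock-site template base; success
    probability comes from ``cfg.lock_success`` (dGTP favored).
    """
    rng = _rng(cfg.seed if seed is None else seed)
    seq = prepared.fragment.template_seq
    j = len(seq) - 1
    while j >= 0 and seq[j] == "A":
        j -= 1
    if j < 0:
        return None  # template entirely A: fill consumes everything
    required = complement(seq[j])
    if rng.random() >= cfg.lock_success[required]:
        return None
    leading_t = 0
    if rng.random() < cfg.p_incomplete_fill:
        leading_t = 1 + int(rng.geometric(0.5))  # >= 2, mean 3
    return LockedTemplate(prepared.fragment, j, required, leading_t)


# ---------------------------------------------------------------------------
# stage 5: sequencing
# ---------------------------------------------------------------------------


def _apply_errors(
    bases: str, cfg: PrepConfig, rng
) -> Tuple[str, int, int]:
    """Error-prone copy of an ideal read. Returns (seq, n_del, n_template)."""
    out = []
    n_del = 0
    n_template = 0
    for b in bases:
        if rng.random() < cfg.ins_rate:
            out.append(BASES[int(rng.integers(0, 4))])
        if rng.random() < cfg.del_rate:
            n_del += 1
            n_template += 1
            continue
        if rng.random() < cfg.sub_rate:
            others = BASES.replace(b, "")
            out.append(others[int(rng.integers(0, 3))])
        else:
            out.append(b)
        n_template += 1
    return "".join(out), n_del, n_template


def _draw_read_cap(cfg: PrepConfig, rng) -> int:
    cap = int(round(rng.normal(cfg.read_len_mean, cfg.read_len_mean * 0.3)))
    return int(np.clip(cap, 5, cfg.read_len_cap))


def _ideal_read(locked: LockedTemplate) -> str:
    """Error-free read: revcomp of the template 5' of the lock site."""
    seq = locked.fragment.template_seq
    return "T" * locked.leading_t + revcomp(seq[: locked.lock_index])


def _truth_context(locked: LockedTemplate) -> Tuple[str, str]:
    seq = locked.fragment.template_seq
    minus1 = complement(seq[locked.lock_index])
    if locked.a_run > 0:
        minus2 = complement(seq[locked.lock_index + 1])  # always T
    else:
        lost = locked.fragment.lost_base_3prime
        minus2 = complement(lost) if lost in BASES else "N"
    return minus1, minus2


def _artifact_read(cfg: PrepConfig, rng) -> str:
    """A read tracking the flow order cyclically (image-registration artifact)."""
    length = int(rng.integers(25, 61))
    fo = cfg.flow_order
    out = []
    ptr = int(rng.integers(0, len(fo)))
    while len(out) < length:
        if rng.random() < 0.9:
            out.append(fo[ptr % len(fo)])
        ptr += 1
    return "".join(out)


def _spike_read(
    oligos: SpikeOligoSet, cfg: PrepConfig, rng
) -> Tuple[str, str, str]:
    """Sequence a poly-A-tailed spike oligo; occasional spike-spike chimeras."""
    ids = list(oligos.oligos)
    oid = ids[int(rng.integers(0, len(ids)))]
    seq = oligos.oligos[oid]
    j = len(seq) - 1
    while j >= 0 and seq[j] == "A":
        j -= 1
    ideal = revcomp(seq[:j]) if j > 0 else revcomp(seq)
    origin = SPIKE
    if rng.random() < cfg.spike_chimera_rate:
        oid2 = ids[int(rng.integers(0, len(ids)))]
        other = revcomp(oligos.oligos[oid2])
        ideal = ideal[: max(1, len(ideal) // 2)] + other[len(other) // 2 :]
        origin = "spike_chimera"
        oid = f"{oid}+{oid2}"
    noisy, _, _ = _apply_errors(ideal, cfg, rng)
    return noisy[: _draw_read_cap(cfg, rng)], origin, oid


def sequence_reads(
    locked: Sequence[Tuple[str, LockedTemplate]],
    cfg: PrepConfig,
    seed=None,
    oligos: Optional[SpikeOligoSet] = None,
) -> List[ReadRecord]:
    """Synthesize reads from locked templates plus artifact and spike reads.

    ``locked`` pairs a source id with each template so truth labels survive.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    reads: List[ReadRecord] = []
    idx = 0
    for source_id, lt in locked:
        ideal = _ideal_read(lt)
        noisy, n_del, n_tmpl = _apply_errors(ideal, cfg, rng)
        noisy = noisy[: _draw_read_cap(cfg, rng)]
        if not noisy:
            continue
        minus1, minus2 = _truth_context(lt)
        reads.append(
            ReadRecord(
                read_id=f"read_{idx:07d}",
                seq=noisy,
                origin=lt.fragment.origin,
                source_id=source_id,
                leading_t=lt.leading_t,
                minus1_truth=minus1,
                minus2_truth=minus2,
                n_del=n_del,
                n_template=n_tmpl,
            )
        )
        idx += 1
    n_real = len(reads)
    n_art = rng.binomial(n_real, cfg.artifact_read_rate) if n_real else 0
    for _ in range(n_art):
        reads.append(
            ReadRecord(f"read_{idx:07d}", _artifact_read(cfg, rng), ARTIFACT, "-")
        )
        idx += 1
    if cfg.spike_fraction > 0 and oligos is not None and n_real:
        slots = int(round(n_real / (1.0 - cfg.spike_fraction)))
        n_spike = int(rng.binomial(slots, cfg.spike_fraction))
        for _ in range(n_spike):
            seq, origin, oid = _spike_read(oligos, cfg, rng)
            if seq:
                reads.append(ReadRecord(f"read_{idx:07d}", seq, origin, oid))
                idx += 1
    return reads


# ---------------------------------------------------------------------------
# channel pipeline
# ---------------------------------------------------------------------------


def run_prep(
    fragments: Sequence[Fragment],
    cfg: PrepConfig,
    seed=None,
    oligos: Optional[SpikeOligoSet] = None,
) -> Tuple[List[ReadRecord], Dict[str, int]]:
    """Run denature -> (phosphatase) -> tail/capture -> lock -> sequence.

    Returns reads plus per-stage counts (pipeline conservation:
    reads <= locked <= captured <= tailed <= denatured <= fragments).
    """
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    counts = {"fragments": len(fragments)}
    pool = denature(fragments, cfg, rng)
    counts["denatured"] = len(pool)
    if cfg.phosphatase:
        pool = phosphatase_treat(pool)
    captured = polya_tail_and_capture(pool, cfg, rng)
    counts["captured"] = len(captured)
    locked = []
    for i, pt in enumerate(captured):
        lt = fill_and_lock(pt, cfg, rng)
        if lt is not None:
            locked.append((f"frag_{i}", lt))
    counts["locked"] = len(locked)
    reads = sequence_reads(locked, cfg, rng, oligos=oligos)
    counts["reads"] = len(reads)
    return reads, counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    """FASTQ with constant placeholder quality (the platform reports none)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def write_truth_tsv(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\tsource_id\tleading_t\tminus1\tminus2\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.origin}\t{r.source_id}\t{r.leading_t}\t"
                f"{r.minus1_truth}\t{r.minus2_truth}\n"
            )


def write_stage_counts(counts: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
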