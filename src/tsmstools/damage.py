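"""Positional damage and composition statistics from alignments.

Post-mortem cytosine deamination shows up in this read chemistry as a G->A
excess at the first positions sequenced (reads are the complement of the
template walked from its 3' end, where single-stranded deamination is
highest).  Depurination leaves a purine excess on the template strand just
past the template's 3' terminus, visible as a pyrimidine (C) excess at
genomic position -2 in read-strand orientation.  The lock chemistry's dGTP
preference enriches G at the locking site (position -1).

All statistics here are computed from alignments and the reference — never
from simulator truth labels — so externally produced SAM works identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import BASES, complement, gc_fraction
from .mapping import DEL, INS, MATCH, MISMATCH, AlignmentRecord
from .simulate import ReferenceSet

MISMATCH_KEYS = [f"{a}>{b}" for a in BASES for b in BASES if a != b]


@dataclass
class MisincorporationTable:
    """Counts and opportunities for the 12 mismatches plus indels, by read
    position (1-based from the chosen read end, 5' by default)."""

    counts: pd.DataFrame          # index pos, columns MISMATCH_KEYS + ins/del
    opportunities: pd.DataFrame   # index pos, columns A/C/G/T + total
    end: str = "5p"
    n_alignments: int = 0
    n_skipped: int = 0

    def frequency(self, key: str) -> pd.Series:
        if key in ("ins", "del"):
            denom = self.opportunities["total"]
        else:
            denom = self.opportunities[key[0]]
        return (self.counts[key] / denom.replace(0, np.nan)).fillna(0.0)


@dataclass
class CompositionProfile:
    """Base frequencies at read position +1 and genomic positions -1/-2
    (read-strand orientation), with genome background."""

    plus1: Dict[str, float]
    minus1: Dict[str, float]
    minus2: Dict[str, float]
    background: Dict[str, float]
    n: int = 0
    n_skipped: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.minus2, self.minus1, self.plus1, self.background],
            index=["-2", "-1", "+1", "background"],
        )[list(BASES)]


def _ref_base(refs: ReferenceSet, rid: str, pos: int) -> Optional[str]:
    seq = refs.sequences[rid]
    n = len(seq)
    if refs.is_circular(rid):
        return seq[pos % n]
    if 0 <= pos < n:
        return seq[pos]
    return None


def _aligned_events(
    aln: AlignmentRecord, read_seq: str, refs: ReferenceSet
) -> Optional[Tuple[List[Tuple[int, str, str]], List[int], List[int], int]]:
    """Per-base events in read 5' orientation.

    Returns (matches, ins_positions, del_positions, read_len) where matches
    are (read_pos_1based, ref_base, read_base) with bases complemented for
    minus-strand alignments so everything is in the read's own orientation.
    Returns None when the alignment overruns a linear reference.
    """
    seq = read_seq if aln.strand == "+" else None
    mapped = read_seq if aln.strand == "+" else _revcomp(read_seq)
    m = len(read_seq)
    qpos = 0
    rpos = aln.pos
    matches: List[Tuple[int, str, str]] = []
    ins_pos: List[int] = []
    del_pos: List[int] = []
    for op, n in aln.ops:
        if op in (MATCH, MISMATCH):
            for t in range(n):
                rb = _ref_base(refs, aln.ref_id, rpos + t)
                if rb is None:
                    return None
                read_b = mapped[qpos + t]
                if aln.strand == "+":
                    p = qpos + t + 1
                    matches.append((p, rb, read_b))
                else:
                    p = m - (qpos + t)
                    matches.append((p, complement(rb), complement(read_b)))
            qpos += n
            rpos += n
        elif op == INS:
            for t in range(n):
                p = qpos + t + 1 if aln.strand == "+" else m - (qpos + t)
                ins_pos.append(p)
            qpos += n
        elif op == DEL:
            # attribute to the flanking read position (5' side, read orientation)
            p = qpos if aln.strand == "+" else m - qpos
            p = max(1, min(m, p))
            del_pos.extend([p] * n)
            if _ref_base(refs, aln.ref_id, rpos + n - 1) is None:
                return None
            rpos += n
    return matches, ins_pos, del_pos, m


def _revcomp(s: str) -> str:
    return complement(s)[::-1]


def misincorporation_table(
    alignments: Iterable[AlignmentRecord],
    refs: ReferenceSet,
    reads: Mapping[str, str],
    n: int = 25,
    end: str = "5p",
) -> MisincorporationTable:
    """Tally mismatch/indel events by read position from the chosen end."""
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    positions = range(1, n + 1)
    counts = {k: np.zeros(n) for k in MISMATCH_KEYS + ["ins", "del"]}
    opps = {b: np.zeros(n) for b in BASES}
    n_aln = 0
    n_skip = 0
    for aln in alignments:
        ev = _aligned_events(aln, reads[aln.read_id], refs)
        if ev is None:
            n_skip += 1
            continue
        matches, ins_pos, del_pos, m = ev
        n_aln += 1

        def to_end(p: int) -> int:
            return p if end == "5p" else m - p + 1

        for p, rb, qb in matches:
            pe = to_end(p)
            if 1 <= pe <= n:
                opps[rb][pe - 1] += 1
                if rb != qb:
                    counts[f"{rb}>{qb}"][pe - 1] += 1
        for p in ins_pos:
            pe = to_end(p)
            if 1 <= pe <= n:
                counts["ins"][pe - 1] += 1
        for p in del_pos:
            pe = to_end(p)
            if 1 <= pe <= n:
                counts["del"][pe - 1] += 1
    cdf = pd.DataFrame(counts, index=list(positions))
    odf = pd.DataFrame(opps, index=list(positions))
    odf["total"] = odf[list(BASES)].sum(axis=1)
    return MisincorporationTable(cdf, odf, end=end, n_alignments=n_aln, n_skipped=n_skip)


def cumulative_ga(table: MisincorporationTable, k: int) -> float:
    """Running sum of per-position G->A frequencies over positions 1..k."""
    if k < 1 or k > len(table.counts):
        raise ValueError("k outside the table range")
    return float(table.frequency("G>A").iloc[:k].sum())


def cumulative_ga_curve(table: MisincorporationTable) -> pd.Series:
    return table.frequency("G>A").cumsum()


def composition_context(
    alignments: Iterable[AlignmentRecord],
    refs: ReferenceSet,
    reads: Mapping[str, str],
) -> CompositionProfile:
    """Base composition at read position +1 and genomic -1/-2 (read strand).

    For a plus-strand alignment the upstream bases are ref[pos-1], ref[pos-2]
    as-is; for a minus-strand alignment they are the complements of the two
    reference bases just past the alignment's right end.
    """
    tallies = {k: {b: 0 for b in BASES} for k in ("+1", "-1", "-2")}
    n_used = 0
    n_skip = 0
    for aln in alignments:
        seq = reads[aln.read_id]
        if aln.strand == "+":
            b1 = _ref_base(refs, aln.ref_id, aln.pos - 1)
            b2 = _ref_base(refs, aln.ref_id, aln.pos - 2)
        else:
            right = aln.pos + aln.ref_span
            b1 = _ref_base(refs, aln.ref_id, right)
            b2 = _ref_base(refs, aln.ref_id, right + 1)
            b1 = complement(b1) if b1 else None
            b2 = complement(b2) if b2 else None
        if b1 is None or b2 is None:
            n_skip += 1
            continue
        first = _first_aligned_base(aln, seq)
        if first is None:
            n_skip += 1
            continue
        tallies["-1"][b1] += 1
        tallies["-2"][b2] += 1
        tallies["+1"][first] += 1
        n_used += 1
    background = _background(refs)

    def norm(d):
        tot = sum(d.values())
        return {b: (d[b] / tot if tot else 0.0) for b in BASES}

    return CompositionProfile(
        plus1=norm(tallies["+1"]),
        minus1=norm(tallies["-1"]),
        minus2=norm(tallies["-2"]),
        background=background,
        n=n_used,
        n_skipped=n_skip,
    )


def _first_aligned_base(aln: AlignmentRecord, read_seq: str) -> Optional[str]:
    """First M/X read base in read orientation."""
    mapped = read_seq if aln.strand == "+" else _revcomp(read_seq)
    qpos = 0
    first_mapped = None
    for op, n in aln.ops:
        if op in (MATCH, MISMATCH):
            first_mapped = qpos
            break
        if op == INS:
            qpos += n
    if first_mapped is None:
        return None
    if aln.strand == "+":
        return mapped[first_mapped]
    # in read orientation the first aligned base is the *last* M/X mapped base
    qpos = 0
    last = None
    for op, n in aln.ops:
        if op in (MATCH, MISMATCH):
            last = qpos + n - 1
        if op in (MATCH, MISMATCH, INS):
            qpos += n
    return complement(mapped[last])


def _background(refs: ReferenceSet) -> Dict[str, float]:
    tot = {b: 0 for b in BASES}
    for seq in refs.sequences.values():
        for b in BASES:
            tot[b] += seq.count(b)
    s = sum(tot.values())
    return {b: tot[b] / s if s else 0.0 for b in BASES}


# ---------------------------------------------------------------------------
# read-level summaries
# ---------------------------------------------------------------------------


def read_summaries(seqs: Iterable[str]) -> Dict[str, object]:
    """Length histogram (per-nt bins), per-read %GC, and means."""
    seqs = list(seqs)
    lengths = pd.Series([len(s) for s in seqs], dtype=int)
    gc = pd.Series([gc_fraction(s) for s in seqs], dtype=float)
    hist = lengths.value_counts().sort_index()
    return {
        "n": len(seqs),
        "length_hist": hist,
        "mean_length": float(lengths.mean()) if len(seqs) else 0.0,
        "gc": gc,
        "mean_gc": float(gc.mean()) if len(seqs) else 0.0,
    }
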