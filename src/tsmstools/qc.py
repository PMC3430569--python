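"""Read quality-control filters for single-molecule sequencing channels.

The filters mirror the standard post-run cleanup for this platform:

* reads starting with >= 2 T's have the whole leading T-run trimmed
  (incomplete fill-and-lock leaves dTTP fill bases at the read start);
* reads shorter than 25 nt after trimming are dropped;
* reads whose bases track the cyclic nucleotide-addition (flow) order too
  closely are image-registration artifacts and are dropped;
* reads matching a known spike oligo (either orientation, gapped) are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from ._seq import BASES, revcomp
from .simulate import SpikeOligoSet


@dataclass
class QCReport:
    """Per-filter accounting; surviving = input - short - artifact - spike."""

    input_reads: int = 0
    removed_short: int = 0
    trimmed_leading_t: int = 0
    removed_artifact: int = 0
    removed_spike: int = 0
    surviving: int = 0
    removed_per_oligo: Dict[str, int] = field(default_factory=dict)
    examples: Dict[str, List[str]] = field(default_factory=dict)

    def check(self) -> None:
        expect = (
            self.input_reads
            - self.removed_short
            - self.removed_artifact
            - self.removed_spike
        )
        if self.surviving != expect:
            raise AssertionError("QC counts are not conserved")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)


def trim_leading_t(seq: str) -> str:
    """Remove the entire leading T-run when a read starts with >= 2 T's."""
    if seq.startswith("TT"):
        return seq.lstrip("T")
    return seq


def filter_min_length(
    seqs: Sequence[str], min_len: int = 25
) -> Tuple[List[str], int]:
    kept = [s for s in seqs if len(s) >= min_len]
    return kept, len(seqs) - len(kept)


def flow_artifact_score(seq: str, flow_order: str = "CTAG") -> float:
    """Flows consumed per base, minimized over the starting flow phase.

    The instrument flashes nucleotides cyclically in ``flow_order``; a read is
    emitted as a subsequence of the flow stream.  Emitting a base costs the
    number of flows stepped to reach it (a repeated base costs a full cycle).
    Genuine reads consume ~(L+1)/2 flows per base for a cycle of length L
    (2.5 for the default CTAG order); artifact reads tracking the flow order
    score near 1.0.
    """
    if not flow_order:
        raise ValueError("flow_order must be non-empty")
    if not seq:
        return float("inf")
    alphabet = set(flow_order)
    if set(seq) - alphabet:
        raise ValueError("read contains a base absent from the flow order")
    L = len(flow_order)
    # steps[p][b]: flows consumed emitting base b with the pointer at phase p
    steps = {}
    for p in range(L):
        for b in alphabet:
            k = next(i for i in range(L) if flow_order[(p + i) % L] == b)
            steps[(p, b)] = k + 1
    best = None
    for p0 in range(L):
        p, total = p0, 0
        for b in seq:
            c = steps[(p, b)]
            total += c
            p = (p + c) % L
        score = total / len(seq)
        best = score if best is None else min(best, score)
    return best


def filter_flow_artifacts(
    seqs: Sequence[str], flow_order: str = "CTAG", threshold: float = 1.25
) -> Tuple[List[str], int]:
    """Drop reads whose flow score is <= threshold (too flow-like)."""
    kept, removed = [], 0
    for s in seqs:
        try:
            score = flow_artifact_score(s, flow_order)
        except ValueError:
            score = float("inf")  # bases outside the flow alphabet: not flow-like
        if score <= threshold:
            removed += 1
        else:
            kept.append(s)
    return kept, removed


def spike_identity(seq: str, oligo: str) -> float:
    """Best read-length-normalized identity vs an oligo, either orientation.

    Uses infix (read fully aligned, gapped) alignment, so partial oligo
    copies with tails or chimera halves still score on the matching span.
    """
    best = 0.0
    for target in (oligo, revcomp(oligo)):
        res = edlib.align(seq, target, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(seq))
    return best


def is_spike(
    seq: str,
    oligos: SpikeOligoSet,
    min_identity: float = 0.8,
    min_read_cov: float = 0.8,
) -> Optional[str]:
    """Return the matching oligo id, or None.

    A single normalized-identity threshold of ``min_identity * min_read_cov``
    is equivalent to demanding >= min_identity over >= min_read_cov of the
    read in the worst case, because unmatched read bases count as errors in
    the infix alignment.
    """
    threshold = min_identity * min_read_cov
    for oid, oseq in oligos.oligos.items():
        if spike_identity(seq, oseq) >= threshold:
            return oid
    return None


def filter_spikes(
    seqs: Sequence[str],
    oligos: SpikeOligoSet,
    min_identity: float = 0.8,
    min_read_cov: float = 0.8,
) -> Tuple[List[str], int, Dict[str, int]]:
    if not len(oligos):
        raise ValueError("spike oligo set is empty")
    kept, removed, per_oligo = [], 0, {}
    for s in seqs:
        hit = is_spike(s, oligos, min_identity, min_read_cov)
        if hit is None:
            kept.append(s)
        else:
            removed += 1
            per_oligo[hit] = per_oligo.get(hit, 0) + 1
    return kept, removed, per_oligo


def run_qc(
    reads: Dict[str, str],
    oligos: Optional[SpikeOligoSet] = None,
    flow_order: str = "CTAG",
    min_len: int = 25,
    artifact_threshold: float = 1.25,
    min_identity: float = 0.8,
    min_read_cov: float = 0.8,
) -> Tuple[Dict[str, str], QCReport]:
    """Apply trim -> length -> artifact -> spike filters to id->seq reads."""
    report = QCReport(input_reads=len(reads))
    trimmed: Dict[str, str] = {}
    for rid, seq in reads.items():
        t = trim_leading_t(seq)
        if t != seq:
            report.trimmed_leading_t += 1
        trimmed[rid] = t
    stage = {rid: s for rid, s in trimmed.items() if len(s) >= min_len}
    report.removed_short = len(trimmed) - len(stage)
    kept: Dict[str, str] = {}
    for rid, s in stage.items():
        try:
            score = flow_artifact_score(s, flow_order)
        except ValueError:
            score = float("inf")
        if score <= artifact_threshold:
            report.removed_artifact += 1
            report.examples.setdefault("artifact", []).append(rid)
        else:
            kept[rid] = s
    if oligos is not None and len(oligos):
        final: Dict[str, str] = {}
        for rid, s in kept.items():
            hit = is_spike(s, oligos, min_identity, min_read_cov)
            if hit is None:
                final[rid] = s
            else:
                report.removed_spike += 1
                report.removed_per_oligo[hit] = report.removed_per_oligo.get(hit, 0) + 1
    else:
        final = kept
    report.surviving = len(final)
    report.check()
    return final, report
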