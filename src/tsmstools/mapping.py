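"""Self-contained gapped read mapping tuned for damaged, indel-rich reads.

Short ancient-DNA reads carry terminal damage and the platform's error mode
is indel-heavy, so the aligner is *glocal*: global in the read (every read
base is aligned, gaps permitted at the read termini at the same linear
penalty as internal gaps) and local in the reference.  Scoring is match +1,
mismatch -2, gap -2 per base.  Candidate loci come from a k-mer index
(k = 12 by default); short reads or small references fall back to exhaustive
scan.  The mapping-quality proxy is 2x the margin between the best and
second-best placement, capped at 60, and a read is "unique" only when the
best placement strictly beats every other one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import encode, revcomp
from .simulate import ReferenceSet

MATCH, MISMATCH, INS, DEL = "MATCH", "MISMATCH", "INS", "DEL"
_READ_CONSUMING = {MATCH, MISMATCH, INS}
_REF_CONSUMING = {MATCH, MISMATCH, DEL}


@dataclass
class MappingParams:
    k: int = 12
    match: int = 1
    mismatch: int = -2
    gap: int = -2
    pad: int = 14                # window slack around the seeded diagonal
    max_candidates: int = 6      # DP evaluations per read
    exhaustive_max: int = 600    # refs at most this long are scanned wholesale
    mapq_min: int = 25
    decoy_score_frac: float = 0.9


@dataclass
class AlignmentRecord:
    read_id: str
    ref_id: str
    pos: int                     # 0-based leftmost reference position
    strand: str
    ops: List[Tuple[str, int]]
    score: float
    mapq: int
    unique: bool

    @property
    def read_span(self) -> int:
        return sum(n for op, n in self.ops if op in _READ_CONSUMING)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in _REF_CONSUMING)


class ReferenceIndex:
    """k-mer index over a reference set; circular refs are end-padded."""

    def __init__(
        self,
        refs: ReferenceSet | Mapping[str, str],
        params: Optional[MappingParams] = None,
        circular_pad: int = 80,
    ):
        if not isinstance(refs, ReferenceSet):
            refs = ReferenceSet(dict(refs))
        self.refs = refs
        self.params = params or MappingParams()
        self.circular_pad = circular_pad
        self._seqs: Dict[str, str] = {}
        self._codes: Dict[str, np.ndarray] = {}
        self._true_len: Dict[str, int] = {}
        self._kmers: Dict[str, tuple] = {}
        k = self.params.k
        self._powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for rid, seq in refs.sequences.items():
            padded = seq + seq[:circular_pad] if refs.is_circular(rid) else seq
            self._seqs[rid] = padded
            self._codes[rid] = encode(padded)
            self._true_len[rid] = len(seq)
            self._kmers[rid] = self._build(self._codes[rid])

    def _build(self, codes: np.ndarray):
        k = self.params.k
        if len(codes) < k:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        hashes = windows.astype(np.int64) @ self._powers
        order = np.argsort(hashes, kind="stable")
        sorted_h = hashes[order]
        uniq, starts = np.unique(sorted_h, return_index=True)
        return uniq, starts, order, len(hashes)

    def lookup(self, rid: str, kmer_hash: int) -> np.ndarray:
        entry = self._kmers[rid]
        if entry is None:
            return np.empty(0, dtype=np.int64)
        uniq, starts, order, n = entry
        i = np.searchsorted(uniq, kmer_hash)
        if i == len(uniq) or uniq[i] != kmer_hash:
            return np.empty(0, dtype=np.int64)
        end = starts[i + 1] if i + 1 < len(starts) else n
        return order[starts[i] : end]

    def hash_query(self, codes: np.ndarray) -> np.ndarray:
        k = self.params.k
        if len(codes) < k:
            return np.empty(0, dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        return windows.astype(np.int64) @ self._powers

    def true_len(self, rid: str) -> int:
        return self._true_len[rid]


# ---------------------------------------------------------------------------
# glocal dynamic programming
# ---------------------------------------------------------------------------


def _glocal_score(
    q: np.ndarray, r: np.ndarray, p: MappingParams
) -> Tuple[float, List[int]]:
    """Best glocal score of query q within reference window r; returns
    (score, optimal end columns).  Multiple end columns signal tied
    placements; the highest column keeps terminal mismatches as mismatches
    rather than trading them for read gaps."""
    m, w = len(q), len(r)
    jidx = np.arange(w + 1)
    prev = np.zeros(w + 1)
    for i in range(1, m + 1):
        sub = np.where(r == q[i - 1], p.match, p.mismatch)
        diag = prev[:-1] + sub
        up = prev + p.gap  # query base as INS (read-consuming gap)
        cand = np.empty(w + 1)
        cand[0] = up[0]
        cand[1:] = np.maximum(diag, up[1:])
        # horizontal (DEL) chains: H[j] = max_{j'<=j} cand[j'] + gap*(j - j')
        run = np.maximum.accumulate(cand - p.gap * jidx)
        prev = run + p.gap * jidx
    best = float(prev.max())
    ends = np.nonzero(prev == best)[0]
    return best, [int(j) for j in ends]


def _glocal_traceback(
    q: np.ndarray, r: np.ndarray, p: MappingParams
) -> Tuple[float, int, List[Tuple[str, int]]]:
    """Full DP with traceback: (score, ref_start, run-length ops)."""
    m, w = len(q), len(r)
    H = np.empty((m + 1, w + 1))
    H[0] = 0.0
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + p.gap
        sub = np.where(r == q[i - 1], p.match, p.mismatch)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + p.gap
        cand = np.maximum(diag, up)
        row = H[i]
        row[1:] = cand
        np.maximum.accumulate(row - p.gap * np.arange(w + 1), out=row)
        row += p.gap * np.arange(w + 1)
        # note: accumulate trick applied in place reproduces the row loop
        H[i] = row
    # highest optimal end column: a trailing mismatch stays a mismatch
    # instead of degrading into a read gap ending one column earlier
    j = int(len(H[m]) - 1 - np.argmax(H[m][::-1]))
    score = float(H[m, j])
    ops: List[Tuple[str, int]] = []
    i = m
    while i > 0:
        if j > 0 and H[i, j] == H[i - 1, j - 1] + (
            p.match if r[j - 1] == q[i - 1] else p.mismatch
        ):
            op = MATCH if r[j - 1] == q[i - 1] else MISMATCH
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + p.gap:
            op = INS
            i -= 1
        else:
            op = DEL
            j -= 1
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    ops.reverse()
    # strip leading/trailing DEL: reference-local, they are not part of the placement
    while ops and ops[0][0] == DEL:
        j += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] == DEL:
        ops.pop()
    return score, j, ops


# ---------------------------------------------------------------------------
# read mapping
# ---------------------------------------------------------------------------


def _candidate_windows(
    index: ReferenceIndex, seq: str, params: MappingParams
) -> List[Tuple[str, str, int, int]]:
    """(ref_id, strand, window_start, n_seeds) candidates, most-seeded first."""
    out: Dict[Tuple[str, str, int], int] = {}
    m = len(seq)
    for rid in index.refs.sequences:
        ref_len = len(index._seqs[rid])
        if ref_len <= params.exhaustive_max or m < params.k:
            for strand in "+-":
                out[(rid, strand, 0)] = out.get((rid, strand, 0), 0) + 1
            continue
        for strand in "+-":
            query = seq if strand == "+" else revcomp(seq)
            qh = index.hash_query(encode(query))
            diags: Dict[int, int] = {}
            for qpos in range(len(qh)):
                hits = index.lookup(rid, int(qh[qpos]))
                if len(hits) > 40:  # repetitive seed, skip
                    continue
                for rpos in hits:
                    d = (int(rpos) - qpos) // params.pad  # coarse diagonal bin
                    diags[d] = diags.get(d, 0) + 1
            for d, cnt in diags.items():
                start = max(0, d * params.pad - params.pad)
                key = (rid, strand, start)
                out[key] = max(out.get(key, 0), cnt)
    cands = sorted(out.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(rid, strand, start, cnt) for (rid, strand, start), cnt in cands]


def map_read(
    read_id: str,
    seq: str,
    index: ReferenceIndex,
    params: Optional[MappingParams] = None,
) -> Optional[AlignmentRecord]:
    """Best glocal placement of a read over both strands of all references."""
    params = params or index.params
    if not seq:
        return None
    cands = _candidate_windows(index, seq, params)
    if not cands:
        return None
    m = len(seq)
    placements = []  # (score, ref, strand, normalized end, window_start, window)
    seen = set()
    for rid, strand, start, _cnt in cands[: params.max_candidates]:
        codes = index._codes[rid]
        ref_len = len(codes)
        if ref_len <= params.exhaustive_max:
            window = codes
            wstart = 0
        else:
            wstart = start
            window = codes[wstart : wstart + m + 3 * params.pad]
        if len(window) == 0:
            continue
        query = encode(seq if strand == "+" else revcomp(seq))
        score, ends = _glocal_score(query, window, params)
        true_len = index.true_len(rid)
        for endj in ends:
            # normalize so a placement and its circular-pad copy collapse
            end_norm = (wstart + endj) % true_len
            key = (rid, strand, end_norm)
            if key in seen:
                continue
            seen.add(key)
            placements.append((score, rid, strand, end_norm, wstart, window, query))
    if not placements:
        return None
    placements.sort(key=lambda t: (-t[0], t[1], -t[3], t[2] != "+"))
    best = placements[0]
    second = placements[1][0] if len(placements) > 1 else 0.0
    unique = len(placements) == 1 or best[0] > placements[1][0]
    mapq = int(min(60, max(0, 2 * (best[0] - max(second, 0.0)))))
    score, rid, strand, _endj, wstart, window, query = best
    tb_score, j, ops = _glocal_traceback(query, window, params)
    pos = wstart + j
    true_len = index.true_len(rid)
    if pos >= true_len:  # placement entirely in the circular pad: normalize
        pos -= true_len
    return AlignmentRecord(
        read_id=read_id,
        ref_id=rid,
        pos=pos,
        strand=strand,
        ops=ops,
        score=tb_score,
        mapq=mapq,
        unique=unique,
    )


def map_reads(
    reads: Mapping[str, str],
    index: ReferenceIndex,
    params: Optional[MappingParams] = None,
) -> Dict[str, AlignmentRecord]:
    out = {}
    for rid, seq in reads.items():
        aln = map_read(rid, seq, index, params)
        if aln is not None:
            out[rid] = aln
    return out


def competitive_filter(
    target: Mapping[str, AlignmentRecord],
    decoy: Mapping[str, AlignmentRecord],
    mapq_min: int = 25,
    decoy_score_frac: float = 0.9,
) -> Dict[str, AlignmentRecord]:
    """Keep reads mapping uniquely to the target (MAPQ > threshold) with no
    competitive decoy hit (decoy score >= ``decoy_score_frac`` of target)."""
    kept = {}
    for rid, aln in target.items():
        if not aln.unique or aln.mapq <= mapq_min:
            continue
        d = decoy.get(rid)
        if d is not None and d.score >= decoy_score_frac * aln.score:
            continue
        kept[rid] = aln
    return kept


# ---------------------------------------------------------------------------
# SAM I/O (pysam)
# ---------------------------------------------------------------------------

_OP_TO_CIGAR = {MATCH: 7, MISMATCH: 8, INS: 1, DEL: 2}
_CIGAR_TO_OP = {7: MATCH, 8: MISMATCH, 0: MATCH, 1: INS, 2: DEL}


def write_sam(
    alignments: Iterable[AlignmentRecord],
    reads: Mapping[str, str],
    ref_lengths: Mapping[str, int],
    path,
) -> None:
    """SAM v1 with =/X CIGAR ops so records round-trip without the reference."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rid, "LN": int(n)} for rid, n in ref_lengths.items()],
    }
    tid = {rid: i for i, rid in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.read_id
            seq = reads[aln.read_id]
            seg.query_sequence = seq if aln.strand == "+" else revcomp(seq)
            seg.flag = 0 if aln.strand == "+" else 16
            seg.reference_id = tid[aln.ref_id]
            seg.reference_start = aln.pos
            seg.mapping_quality = aln.mapq
            seg.cigartuples = [(_OP_TO_CIGAR[op], n) for op, n in aln.ops]
            seg.set_tag("AS", int(aln.score))
            seg.set_tag("XU", 1 if aln.unique else 0)
            fh.write(seg)


def read_sam(path) -> Tuple[List[AlignmentRecord], Dict[str, str], int]:
    """Parse SAM into records; returns (alignments, seqs, n_skipped).

    Unmapped records and records with hard clips (or other unsupported ops)
    are skipped and counted.  Soft clips are converted to read-terminal INS
    so externally produced SAM remains usable by the profiling modules.
    """
    import pysam

    alns: List[AlignmentRecord] = []
    seqs: Dict[str, str] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                skipped += 1
                continue
            ops: List[Tuple[str, int]] = []
            ok = True
            for code, n in seg.cigartuples:
                if code in _CIGAR_TO_OP:
                    op = _CIGAR_TO_OP[code]
                elif code == 4:  # soft clip: read-consuming, no reference
                    op = INS
                else:  # hard clip / pad / skip: unsupported
                    ok = False
                    break
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + n)
                else:
                    ops.append((op, n))
            if not ok:
                skipped += 1
                continue
            strand = "-" if seg.is_reverse else "+"
            mapped_seq = seg.query_sequence or ""
            seqs[seg.query_name] = (
                mapped_seq if strand == "+" else revcomp(mapped_seq)
            )
            score = seg.get_tag("AS") if seg.has_tag("AS") else 0
            unique = bool(seg.get_tag("XU")) if seg.has_tag("XU") else True
            alns.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    pos=seg.reference_start,
                    strand=strand,
                    ops=ops,
                    score=float(score),
                    mapq=seg.mapping_quality,
                    unique=unique,
                )
            )
    return alns, seqs, skipped
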