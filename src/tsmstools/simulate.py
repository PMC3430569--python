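"""Synthetic references, spike oligos, and damaged single-stranded templates.

Ancient DNA survives as short single-stranded fragments whose ends carry the
chemical scars of post-mortem decay.  Two processes dominate:

* **Depurination** — loss of a purine base creates an abasic site; subsequent
  beta-elimination cleaves the backbone, so fragment 3' termini sit
  immediately 5' of a (lost) purine and frequently carry a 3'-phosphate or
  another tailing-incompatible modification instead of a 3'-OH.
* **Cytosine deamination** — C -> U (read as T) conversions accumulate
  preferentially near the single-stranded fragment ends, producing the
  familiar terminal C->T / G->A misincorporation excess.

This module draws fragments from synthetic references under an explicit
per-bond breakage model: each internucleotide bond breaks with probability
``q`` (plain nick) and, when the base on the 3' side of the bond is a purine,
an additional depurination channel multiplies the total rate to
``q * depurination_odds``.  Exogenous (microbial / contaminant) fragments are
drawn longer and undamaged, mimicking the modern environmental background that
dominates ancient extracts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from ._seq import (
    BASES,
    circular_slice,
    complement,
    decode,
    encode,
    gc_fraction,
    is_purine_code,
    revcomp,
)

# 3'-end chemistry states
OH = "OH"
PHOSPHATE = "PHOSPHATE"
BLOCKED = "BLOCKED"
END3_STATES = (OH, PHOSPHATE, BLOCKED)

ENDO_ORIGINS = ("endo_nuclear", "endo_mito")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ReferenceSet:
    """Named reference sequences; ``circular`` flags wrap-around references."""

    sequences: Dict[str, str]
    circular: frozenset = frozenset()

    def __post_init__(self):
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("reference ids must be unique")
        self._encoded: Dict[str, np.ndarray] = {}

    def encoded(self, ref_id: str) -> np.ndarray:
        if ref_id not in self._encoded:
            self._encoded[ref_id] = encode(self.sequences[ref_id])
        return self._encoded[ref_id]

    def is_circular(self, ref_id: str) -> bool:
        return ref_id in self.circular

    def gc(self, ref_id: str) -> float:
        return gc_fraction(self.sequences[ref_id])

    @property
    def microbial_ids(self) -> List[str]:
        return sorted(r for r in self.sequences if r.startswith("microbial"))

    def ids_for_origin(self, origin: str) -> List[str]:
        if origin == "microbial":
            return self.microbial_ids
        if origin in self.sequences:
            return [origin]
        raise KeyError(origin)

    def slice(self, ref_id: str, start: int, end: int) -> str:
        seq = self.sequences[ref_id]
        if self.is_circular(ref_id):
            return circular_slice(seq, start, end)
        return seq[start:end]

    def write_fasta(self, path) -> None:
        write_fasta(self.sequences, path)


@dataclass
class SpikeOligoSet:
    """Known oligonucleotides spiked into a channel for image registration."""

    oligos: Dict[str, str]

    def __post_init__(self):
        if len(set(self.oligos.values())) != len(self.oligos):
            raise ValueError("spike oligo sequences must be distinct")

    def __len__(self):
        return len(self.oligos)

    def write_fasta(self, path) -> None:
        write_fasta(self.oligos, path)


@dataclass
class FragmentConfig:
    """Parameters of the fragmentation / deamination / end-chemistry model.

    ``base_nick_rate`` is the per-bond cleavage probability q; bonds whose 3'
    base (the base that would be lost) is a purine break at q *
    ``depurination_odds``.  Mean endogenous fragment length is therefore
    emergent: ~ 1 / (q * E[weight]).  Exogenous fragments bypass the bond
    model and draw geometric lengths (modern DNA, longer and undamaged).
    """

    n_fragments: int = 10_000
    origin_mixture: Dict[str, float] = field(
        default_factory=lambda: {
            "endo_nuclear": 0.0100,
            "endo_mito": 0.0005,
            "decoy": 0.0100,
            "microbial": 0.9795,
        }
    )
    base_nick_rate: float = 0.0073          # q: per-bond cleavage probability
    depurination_odds: float = 4.0          # lambda_dep >= 1
    # deamination
    p_end5: float = 0.20
    p_end3: float = 0.45
    p_base: float = 0.01
    lambda_decay: float = 3.0               # exponential decay length, nt
    damage_origins: Sequence[str] = ENDO_ORIGINS
    # 3'-end chemistry given the type of the 3'-flank break
    dep_end_chem: Dict[str, float] = field(
        default_factory=lambda: {PHOSPHATE: 0.8, OH: 0.1, BLOCKED: 0.1}
    )
    nick_end_chem: Dict[str, float] = field(
        default_factory=lambda: {OH: 0.60, PHOSPHATE: 0.25, BLOCKED: 0.15}
    )
    exo_end_chem: Dict[str, float] = field(
        default_factory=lambda: {OH: 0.08, PHOSPHATE: 0.82, BLOCKED: 0.10}
    )
    exo_mean_length: float = 180.0
    exo_min_length: int = 30
    max_frag_length: int = 400
    seed: int = 0

    def validate(self) -> "FragmentConfig":
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        probs = list(self.origin_mixture.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("origin_mixture must be non-negative and sum to 1")
        if not 0.0 <= self.base_nick_rate <= 1.0:
            raise ValueError("base_nick_rate must be in [0,1]")
        if self.depurination_odds < 1.0:
            raise ValueError("depurination_odds must be >= 1")
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be > 0")
        for p in (self.p_end5, self.p_end3, self.p_base):
            if not 0.0 <= p <= 1.0:
                raise ValueError("deamination probabilities must be in [0,1]")
        for chem in (self.dep_end_chem, self.nick_end_chem, self.exo_end_chem):
            if abs(sum(chem.values()) - 1.0) > 1e-9:
                raise ValueError("end-chemistry distributions must sum to 1")
        return self


@dataclass
class Fragment:
    """A single-stranded template with truth labels for downstream tests.

    ``template_seq`` is the ancient-strand sequence 5'->3' *after* deamination
    (deaminated C stored as T, offsets listed in ``deam_sites``).
    ``lost_base_3prime`` is the template-strand base immediately 3' of the
    template's 3' terminus (the base lost at a depurination break).
    """

    origin: str
    ref_id: str
    start: int
    end: int
    strand: str
    template_seq: str
    deam_sites: List[int] = field(default_factory=list)
    end3_chem: str = OH
    lost_base_3prime: str = "N"

    def __len__(self):
        return len(self.template_seq)

    @property
    def length(self) -> int:
        return len(self.template_seq)

    @property
    def deam_fraction(self) -> float:
        return len(self.deam_sites) / max(1, len(self.template_seq))

    def genomic_template(self) -> str:
        """Template sequence with deaminated T's restored to C."""
        if not self.deam_sites:
            return self.template_seq
        chars = list(self.template_seq)
        for i in self.deam_sites:
            chars[i] = "C"
        return "".join(chars)


# ---------------------------------------------------------------------------
# references and oligos
# ---------------------------------------------------------------------------

DEFAULT_SIZES = {
    "endo_nuclear": 500_000,
    "endo_mito": 16_660,
    "decoy": 500_000,
    "microbial": 50_000,
}


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    if n <= 0:
        raise ValueError("sequence size must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("GC target must be in [0,1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def make_references(
    sizes: Optional[Mapping[str, int]] = None,
    gc_targets: float | Mapping[str, float] = 0.5,
    n_microbial: int = 3,
    seed: int = 0,
) -> ReferenceSet:
    """Draw i.i.d. reference sequences at the requested GC fractions.

    ``sizes`` maps {endo_nuclear, endo_mito, decoy, microbial} to lengths;
    the microbial entry is replicated into ``n_microbial`` pool members.
    The mitochondrial reference is flagged circular.
    """
    rng = _rng(seed)
    sz = dict(DEFAULT_SIZES)
    if sizes:
        sz.update(sizes)
    if isinstance(gc_targets, Mapping):
        gc = {k: gc_targets.get(k, 0.5) for k in sz}
    else:
        gc = {k: float(gc_targets) for k in sz}
    seqs: Dict[str, str] = {}
    for key in ("endo_nuclear", "endo_mito", "decoy"):
        if sz.get(key, 0):
            seqs[key] = random_sequence(sz[key], gc[key], rng)
    for i in range(n_microbial):
        if sz.get("microbial", 0):
            seqs[f"microbial_{i + 1}"] = random_sequence(sz["microbial"], gc["microbial"], rng)
    return ReferenceSet(seqs, circular=frozenset({"endo_mito"} & set(seqs)))


def make_spike_oligos(
    n: int = 30, length_range: tuple[int, int] = (25, 60), seed: int = 0
) -> SpikeOligoSet:
    """Generate ``n`` distinct random oligos (default 30, 25-60 nt)."""
    if n < 1:
        raise ValueError("need at least one oligo")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("invalid length_range")
    rng = _rng(seed)
    oligos: Dict[str, str] = {}
    seen = set()
    i = 0
    while len(oligos) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = decode(rng.integers(0, 4, size=length).astype(np.uint8))
        if seq in seen:
            continue
        seen.add(seq)
        i += 1
        oligos[f"spike_{i:02d}"] = seq
    return SpikeOligoSet(oligos)


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def _sample_chem(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    states = list(dist)
    probs = np.array([dist[s] for s in states])
    return states[rng.choice(len(states), p=probs / probs.sum())]


def _sample_break_end(
    codes: np.ndarray, circular: bool, lam: float, rng: np.random.Generator, strand: str
) -> int:
    """Rejection-sample the 3'-flank break position, weighted by the lost base.

    Returns the genomic index of the lost base.  On the plus strand the
    template-strand base equals the reference base; on the minus strand it is
    the complement, so the purine test flips to reference pyrimidines.
    """
    n = len(codes)
    while True:
        b = int(rng.integers(0, n))
        code = codes[b]
        purine = (code % 2 == 0) if strand == "+" else (code % 2 == 1)
        w = lam if purine else 1.0
        if rng.random() < w / lam:
            return b


def _scan_5prime(
    window_codes: np.ndarray, q: float, lam: float, strand: str, rng: np.random.Generator
) -> int:
    """Number of bases retained scanning 5'-ward before the next break.

    ``window_codes`` lists reference codes in scan order (first element is the
    base adjacent to the 3' break).  Breaking at scan step k means k bases are
    retained.  Returns a value in [0, len(window)]; len(window) means no break
    inside the window (length capped).
    """
    if len(window_codes) == 0 or q <= 0:
        return len(window_codes)
    purine = (window_codes % 2 == 0) if strand == "+" else (window_codes % 2 == 1)
    p = np.where(purine, min(1.0, q * lam), q)
    surv = np.cumprod(1.0 - p)
    cum = 1.0 - surv  # P(break within first k+1 scanned bases)
    u = rng.random()
    k = int(np.searchsorted(cum, u, side="left"))
    return k


def _window_codes(codes: np.ndarray, idxs: np.ndarray, circular: bool) -> np.ndarray:
    if circular:
        return codes.take(idxs, mode="wrap")
    valid = (idxs >= 0) & (idxs < len(codes))
    return codes[idxs[valid]]


def draw_fragments(
    refs: ReferenceSet, cfg: FragmentConfig, seed=None
) -> List[Fragment]:
    """Draw ``cfg.n_fragments`` single-stranded fragments from ``refs``.

    Endogenous fragments follow the per-bond breakage model (purine-weighted
    3' breaks, mechanistic end chemistry); decoy/microbial fragments draw
    geometric lengths with the exogenous end-chemistry distribution and no
    damage.  Deamination is applied afterwards via ``apply_deamination``.
    """
    cfg.validate()
    if not refs.sequences:
        raise ValueError("empty reference pool")
    rng = _rng(cfg.seed if seed is None else seed)
    origins = list(cfg.origin_mixture)
    probs = np.array([cfg.origin_mixture[o] for o in origins])
    choices = rng.choice(len(origins), size=cfg.n_fragments, p=probs)
    frags: List[Fragment] = []
    for c in choices:
        origin = origins[c]
        pool = refs.ids_for_origin(origin)
        ref_id = pool[int(rng.integers(0, len(pool)))] if len(pool) > 1 else pool[0]
        if origin in ENDO_ORIGINS:
            frag = _draw_endo_fragment(refs, ref_id, origin, cfg, rng)
        else:
            frag = _draw_exo_fragment(refs, ref_id, origin, cfg, rng)
        if frag is not None:
            frags.append(frag)
    return frags


def _draw_endo_fragment(
    refs: ReferenceSet, ref_id: str, origin: str, cfg: FragmentConfig, rng
) -> Optional[Fragment]:
    codes = refs.encoded(ref_id)
    circular = refs.is_circular(ref_id)
    n = len(codes)
    q, lam = cfg.base_nick_rate, cfg.depurination_odds
    for _ in range(20):  # retry degenerate (length-0) draws
        strand = "+" if rng.random() < 0.5 else "-"
        b = _sample_break_end(codes, circular, lam, rng, strand)
        max_len = min(cfg.max_frag_length, n - 1)
        if strand == "+":
            idxs = b - 1 - np.arange(max_len)
            window = _window_codes(codes, idxs, circular)
            k = _scan_5prime(window, q, lam, strand, rng)
            if k == 0:
                continue
            start, end = b - k, b
            if circular and start < 0:
                start += n
                end += n
            seq = refs.slice(ref_id, start % n if circular else start, end)
            lost = BASES[codes[b]]
        else:
            idxs = b + 1 + np.arange(max_len)
            window = _window_codes(codes, idxs, circular)
            k = _scan_5prime(window, q, lam, strand, rng)
            if k == 0:
                continue
            start, end = b + 1, b + 1 + k
            seq = revcomp(refs.slice(ref_id, start, end))
            lost = complement(BASES[codes[b]])
        # break type: purine breaks are depurination with odds (lam-1):1 vs nick
        purine_lost = lost in "AG"
        is_dep = purine_lost and rng.random() < (lam - 1.0) / lam
        chem = _sample_chem(cfg.dep_end_chem if is_dep else cfg.nick_end_chem, rng)
        return Fragment(
            origin=origin,
            ref_id=ref_id,
            start=start if not circular else start % n,
            end=end,
            strand=strand,
            template_seq=seq,
            end3_chem=chem,
            lost_base_3prime=lost,
        )
    return None


def _draw_exo_fragment(
    refs: ReferenceSet, ref_id: str, origin: str, cfg: FragmentConfig, rng
) -> Optional[Fragment]:
    codes = refs.encoded(ref_id)
    n = len(codes)
    mean, lo = cfg.exo_mean_length, cfg.exo_min_length
    length = lo + int(rng.geometric(1.0 / max(1.0, mean - lo)))
    length = min(length, cfg.max_frag_length, n - 2)
    start = int(rng.integers(1, n - length))
    end = start + length
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        seq = refs.sequences[ref_id][start:end]
        lost = refs.sequences[ref_id][end]
    else:
        seq = revcomp(refs.sequences[ref_id][start:end])
        lost = complement(refs.sequences[ref_id][start - 1])
    chem = _sample_chem(cfg.exo_end_chem, rng)
    return Fragment(
        origin=origin,
        ref_id=ref_id,
        start=start,
        end=end,
        strand=strand,
        template_seq=seq,
        end3_chem=chem,
        lost_base_3prime=lost,
    )


# ---------------------------------------------------------------------------
# deamination
# ---------------------------------------------------------------------------


def deamination_probability(
    d5: np.ndarray, d3: np.ndarray, cfg: FragmentConfig
) -> np.ndarray:
    """Per-C conversion probability at distances d5/d3 from the fragment ends."""
    p = (
        cfg.p_base
        + cfg.p_end5 * np.exp(-np.asarray(d5) / cfg.lambda_decay)
        + cfg.p_end3 * np.exp(-np.asarray(d3) / cfg.lambda_decay)
    )
    return np.minimum(1.0, p)


def apply_deamination(fragment: Fragment, cfg: FragmentConfig, seed=None) -> Fragment:
    """Convert template C -> T with end-elevated probabilities (new Fragment)."""
    if fragment.deam_sites:
        raise ValueError("fragment already deaminated")
    rng = _rng(cfg.seed if seed is None else seed)
    seq = fragment.template_seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    c_pos = np.nonzero(arr == ord("C"))[0]
    if len(c_pos) == 0:
        return fragment
    L = len(seq)
    p = deamination_probability(c_pos, L - 1 - c_pos, cfg)
    hit = c_pos[rng.random(len(c_pos)) < p]
    if len(hit) == 0:
        return fragment
    chars = bytearray(seq, "ascii")
    for i in hit:
        chars[i] = ord("T")
    return dataclasses.replace(
        fragment, template_seq=chars.decode("ascii"), deam_sites=[int(i) for i in hit]
    )


def deaminate_all(
    fragments: Iterable[Fragment], cfg: FragmentConfig, seed=None
) -> List[Fragment]:
    """Apply deamination to fragments of damaged origins (endogenous default)."""
    rng = _rng(cfg.seed if seed is None else seed)
    out = []
    for f in fragments:
        if f.origin in cfg.damage_origins:
            out.append(apply_deamination(f, cfg, rng))
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


FRAGMENT_TSV_HEADER = "origin\tref_id\tstart\tend\tstrand\tend3_chem\tlost_base_3prime\tdeam_sites"


def fragments_to_tsv(fragments: Sequence[Fragment], path) -> None:
    with open(path, "w") as fh:
        fh.write(FRAGMENT_TSV_HEADER + "\n")
        for f in fragments:
            sites = ",".join(map(str, f.deam_sites))
            fh.write(
                f"{f.origin}\t{f.ref_id}\t{f.start}\t{f.end}\t{f.strand}\t"
                f"{f.end3_chem}\t{f.lost_base_3prime}\t{sites}\n"
            )


def fragments_fasta(fragments: Sequence[Fragment], path) -> None:
    write_fasta(
        {f"frag_{i}|{f.origin}": f.template_seq for i, f in enumerate(fragments)}, path
    )
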