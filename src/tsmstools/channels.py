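"""Channel-level statistics for tSMS sequencing experiments.

Works on per-channel read/bp tallies (sample, condition, total reads, nuclear
and mitochondrial reads and base pairs).  A fixture of published channel
tallies from tSMS runs of two Pleistocene horse-bone extracts ships with the
package (``data/channel_counts.tsv``) so every derived summary — endogenous
ratios, spiking expectations, phosphatase fold changes, megabase totals, and
mitochondrial coverage — can be recomputed from raw counts.

The spiking expectation answers: *if a spiked channel behaved like the
unspiked ones, how many endogenous reads should it produce?*  The endogenous
ratio of each unspiked channel is combined into a weighted average ``Rmin``
(weights proportional to pooled volume over per-channel loaded volume), and
the expected read count range is the 5%/95% quantile of
Binomial(n_total_spiked, Rmin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .mapping import DEL, INS, MATCH, MISMATCH, AlignmentRecord
from .simulate import ReferenceSet

MITO_LENGTH = 16_660  # default circular mitochondrial reference length, bases


@dataclass
class ChannelCounts:
    """Read and base-pair tallies for one sequencing channel."""

    label: str
    total_reads: int
    nuc_reads: int = 0
    nuc_bp: int = 0
    mt_reads: int = 0
    mt_bp: int = 0

    def __post_init__(self):
        if self.nuc_reads + self.mt_reads > self.total_reads:
            raise ValueError("endogenous reads exceed total reads")

    @property
    def endo_reads(self) -> int:
        return self.nuc_reads + self.mt_reads

    @property
    def endo_bp(self) -> int:
        return self.nuc_bp + self.mt_bp


@dataclass
class SpikingExpectation:
    rmin: float
    weights: List[float]
    ratios: List[float]
    n: int
    q_low: int
    q_high: int


@dataclass
class ConsensusResult:
    calls: Dict[int, str] = field(default_factory=dict)
    n_sites_depth2: int = 0
    prop_identical_depth2: float = 0.0
    n_sites_depth3plus: int = 0
    prop_majority_depth3plus: float = 0.0
    n_sites_called: int = 0
    accuracy: Optional[float] = None


# ---------------------------------------------------------------------------
# fixture
# ---------------------------------------------------------------------------


def load_channel_counts(path=None) -> pd.DataFrame:
    """Load per-channel tallies (packaged fixture when no path is given)."""
    if path is None:
        src = resources.files("tsmstools").joinpath("data/channel_counts.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", na_values=".")
    else:
        df = pd.read_csv(path, sep="\t", na_values=".")
    return df


def row_counts(row) -> ChannelCounts:
    return ChannelCounts(
        label=f"{row['sample']}:{row['condition']}",
        total_reads=int(row["total_reads"]),
        nuc_reads=int(row["nuc_reads"]),
        nuc_bp=int(row["nuc_bp"]),
        mt_reads=int(row["mt_reads"]),
        mt_bp=int(row["mt_bp"]),
    )


# ---------------------------------------------------------------------------
# ratios and quantiles
# ---------------------------------------------------------------------------


def endogenous_ratio(counts: ChannelCounts) -> float:
    """Endogenous percentage 100*(nuclear + mito reads)/total, 2 decimals."""
    if counts.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return round(100.0 * counts.endo_reads / counts.total_reads, 2)


_EXACT_QUANTILE_MAX_N = 5_000


def binomial_quantile(q: float, n: int, p: float) -> int:
    """Smallest k with Binomial CDF(k; n, p) >= q.

    Small n uses exact integer arithmetic (floats are dyadic rationals, so
    the CDF comparison is an integer inequality, correct even at exact ties
    such as CDF(166; 333, 1/2) = 1/2); large n falls back to ``binom.ppf``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0,1)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if p == 0.0:
        return 0
    if p == 1.0:
        return n
    if n <= _EXACT_QUANTILE_MAX_N:
        pm, pd = float(p).as_integer_ratio()
        qm, qd = float(q).as_integer_ratio()
        threshold = qm * pd**n  # compare acc*qd >= q*pd^n with integers
        term = (pd - pm) ** n  # k = 0
        acc = term
        k = 0
        while acc * qd < threshold and k < n:
            term = term * (n - k) * pm // ((k + 1) * (pd - pm))
            acc += term
            k += 1
        return k
    return int(binom.ppf(q, n, p))


def spiking_expectation(
    channels: Sequence[Mapping[str, float]],
    n_spiked_total: int,
    q_low: float = 0.05,
    q_high: float = 0.95,
) -> SpikingExpectation:
    """Expected endogenous reads in a spiked channel under the Rmin model.

    Each unspiked channel supplies ``nuc_reads``, ``total_reads``,
    ``loaded_volume`` and ``pooled_volume``.  Ratios are nuclear reads over
    total reads; weights are pooled/loaded volume, normalized.
    """
    if not channels:
        raise ValueError("need at least one unspiked channel")
    ratios, weights = [], []
    for ch in channels:
        if ch["total_reads"] <= 0:
            raise ValueError("total_reads must be positive")
        if ch.get("loaded_volume", 0) <= 0 or ch.get("pooled_volume", 0) <= 0:
            raise ValueError("volumes must be positive")
        ratios.append(ch["nuc_reads"] / ch["total_reads"])
        weights.append(ch["pooled_volume"] / ch["loaded_volume"])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    rmin = float(np.dot(w, ratios))
    return SpikingExpectation(
        rmin=rmin,
        weights=w.tolist(),
        ratios=ratios,
        n=n_spiked_total,
        q_low=binomial_quantile(q_low, n_spiked_total, rmin),
        q_high=binomial_quantile(q_high, n_spiked_total, rmin),
    )


def spiking_expectation_from_table(
    df: pd.DataFrame, sample: str
) -> SpikingExpectation:
    """Rmin expectation for one sample of the channel-counts table."""
    sub = df[df["sample"] == sample]
    spiked = sub[sub["condition"] == "spiking"]
    if len(spiked) != 1:
        raise ValueError(f"sample {sample} has no unique spiked channel")
    n = int(spiked["total_reads"].iloc[0])
    channels = []
    for cond in ("95C", "80C"):
        row = sub[sub["condition"] == cond].iloc[0]
        channels.append(
            {
                "nuc_reads": int(row["nuc_reads"]),
                "total_reads": int(row["total_reads"]),
                "loaded_volume": float(row["loaded_volume_ul"]),
                "pooled_volume": float(row["pooled_volume_ul"]),
            }
        )
    return spiking_expectation(channels, n)


# ---------------------------------------------------------------------------
# phosphatase fold changes and totals
# ---------------------------------------------------------------------------


def fold_change_summary(
    df: pd.DataFrame,
    treatment: str = "80C_phosphatase",
    control: str = "80C",
    fov: Optional[int] = 110,
    failed_read_ratio: float = 2.0,
) -> pd.DataFrame:
    """Per-sample treatment/control ratios from the channel-counts table.

    Columns: total-read ratio, endogenous-bp ratio, endogenous-percentage
    decrease ratio (control/treatment), and a ``failed`` flag for pairs whose
    read enrichment fell below ``failed_read_ratio`` (a channel-quality
    failure; such pairs are excluded from enrichment min/max summaries).
    """
    rows = []
    sub = df if fov is None else df[df["fov"] == fov]
    for sample in sub["sample"].unique():
        s = sub[sub["sample"] == sample]
        t = s[s["condition"] == treatment]
        c = s[s["condition"] == control]
        if len(t) != 1 or len(c) != 1:
            continue
        tc, cc = row_counts(t.iloc[0]), row_counts(c.iloc[0])
        if cc.total_reads == 0 or cc.endo_bp == 0:
            continue
        read_ratio = tc.total_reads / cc.total_reads
        bp_ratio = tc.endo_bp / cc.endo_bp
        ratio_decrease = endogenous_ratio(cc) / endogenous_ratio(tc)
        rows.append(
            {
                "sample": sample,
                "read_ratio": read_ratio,
                "endo_bp_ratio": bp_ratio,
                "endo_ratio_decrease": ratio_decrease,
                "failed": read_ratio < failed_read_ratio,
            }
        )
    return pd.DataFrame(rows)


def enrichment_range(pairs: pd.DataFrame) -> Dict[str, float]:
    """1-decimal min/max display values across non-failed pairs."""
    ok = pairs[~pairs["failed"]]
    return {
        "read_ratio_min": round(float(ok["read_ratio"].min()), 1),
        "read_ratio_max": round(float(ok["read_ratio"].max()), 1),
        "endo_bp_ratio_max": round(float(ok["endo_bp_ratio"].max()), 1),
        "endo_ratio_decrease_min": round(float(pairs["endo_ratio_decrease"].min()), 1),
        "endo_ratio_decrease_max": round(float(pairs["endo_ratio_decrease"].max()), 1),
    }


def mb_and_coverage_summary(
    df: pd.DataFrame, ref_len: int = MITO_LENGTH
) -> Dict[str, float]:
    """Total endogenous Mb (1 decimal), mt bp sum, and mito fold coverage."""
    nuc = df["nuc_bp"].sum()
    mt = df["mt_bp"].sum()
    return {
        "total_mb": round((nuc + mt) / 1e6, 1),
        "mt_bp": int(mt),
        "mito_coverage": float(mt / ref_len),
    }


# ---------------------------------------------------------------------------
# consensus from a pileup
# ---------------------------------------------------------------------------


def pileup(
    alignments: Iterable[AlignmentRecord],
    reads: Mapping[str, str],
    ref_len: int,
    circular: bool = True,
) -> Dict[int, List[str]]:
    """Reference position -> read bases from M/X columns (indels ignored)."""
    from ._seq import revcomp as _rc

    columns: Dict[int, List[str]] = {}
    for aln in alignments:
        seq = reads[aln.read_id]
        mapped = seq if aln.strand == "+" else _rc(seq)
        qpos, rpos = 0, aln.pos
        for op, n in aln.ops:
            if op in (MATCH, MISMATCH):
                for t in range(n):
                    pos = (rpos + t) % ref_len if circular else rpos + t
                    if 0 <= pos < ref_len:
                        columns.setdefault(pos, []).append(mapped[qpos + t])
                qpos += n
                rpos += n
            elif op == INS:
                qpos += n
            elif op == DEL:
                rpos += n
    return columns


def consensus(
    columns: Mapping[int, Sequence[str]],
    min_depth: int = 2,
    min_agreement: float = 0.5,
    truth: Optional[str] = None,
) -> ConsensusResult:
    """Depth-threshold consensus over pileup columns, ignoring indels.

    Depth-2 sites are scored identical/discordant; depth >= 3 sites by
    strict-majority (> ``min_agreement``) agreement.  A consensus base is
    called where depth >= ``min_depth`` and the top base exceeds the
    agreement threshold.  When ``truth`` is given, called bases are compared
    to it and accuracy reported.
    """
    res = ConsensusResult()
    n2 = ident2 = 0
    n3 = maj3 = 0
    correct = total_called = 0
    for pos, bases in columns.items():
        d = len(bases)
        if d < 2:
            continue
        top, top_n = _top(bases)
        if d == 2:
            n2 += 1
            if bases[0] == bases[1]:
                ident2 += 1
        else:
            n3 += 1
            if top_n / d > min_agreement:
                maj3 += 1
        if d >= min_depth and top_n / d > min_agreement:
            res.calls[pos] = top
            total_called += 1
            if truth is not None and truth[pos % len(truth)] == top:
                correct += 1
    res.n_sites_depth2 = n2
    res.prop_identical_depth2 = ident2 / n2 if n2 else 0.0
    res.n_sites_depth3plus = n3
    res.prop_majority_depth3plus = maj3 / n3 if n3 else 0.0
    res.n_sites_called = total_called
    if truth is not None and total_called:
        res.accuracy = correct / total_called
    return res


def _top(bases: Sequence[str]) -> Tuple[str, int]:
    best, best_n = "", -1
    for b in sorted(set(bases)):  # sorted: deterministic tie-break
        c = list(bases).count(b)
        if c > best_n:
            best, best_n = b, c
    return best, best_n
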