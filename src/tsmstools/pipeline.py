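"""End-to-end scenarios: simulate -> prep -> QC -> map -> profile -> stats.

A scenario bundles a reference set, per-channel fragment and prep
configurations, and the QC/mapping parameters, mirroring the experimental
designs the analysis targets: temperature contrasts, oligo spiking,
phosphatase treatment, and the re-extraction ("molecular niche") contrast.
One global seed fans out to per-stage seeds through ``numpy``'s
``SeedSequence`` spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import channels as chan
from . import damage, mapping, prep, qc, simulate

DEFAULT_SIZES = {
    "endo_nuclear": 120_000,
    "endo_mito": 16_660,
    "decoy": 60_000,
    "microbial": 40_000,
}


@dataclass
class ChannelSpec:
    label: str
    fragment_cfg: simulate.FragmentConfig
    prep_cfg: prep.PrepConfig
    spiked: bool = False


@dataclass
class ScenarioConfig:
    name: str
    channels: List[ChannelSpec]
    sizes: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    n_microbial: int = 2
    gc: float = 0.5
    n_spike_oligos: int = 30
    min_len: int = 25
    flow_order: str = "CTAG"
    mapq_min: int = 25
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def builtin_scenario(name: str, n_fragments: int = 20_000, seed: int = 0) -> ScenarioConfig:
    """Built-in experimental designs.

    * ``TP-phosphatase``: 80 degC denaturation with and without phosphatase.
    * ``TP-temperature``: 80 vs 95 degC denaturation.
    * ``CA-spiking``: pooled 80+95 degC channel with spike oligos vs unspiked.
    * ``TP-redigest``: first extraction vs redigested residue (lower
      deamination, higher endogenous fraction).
    """
    fc = lambda **kw: simulate.FragmentConfig(n_fragments=n_fragments, **kw)
    pc = prep.PrepConfig
    if name == "TP-phosphatase":
        specs = [
            ChannelSpec("phosphatase", fc(), pc(temperature=80, phosphatase=True)),
            ChannelSpec("control", fc(), pc(temperature=80, phosphatase=False)),
        ]
    elif name == "TP-temperature":
        specs = [
            ChannelSpec("80C", fc(), pc(temperature=80)),
            ChannelSpec("95C", fc(), pc(temperature=95)),
        ]
    elif name == "CA-spiking":
        specs = [
            ChannelSpec(
                "spiked",
                fc(),
                pc(temperature=80, spike_fraction=0.85),
                spiked=True,
            ),
            ChannelSpec("80C", fc(), pc(temperature=80)),
            ChannelSpec("95C", fc(), pc(temperature=95)),
        ]
    elif name == "TP-redigest":
        # Endogenous fractions are set higher than the other scenarios so the
        # damage contrast between channels is measurable at default read depth.
        first = fc(
            origin_mixture={
                "endo_nuclear": 0.100,
                "endo_mito": 0.002,
                "decoy": 0.010,
                "microbial": 0.888,
            },
        )
        redigest = fc(
            p_end5=0.10,
            p_end3=0.22,
            origin_mixture={
                "endo_nuclear": 0.250,
                "endo_mito": 0.004,
                "decoy": 0.010,
                "microbial": 0.736,
            },
        )
        specs = [
            ChannelSpec("first_extraction", first, pc(temperature=80)),
            ChannelSpec("redigest", redigest, pc(temperature=80)),
        ]
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return ScenarioConfig(name=name, channels=specs, seed=seed)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def run_channel(
    spec: ChannelSpec,
    refs: simulate.ReferenceSet,
    oligos: simulate.SpikeOligoSet,
    target_index: mapping.ReferenceIndex,
    decoy_index: mapping.ReferenceIndex,
    scenario: ScenarioConfig,
    seed_seq: np.random.SeedSequence,
) -> Dict[str, object]:
    """Run one channel end to end; returns the in-memory result bundle."""
    s_frag, s_deam, s_prep = (np.random.default_rng(s) for s in seed_seq.spawn(3))
    frags = simulate.draw_fragments(refs, spec.fragment_cfg, s_frag)
    frags = simulate.deaminate_all(frags, spec.fragment_cfg, s_deam)
    reads, counts = prep.run_prep(
        frags, spec.prep_cfg, s_prep, oligos=oligos if spec.spiked else None
    )
    raw = {r.read_id: r.seq for r in reads}
    clean, report = qc.run_qc(
        raw,
        oligos=oligos if spec.spiked else None,
        flow_order=scenario.flow_order,
        min_len=scenario.min_len,
    )
    target_alns = mapping.map_reads(clean, target_index)
    decoy_alns = mapping.map_reads(
        {r: s for r, s in clean.items() if r in target_alns}, decoy_index
    )
    retained = mapping.competitive_filter(
        target_alns, decoy_alns, mapq_min=scenario.mapq_min
    )
    by_ref: Dict[str, int] = {}
    bp_by_ref: Dict[str, int] = {}
    for aln in retained.values():
        by_ref[aln.ref_id] = by_ref.get(aln.ref_id, 0) + 1
        bp_by_ref[aln.ref_id] = bp_by_ref.get(aln.ref_id, 0) + len(clean[aln.read_id])
    counts_obj = chan.ChannelCounts(
        label=spec.label,
        total_reads=len(clean),
        nuc_reads=by_ref.get("endo_nuclear", 0),
        nuc_bp=bp_by_ref.get("endo_nuclear", 0),
        mt_reads=by_ref.get("endo_mito", 0),
        mt_bp=bp_by_ref.get("endo_mito", 0),
    )
    return {
        "spec": spec,
        "fragments": frags,
        "reads": reads,
        "clean": clean,
        "qc_report": report,
        "stage_counts": counts,
        "alignments": retained,
        "channel_counts": counts_obj,
    }


def run_scenario(
    scenario: ScenarioConfig, outdir, seed: Optional[int] = None
) -> Dict[str, object]:
    """Run every channel of a scenario, writing all stage outputs to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.touch()
    seed = scenario.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    s_refs, s_oligos, *s_channels = root.spawn(2 + len(scenario.channels))
    refs = simulate.make_references(
        sizes=scenario.sizes,
        gc_targets=scenario.gc,
        n_microbial=scenario.n_microbial,
        seed=np.random.default_rng(s_refs),
    )
    oligos = simulate.make_spike_oligos(
        scenario.n_spike_oligos, seed=np.random.default_rng(s_oligos)
    )
    refs.write_fasta(outdir / "references.fasta")
    oligos.write_fasta(outdir / "spike_oligos.fasta")
    target = {
        k: refs.sequences[k] for k in ("endo_nuclear", "endo_mito") if k in refs.sequences
    }
    target_refs = simulate.ReferenceSet(target, circular=refs.circular & set(target))
    decoy_refs = simulate.ReferenceSet({"decoy": refs.sequences["decoy"]})
    target_index = mapping.ReferenceIndex(target_refs)
    decoy_index = mapping.ReferenceIndex(decoy_refs)

    summary: Dict[str, object] = {
        "scenario": scenario.name,
        "seed": seed,
        "config_hash": scenario.config_hash(),
        "channels": {},
    }
    results: Dict[str, object] = {}
    for spec, sseq in zip(scenario.channels, s_channels):
        res = run_channel(spec, refs, oligos, target_index, decoy_index, scenario, sseq)
        results[spec.label] = res
        label = spec.label
        prep.write_fastq(res["reads"], outdir / f"{label}.raw.fastq")
        prep.write_truth_tsv(res["reads"], outdir / f"{label}.truth.tsv")
        with open(outdir / f"{label}.clean.fastq", "w") as fh:
            for rid, s in res["clean"].items():
                fh.write(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n")
        res["qc_report"].to_json(outdir / f"{label}.qc.json")
        mapping.write_sam(
            res["alignments"].values(),
            res["clean"],
            {rid: len(seq) for rid, seq in target.items()},
            outdir / f"{label}.sam",
        )
        mis = damage.misincorporation_table(
            res["alignments"].values(), target_refs, res["clean"]
        )
        mis.counts.to_csv(outdir / f"{label}.misincorporation.tsv", sep="\t")
        comp = damage.composition_context(
            res["alignments"].values(), target_refs, res["clean"]
        )
        comp.as_frame().to_csv(outdir / f"{label}.composition.tsv", sep="\t")
        cc = res["channel_counts"]
        ga1 = float(mis.frequency("G>A").iloc[0]) if mis.n_alignments else 0.0
        summary["channels"][label] = {
            "stage_counts": res["stage_counts"],
            "qc": {
                "input": res["qc_report"].input_reads,
                "surviving": res["qc_report"].surviving,
            },
            "total_reads": cc.total_reads,
            "nuc_reads": cc.nuc_reads,
            "nuc_bp": cc.nuc_bp,
            "mt_reads": cc.mt_reads,
            "mt_bp": cc.mt_bp,
            "endo_pct": chan.endogenous_ratio(cc) if cc.total_reads else 0.0,
            "ga_position1": ga1,
            "mean_read_len": damage.read_summaries(res["clean"].values())["mean_length"],
        }
        res["misincorporation"] = mis
        res["composition"] = comp
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    marker.unlink()
    results["summary"] = summary
    return results


def report(outdir) -> str:
    """Human-readable summary of a completed scenario run."""
    outdir = Path(outdir)
    path = outdir / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"no summary.json under {outdir}; run the scenario first")
    with open(path) as fh:
        summary = json.load(fh)
    lines = [
        f"scenario: {summary['scenario']}  (seed {summary['seed']}, "
        f"config {summary['config_hash']})",
        f"{'channel':<18}{'reads':>9}{'nuc':>8}{'mt':>6}{'%endo':>8}{'G>A@1':>8}",
    ]
    chans = summary["channels"]
    for label, c in chans.items():
        lines.append(
            f"{label:<18}{c['total_reads']:>9}{c['nuc_reads']:>8}"
            f"{c['mt_reads']:>6}{c['endo_pct']:>8.2f}{c['ga_position1']:>8.3f}"
        )
    labels = list(chans)
    if "phosphatase" in labels and "control" in labels:
        t, c = chans["phosphatase"], chans["control"]
        if c["total_reads"]:
            lines.append(
                f"fold change (phosphatase/control): reads "
                f"{t['total_reads'] / c['total_reads']:.1f}x, endo-bp "
                f"{(t['nuc_bp'] + t['mt_bp']) / max(1, c['nuc_bp'] + c['mt_bp']):.1f}x"
            )
    return "\n".join(lines)
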