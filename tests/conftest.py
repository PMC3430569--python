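"""Shared fixtures: small reference sets and session-scoped scenario runs."""

import json

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsmstools import pipeline, prep, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_refs():
    return simulate.make_references(
        {"endo_nuclear": 60_000, "endo_mito": 16_660, "decoy": 20_000, "microbial": 20_000},
        gc_targets=0.5,
        n_microbial=2,
        seed=101,
    )


@pytest.fixture(scope="session")
def endo_fragments(small_refs):
    """A pool of purely endogenous fragments with damage applied."""
    cfg = simulate.FragmentConfig(
        n_fragments=4_000,
        origin_mixture={
            "endo_nuclear": 0.99,
            "endo_mito": 0.01,
            "decoy": 0.0,
            "microbial": 0.0,
        },
    )
    frags = simulate.draw_fragments(small_refs, cfg, seed=202)
    return simulate.deaminate_all(frags, cfg, seed=203), cfg


@pytest.fixture(scope="session")
def phosphatase_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("phos")
    cfg = pipeline.builtin_scenario("TP-phosphatase", n_fragments=20_000, seed=7)
    res = pipeline.run_scenario(cfg, outdir)
    return outdir, res


@pytest.fixture(scope="session")
def prep_reads(endo_fragments):
    frags, _ = endo_fragments
    reads, counts = prep.run_prep(frags, prep.PrepConfig(temperature=80), seed=303)
    return reads, counts
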