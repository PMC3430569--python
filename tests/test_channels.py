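"""Channel statistics: ratios, binomial quantiles, fold changes, consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_binomial_quantile

from tsmstools import channels as chan


@pytest.fixture(scope="module")
def table():
    return chan.load_channel_counts()


def test_quantile_matches_brute_force_on_grid():
    for n in (1, 2, 7, 33, 250, 1000):
        for p in (0.001, 0.137, 0.5, 0.731, 0.999):
            for q in (0.05, 0.5, 0.95):
                assert chan.binomial_quantile(q, n, p) == brute_force_binomial_quantile(
                    q, n, p
                ), (n, p, q)


def test_quantile_edge_cases():
    assert chan.binomial_quantile(0.95, 100, 0.0) == 0
    assert chan.binomial_quantile(0.05, 100, 1.0) == 100
    with pytest.raises(ValueError):
        chan.binomial_quantile(0.0, 10, 0.5)
    with pytest.raises(ValueError):
        chan.binomial_quantile(0.5, 10, 1.5)


@given(
    ratios=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=5),
    weights=st.lists(st.floats(min_value=0.1, max_value=10.0), min_size=5, max_size=5),
)
@settings(max_examples=60)
def test_rmin_is_convex_combination(ratios, weights):
    chans = [
        {
            "nuc_reads": r * 1000,
            "total_reads": 1000,
            "loaded_volume": 1.0,
            "pooled_volume": w,
        }
        for r, w in zip(ratios, weights)
    ]
    exp = chan.spiking_expectation(chans, 10_000)
    assert min(ratios[: len(chans)]) - 1e-9 <= exp.rmin <= max(ratios[: len(chans)]) + 1e-9


def test_endogenous_ratio_includes_mito():
    cc = chan.ChannelCounts("x", total_reads=1000, nuc_reads=50, mt_reads=10)
    assert chan.endogenous_ratio(cc) == 6.0


def test_endogenous_reads_cannot_exceed_total():
    with pytest.raises(ValueError):
        chan.ChannelCounts("x", total_reads=10, nuc_reads=8, mt_reads=5)


def test_fixture_loads_with_volumes(table):
    assert len(table) == 19
    spiked = table[table["condition"] == "spiking"]
    assert spiked["loaded_volume_ul"].isna().all()


def test_fold_change_flags_failed_pair(table):
    pairs = chan.fold_change_summary(table)
    by_sample = pairs.set_index("sample")
    assert bool(by_sample.loc["TP2RE", "failed"])
    assert not bool(by_sample.loc["TP2", "failed"])


def test_fold_change_arithmetic_small_example():
    df = pd.DataFrame(
        [
            dict(sample="S", fov=110, n_channels=1, condition="80C_phosphatase",
                 total_reads=1000, nuc_reads=60, nuc_bp=1800, mt_reads=0, mt_bp=0,
                 loaded_volume_ul=np.nan, pooled_volume_ul=np.nan),
            dict(sample="S", fov=110, n_channels=1, condition="80C",
                 total_reads=100, nuc_reads=30, nuc_bp=900, mt_reads=0, mt_bp=0,
                 loaded_volume_ul=np.nan, pooled_volume_ul=np.nan),
        ]
    )
    pairs = chan.fold_change_summary(df)
    row = pairs.iloc[0]
    assert row["read_ratio"] == 10.0
    assert row["endo_bp_ratio"] == 2.0
    assert row["endo_ratio_decrease"] == pytest.approx(30.0 / 6.0)


def test_table_recomputation_is_deterministic(table):
    a = chan.fold_change_summary(table)
    b = chan.fold_change_summary(chan.load_channel_counts())
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def _synthetic_columns(rng, n_sites, depth, error):
    truth = rng.choice(list("ACGT"), n_sites)
    cols = {}
    for i, t in enumerate(truth):
        bases = []
        for _ in range(depth):
            if rng.random() < error:
                bases.append(str(rng.choice([b for b in "ACGT" if b != t])))
            else:
                bases.append(str(t))
        cols[i] = bases
    return "".join(truth), cols


def test_consensus_depth2_identical_proportion():
    rng = np.random.default_rng(99)
    e = 0.1
    truth, cols = _synthetic_columns(rng, 5000, 2, e)
    res = chan.consensus(cols, min_depth=2)
    expected = (1 - e) ** 2 + e**2 / 3
    se = math.sqrt(expected * (1 - expected) / 5000)
    assert abs(res.prop_identical_depth2 - expected) < 3 * se


def test_consensus_accuracy_monotone_in_depth():
    # Same pileup, rising depth threshold: shallow (depth-2) calls are the
    # least accurate component, so accuracy must not decrease.
    rng = np.random.default_rng(7)
    cols = {}
    truth_parts = []
    offset = 0
    for depth in (2, 4, 6):
        t, c = _synthetic_columns(rng, 5000, depth, 0.3)
        truth_parts.append(t)
        cols.update({offset + k: v for k, v in c.items()})
        offset += 5000
    truth = "".join(truth_parts)
    accs = [
        chan.consensus(cols, min_depth=d, truth=truth).accuracy for d in (2, 3, 4)
    ]
    assert accs[0] <= accs[1] <= accs[2]


def test_consensus_ignores_low_depth_sites():
    cols = {0: ["A"], 1: ["C", "C"], 2: ["G", "G", "T"]}
    res = chan.consensus(cols, min_depth=2)
    assert 0 not in res.calls
    assert res.calls[1] == "C"
    assert res.calls[2] == "G"


def test_consensus_no_call_on_tie():
    res = chan.consensus({0: ["A", "C"]}, min_depth=2)
    assert 0 not in res.calls
    assert res.prop_identical_depth2 == 0.0


def test_mito_coverage_summary():
    df = pd.DataFrame(
        [dict(sample="S", fov=110, n_channels=1, condition="80C",
              total_reads=10, nuc_reads=1, nuc_bp=100, mt_reads=2, mt_bp=16660,
              loaded_volume_ul=np.nan, pooled_volume_ul=np.nan)]
    )
    out = chan.mb_and_coverage_summary(df)
    assert out["mito_coverage"] == pytest.approx(1.0)
    assert out["mt_bp"] == 16660
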