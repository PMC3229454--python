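import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bmptc.filtering import (
    FilterConfig,
    cellline_filter,
    count_events,
    count_events_table,
    general_filter,
    is_regulated,
    rank_genes,
    timepoint_filter,
    up_fraction,
)
from bmptc.io_model import CANONICAL_TIMES, ValidationError
from tests.conftest import make_matrix

FIVE_LINES = ("L1", "L2", "L3", "L4", "L5")


def brute_force_events(values, threshold):
    """Independent per-cell scan counting (up, down) qualifying events."""
    cut = math.log2(threshold)
    up = down = 0
    for v in values:
        if not math.isfinite(v):
            continue
        if v >= cut:
            up += 1
        elif v <= -cut:
            down += 1
    return up, down


@pytest.mark.parametrize("ratio, fold, expected", [
    (1.0, 2, "up"),
    (-1.0, 2, "down"),
    (0.99, 2, "none"),
    (-0.99, 2, "none"),
    (math.log2(3), 3, "up"),
    (0.0, 2, "none"),
])
def test_is_regulated(ratio, fold, expected):
    assert is_regulated(ratio, fold) == expected


def test_is_regulated_rejects_bad_threshold():
    with pytest.raises(ValidationError):
        is_regulated(1.0, 1.0)


def test_cellline_filter_examples():
    values = np.array([
        [0, 0, 0, 0, 0, 1.1],       # one qualifying time point
        [0.9, -0.9, 0.5, 0, 0, 0],  # never reaches 2-fold
    ])
    kept = cellline_filter(make_matrix(values))
    assert kept == ["p0"]


def test_cellline_filter_excludes_incomplete_probes():
    values = np.array([[np.nan, 0, 0, 0, 0, 2.0], [0, 0, 0, 0, 0, 2.0]])
    assert cellline_filter(make_matrix(values)) == ["p1"]


def test_cellline_filter_needs_six_timepoints(dataset):
    matrices, _, _, _ = dataset
    with pytest.raises(ValidationError):
        cellline_filter(matrices["BMP4"])  # five cell lines at once


def test_timepoint_filter_examples():
    values = np.zeros((2, 6))
    values[0, 2] = 1.0  # 3 h
    m = make_matrix(values)
    assert timepoint_filter(m, 3.0) == ["p0"]
    assert timepoint_filter(m, 6.0) == []
    with pytest.raises(ValidationError):
        timepoint_filter(m, 2.0)


def test_general_filter_rule():
    log2_3 = math.log2(3)
    values = np.zeros((4, 30))
    values[0, :3] = log2_3        # exactly 3 events at 3-fold -> retained
    values[1, :3] = 1.0           # 3 events at 2-fold only -> dropped
    values[2, 4:8] = -1.0         # 4 events at 2-fold down -> retained
    m = make_matrix(values, cell_lines=FIVE_LINES)
    assert general_filter(m) == ["p0", "p2"]


def test_general_filter_rejects_mixed_ligands(dataset):
    matrices, _, _, _ = dataset
    merged = matrices["BMP4"].data.join(matrices["BMP7"].data, lsuffix="")
    from bmptc.io_model import ExpressionMatrix
    with pytest.raises(ValidationError, match="ligand"):
        general_filter(ExpressionMatrix(merged))


def test_filters_match_brute_force_scan():
    """All three filters agree with exhaustive per-cell scans."""
    rng = np.random.default_rng(21)
    cfg = FilterConfig()
    for _ in range(5):
        values = rng.normal(0, 0.8, (200, 30))
        values[rng.random((200, 30)) < 0.02] = np.nan
        m = make_matrix(values, cell_lines=FIVE_LINES)
        # general
        expected = []
        for i, pid in enumerate(m.probe_ids):
            n3 = sum(1 for v in values[i] if math.isfinite(v) and abs(v) >= math.log2(3))
            n2 = sum(1 for v in values[i] if math.isfinite(v) and abs(v) >= 1.0)
            if n3 >= 3 or n2 >= 4:
                expected.append(pid)
        assert general_filter(m, cfg) == expected
        # per cell line
        for ci, cl in enumerate(FIVE_LINES):
            block = values[:, ci * 6:(ci + 1) * 6]
            expected = [
                pid for i, pid in enumerate(m.probe_ids)
                if np.isfinite(block[i]).all() and (np.abs(block[i]) >= 1.0).any()
            ]
            assert cellline_filter(m.subset_cell_line(cl), cfg) == expected
        # per time point
        for ti, t in enumerate(CANONICAL_TIMES):
            cols = values[:, ti::6]
            expected = [
                pid for i, pid in enumerate(m.probe_ids)
                if any(math.isfinite(v) and abs(v) >= 1.0 for v in cols[i])
            ]
            assert timepoint_filter(m, t, cfg) == expected


def test_count_events_thirty_event_bound():
    m = make_matrix(np.full((1, 30), 1.0), cell_lines=FIVE_LINES)
    count = count_events(m, "p0")
    assert (count.up_events, count.down_events, count.total_events) == (30, 0, 30)


def test_count_events_mixed_directions():
    values = np.zeros((1, 6))
    values[0, :3] = [1.2, -1.5, 0.3]
    count = count_events(make_matrix(values), "p0")
    assert (count.up_events, count.down_events, count.total_events) == (1, 1, 2)
    with pytest.raises(KeyError):
        count_events(make_matrix(values), "nope")


def test_count_events_table_matches_exhaustive_scan(dataset):
    matrices, _, _, _ = dataset
    m = matrices["BMP7"]
    table = count_events_table(m).set_index("probe_id")
    rng = np.random.default_rng(0)
    for pid in rng.choice(m.probe_ids, 50, replace=False):
        up, down = brute_force_events(m.data.loc[pid].to_numpy(), 2.0)
        assert table.loc[pid, "up_events"] == up
        assert table.loc[pid, "down_events"] == down


def test_count_events_invariant_under_column_permutation(dataset):
    matrices, _, _, _ = dataset
    m = matrices["BMP4"]
    table = count_events_table(m)
    shuffled = m.data[list(np.random.default_rng(5).permutation(m.data.columns))]
    up = (shuffled >= 1.0).sum(axis=1)
    assert (table.set_index("probe_id")["up_events"] == up).all()


def test_gene_representative_is_strongest_probe():
    values = np.zeros((3, 6))
    values[0, :2] = 1.5   # gene gA via probe p0: 2 events
    values[1, :4] = 1.5   # gene gA via probe p1: 4 events  (representative)
    values[2, :1] = -1.5  # gene gB
    table = count_events_table(make_matrix(values), {"p0": "gA", "p1": "gA", "p2": "gB"})
    row = table.set_index("gene_id").loc["gA"]
    assert row["probe_id"] == "p1" and row["total_events"] == 4


def test_rank_genes_order_and_ties():
    counts = pd.DataFrame([
        {"gene_id": "gA", "probe_id": "p1", "up_events": 5, "down_events": 0, "total_events": 5},
        {"gene_id": "gB", "probe_id": "p2", "up_events": 0, "down_events": 7, "total_events": 7},
        {"gene_id": "gC", "probe_id": "p3", "up_events": 3, "down_events": 2, "total_events": 5},
        {"gene_id": "gD", "probe_id": "p4", "up_events": 1, "down_events": 1, "total_events": 2},
    ])
    ranked = rank_genes(counts, min_total=3)
    assert ranked["gene_id"].tolist() == ["gB", "gA", "gC"]  # tie: gA (5 up) before gC


def test_rank_genes_full_sort_oracle():
    rng = np.random.default_rng(17)
    counts = pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(500)],
        "probe_id": [f"p{i:03d}" for i in range(500)],
        "up_events": rng.integers(0, 16, 500),
        "down_events": rng.integers(0, 16, 500),
    })
    counts["total_events"] = counts["up_events"] + counts["down_events"]
    ranked = rank_genes(counts, min_total=1)
    oracle = sorted(
        (r for r in counts.to_dict("records") if r["total_events"] >= 1),
        key=lambda r: (-r["total_events"], -r["up_events"], r["gene_id"]),
    )
    assert ranked["gene_id"].tolist() == [r["gene_id"] for r in oracle]


def test_up_fraction():
    ranked = pd.DataFrame({
        "gene_id": ["a", "b"], "up_events": [3, 5], "down_events": [1, 0],
        "total_events": [4, 5],
    })
    assert up_fraction(ranked, 1) == 0.75
    assert up_fraction(ranked.assign(down_events=0, total_events=[3, 5]), 2) == 1.0
    assert up_fraction(ranked, 2) == pytest.approx(8 / 9)
    with pytest.raises(ValidationError):
        up_fraction(ranked, 0)
    with pytest.raises(ValidationError):
        up_fraction(ranked, 3)


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000), fc_lo=st.floats(1.5, 2.5), fc_hi=st.floats(2.5, 6.0))
def test_threshold_monotonicity(seed, fc_lo, fc_hi):
    """Raising the fold-change cutoff never grows retained sets or counts."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1.0, (50, 6))
    m = make_matrix(values)
    lo = FilterConfig(fc2_threshold=fc_lo, fc3_threshold=6.0)
    hi = FilterConfig(fc2_threshold=fc_hi, fc3_threshold=6.0)
    assert set(cellline_filter(m, hi)) <= set(cellline_filter(m, lo))
    assert set(timepoint_filter(m, 3.0, hi)) <= set(timepoint_filter(m, 3.0, lo))
    t_lo = count_events_table(m, config=lo).set_index("probe_id")
    t_hi = count_events_table(m, config=hi).set_index("probe_id")
    assert (t_hi["total_events"] <= t_lo["total_events"]).all()


def test_general_implies_some_cellline_pass(dataset):
    """Every general-filter survivor passes the cell-line filter somewhere."""
    matrices, _, _, _ = dataset
    m = matrices["BMP4"]
    survivors = set(general_filter(m))
    union = set()
    for cl in m.cell_lines:
        union |= set(cellline_filter(m.subset_cell_line(cl)))
    assert survivors <= union
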