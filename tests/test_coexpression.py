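import numpy as np
import pytest

from bmptc.coexpression import (
    average_linkage_cluster,
    correlation_distance,
    extract_tight_clusters,
    intersect_clusters,
    mean_pairwise_correlation,
    sample_cluster,
    TightCluster,
)
from bmptc.filtering import general_filter
from bmptc.io_model import ValidationError
from bmptc.synthetic_data import jaccard
from tests.conftest import make_matrix

FIVE_LINES = ("L1", "L2", "L3", "L4", "L5")


def naive_upgma(dist):
    """O(n^3) UPGMA reference: repeatedly merge the closest pair, where
    cluster distance is the unweighted mean over all member pairs."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def cophenetic_from_merges(merges, n):
    """Leaf-pair cophenetic heights implied by a merge list."""
    members = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for step, (a, b, d, _) in enumerate(merges):
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = d
        members[n + step] = members.pop(a) + members.pop(b)
    return coph


def test_correlation_distance_definition():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 1, 30)
    assert correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)
    assert correlation_distance(x, -x) == pytest.approx(2.0, abs=1e-12)
    r = np.corrcoef(x, y)[0, 1]
    assert correlation_distance(x, y) == pytest.approx(1 - r, abs=1e-12)
    with pytest.raises(ValidationError):
        correlation_distance(np.ones(10), x[:10])


def test_two_identical_rows_merge_at_zero():
    rng = np.random.default_rng(2)
    row = rng.normal(0, 1, 30)
    m = make_matrix(np.vstack([row, row]), cell_lines=FIVE_LINES)
    dendro = average_linkage_cluster(m)
    assert dendro.merges.shape == (1, 4)
    assert dendro.merges[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_linkage_matches_naive_oracle():
    """Merge heights and implied cophenetic structure equal the O(n^3) UPGMA."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        values = rng.normal(0, 1, (n, 12))
        from scipy.spatial.distance import squareform, pdist
        dist = squareform(pdist(values, "correlation"))
        m = make_matrix(values, cell_lines=("L1", "L2"))
        dendro = average_linkage_cluster(m)
        oracle = naive_upgma(dist)
        np.testing.assert_allclose(
            dendro.merges[:, 2], [h for *_, h, _ in oracle], atol=1e-9
        )
        coph_impl = cophenetic_from_merges(
            [(int(a), int(b), h, int(c)) for a, b, h, c in dendro.merges], n
        )
        coph_oracle = cophenetic_from_merges(oracle, n)
        np.testing.assert_allclose(coph_impl, coph_oracle, atol=1e-9)


def test_duplicated_rows_merge_first():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, (6, 30))
    doubled = np.repeat(base, 2, axis=0)
    m = make_matrix(doubled, cell_lines=FIVE_LINES)
    dendro = average_linkage_cluster(m)
    assert np.all(dendro.merges[:6, 2] < 1e-12)


def test_tight_cluster_planted_block():
    """A planted 40-probe correlated block among 400 nulls is recovered."""
    rng = np.random.default_rng(5)
    latent = rng.normal(0, 1.5, 30)
    block = latent + rng.normal(0, 0.25, (40, 30))
    nulls = rng.normal(0, 1, (400, 30))
    values = np.vstack([block, nulls])
    m = make_matrix(values, cell_lines=FIVE_LINES,
                    probe_ids=[f"b{i}" for i in range(40)] + [f"n{i}" for i in range(400)])
    dendro = average_linkage_cluster(m)
    tight = extract_tight_clusters(dendro, m)
    assert len(tight) == 1
    planted = {f"b{i}" for i in range(40)}
    assert len(planted & set(tight[0].members)) >= 36
    assert tight[0].mean_correlation >= 0.8


def test_no_tight_cluster_in_noise():
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(0, 1, (300, 30)), cell_lines=FIVE_LINES)
    dendro = average_linkage_cluster(m)
    assert extract_tight_clusters(dendro, m) == []


def test_cut_zero_gives_no_clusters():
    rng = np.random.default_rng(7)
    m = make_matrix(rng.normal(0, 1, (30, 6)))
    dendro = average_linkage_cluster(m)
    assert extract_tight_clusters(dendro, m, cut_height=0.0, min_size=2, tightness=0.01) == []


def test_tight_clusters_partition_leaves(dataset):
    matrices, _, _, _ = dataset
    m = matrices["BMP4"]
    sub = m.subset_probes(general_filter(m))
    dendro = average_linkage_cluster(sub)
    tight = extract_tight_clusters(dendro, sub, cut_height=0.6, min_size=5, tightness=0.3)
    seen = [p for c in tight for p in c.members]
    assert len(seen) == len(set(seen))  # no probe in two clusters


def test_intersect_clusters():
    a = TightCluster(["p1", "p2", "p3"], 0.9, 0.3)
    b = TightCluster(["p2", "p3", "p4"], 0.9, 0.3)
    g = intersect_clusters(a, b)
    assert g.shared_probes == ["p2", "p3"]
    assert (g.size_a, g.size_b) == (3, 3)
    assert intersect_clusters(b, a).shared_probes == g.shared_probes  # commutative
    disjoint = intersect_clusters(a, TightCluster(["x"], 1.0, 0.3))
    assert disjoint.shared_probes == []


def test_synexpression_group_recovery(dataset):
    """Intersecting the top tight cluster per ligand recovers the planted
    shared group (Jaccard >= 0.8) and its unique-gene subset."""
    matrices, annotations, _, truth = dataset
    tops = {}
    for lig, m in matrices.items():
        sub = m.subset_probes(general_filter(m))
        tight = extract_tight_clusters(average_linkage_cluster(sub), sub)
        assert tight, f"no tight cluster for {lig}"
        tops[lig] = tight[0]
    group = intersect_clusters(tops["BMP4"], tops["BMP7"], annotations)
    assert jaccard(group.shared_probes, truth.shared_group) >= 0.8
    assert 0 < len(group.unique_genes) <= group.size


def test_samples_cocluster_by_cell_line(dataset):
    """Within-cell-line samples correlate more than between-line samples."""
    matrices, _, _, _ = dataset
    m = matrices["BMP4"]
    sub = m.subset_probes(general_filter(m))
    corr = np.corrcoef(sub.values.T)
    lines = [e.cell_line for e in sub.events]
    within, between = [], []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            (within if lines[i] == lines[j] else between).append(corr[i, j])
    assert np.mean(within) > np.mean(between)
    # and the column dendrogram is at least buildable on the same metric
    assert sample_cluster(sub).merges.shape == (len(lines) - 1, 4)


def test_newick_and_json_export(tmp_path):
    rng = np.random.default_rng(8)
    m = make_matrix(rng.normal(0, 1, (5, 6)), probe_ids=list("abcde"))
    dendro = average_linkage_cluster(m)
    dendro.write(tmp_path / "t.nwk", tmp_path / "t.json")
    nwk = (tmp_path / "t.nwk").read_text()
    assert nwk.endswith(";\n") and all(leaf in nwk for leaf in "abcde")
    import json
    payload = json.loads((tmp_path / "t.json").read_text())
    assert payload["leaves"] == list("abcde") and len(payload["merges"]) == 4
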