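"""Windowed FST, permutation flags, Garud H, clustering, gene overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from conftest import make_matrix, make_panel
from vectorsweep.selection import (HaplotypeCluster, cluster_haplotypes,
                                   cluster_association_table,
                                   cluster_phenotype_association, garud_h,
                                   genes_in_windows, h12_scan, hudson_numden,
                                   read_gff3_genes, sweep_regions,
                                   windowed_fst)
from vectorsweep.synthetic import PlantedFeature, SimulationConfig, generate_panel


def hap_cols(sample_idx):
    idx = np.asarray(sample_idx)
    return np.stack([2 * idx, 2 * idx + 1], axis=1).reshape(-1)


# ---------------------------------------------------------------------------
# Hudson FST

def test_opposite_fixation_gives_fst_one():
    haps = np.zeros((5, 20), dtype=np.int8)
    haps[:, :12] = 1  # group A (6 samples) fixed alt, group B (4) fixed ref
    matrix = make_matrix(haps)
    out = windowed_fst(matrix, np.arange(12), np.arange(12, 20),
                       window_bp=1000)
    assert len(out) == 1
    assert out["fst"].iloc[0] == pytest.approx(1.0)
    assert out["n_variants"].iloc[0] == 5


def test_identical_frequencies_near_zero():
    config = SimulationConfig(n_resistant=200, n_susceptible=200, n_control=0,
                              chromosomes=(("2L", 100_000),), n_sites=500,
                              seed=13)
    panel, matrix, _ = generate_panel(config)
    out = windowed_fst(matrix, panel.haplotype_indices("resistant"),
                       panel.haplotype_indices("susceptible"),
                       window_bp=100_000)
    assert abs(out["fst"].iloc[0]) < 0.02


def test_three_site_window_matches_hand_oracle():
    """Ratio-of-sums over listed genotypes equals per-site hand evaluation."""
    a = np.array([[1, 1, 0, 1, 0, 1],    # group A haplotypes per site
                  [0, 0, 0, 1, 1, 0],
                  [1, 0, 1, 1, 1, 1]], dtype=np.int8)
    b = np.array([[0, 0, 1, 0],
                  [1, 1, 0, 1],
                  [0, 0, 0, 1]], dtype=np.int8)
    haps = np.concatenate([a, b], axis=1)
    matrix = make_matrix(haps)
    out = windowed_fst(matrix, np.arange(6), np.arange(6, 10), window_bp=10)

    nums, dens = [], []
    for site in range(3):
        n1, n2 = 6, 4
        p1, p2 = a[site].sum() / n1, b[site].sum() / n2
        nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    assert out["fst"].iloc[0] == pytest.approx(sum(nums) / sum(dens), abs=1e-12)


def test_single_site_window_equals_per_site_estimator():
    hap = np.array([[1, 1, 1, 0, 1, 0, 0, 1, 0, 0]], dtype=np.int8)
    matrix = make_matrix(hap)
    out = windowed_fst(matrix, np.arange(6), np.arange(6, 10), window_bp=1)
    num, den = hudson_numden([4], [6], [1], [4])
    assert out["fst"].iloc[0] == pytest.approx(float(num[0] / den[0]))


def test_windows_without_variants_omitted():
    hap = np.zeros((2, 8), dtype=np.int8)
    hap[:, 0] = 1
    matrix = make_matrix(hap, positions=[100, 5100])
    out = windowed_fst(matrix, np.arange(4), np.arange(4, 8), window_bp=1000)
    assert set(out["win_start"]) == {1, 5001}


def test_empty_group_rejected():
    matrix = make_matrix(np.zeros((1, 8), dtype=np.int8))
    with pytest.raises(ValueError):
        windowed_fst(matrix, np.arange(2), np.arange(2, 8))


# ---------------------------------------------------------------------------
# Garud's H statistics

def test_garud_closed_forms():
    # frequencies {0.4, 0.3, 0.2, 0.1} over 10 haplotypes of 2 SNPs
    haps = np.array([[0, 0]] * 4 + [[0, 1]] * 3 + [[1, 0]] * 2 + [[1, 1]],
                    dtype=np.int8)
    h1, h12, h123, h2h1 = garud_h(haps)
    assert h1 == pytest.approx(0.30)
    assert h12 == pytest.approx(0.54)
    assert h123 == pytest.approx(0.9 ** 2 + 0.1 ** 2)
    assert h2h1 == pytest.approx((0.30 - 0.16) / 0.30)


def test_garud_all_identical():
    h1, h12, _, h2h1 = garud_h(np.zeros((8, 5), dtype=np.int8))
    assert h1 == 1.0 and h12 == 1.0 and h2h1 == 0.0


def test_garud_all_singletons_closed_form():
    n = 8
    haps = np.eye(n, dtype=np.int8)  # n distinct haplotypes
    _, h12, _, _ = garud_h(haps)
    assert h12 == pytest.approx((2 / n) ** 2 + (n - 2) / n ** 2)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 2 ** 20))
def test_garud_invariants_and_order_independence(seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(rng.integers(2, 25), 6)).astype(np.int8)
    h1, h12, h123, h2h1 = garud_h(haps)
    assert 0 < h1 <= h12 <= h123 <= 1.0
    assert 0 <= h2h1 < 1.0
    shuffled = haps[rng.permutation(haps.shape[0])]
    assert garud_h(shuffled) == garud_h(haps)


def test_garud_input_validation():
    with pytest.raises(ValueError):
        garud_h(np.zeros((1, 4), dtype=np.int8))
    with pytest.raises(ValueError):
        garud_h(np.full((3, 4), -1, dtype=np.int8))


# ---------------------------------------------------------------------------
# H12 scan

def scan_panel(seed=17):
    config = SimulationConfig(n_resistant=6, n_susceptible=5, n_control=0,
                              chromosomes=(("2L", 40_000),), n_sites=200,
                              seed=seed)
    return generate_panel(config)


def test_h12_scan_degenerate_equals_direct():
    panel, matrix, _ = scan_panel()
    scan = h12_scan(matrix, panel, window_snps=100, n_iter=1,
                    subsample_size=12, groups=("resistant",), seed=0)
    assert len(scan) == 2
    for _, row in scan.iterrows():
        lo = matrix.sites[(matrix.sites["pos"] >= row["start_pos"])
                          & (matrix.sites["pos"] < row["end_pos"])].index
        block = matrix.haplotypes()[np.ix_(lo, hap_cols(np.arange(6)))].T
        assert row["mean_h12"] == pytest.approx(garud_h(block)[1])


def test_h12_scan_subsample_too_large_rejected():
    panel, matrix, _ = scan_panel()
    with pytest.raises(ValueError, match="subsample"):
        h12_scan(matrix, panel, window_snps=100, subsample_size=13,
                 groups=("resistant",))


def test_h12_scan_terminal_partial_window_dropped():
    panel, matrix, _ = scan_panel()
    scan = h12_scan(matrix, panel, window_snps=150, n_iter=2,
                    subsample_size=8, seed=1)
    # 200 sites -> one full 150-SNP window per group, remainder dropped
    assert len(scan) == 2
    assert set(scan["group"]) == {"resistant", "susceptible"}


def test_sweep_regions_collapse_runs():
    scan = pd.DataFrame({
        "chrom": ["X"] * 4, "group": ["resistant"] * 4,
        "start_pos": [1, 1001, 2001, 3001],
        "end_pos": [1001, 2001, 3001, 4001],
        "mean_h12": [0.1, 0.5, 0.6, 0.1],
        "is_sweep": [False, True, True, False]})
    regions = sweep_regions(scan)
    assert len(regions) == 1
    row = regions.iloc[0]
    assert (row["start_pos"], row["end_pos"], row["n_windows"]) == (1001, 3001, 2)
    assert row["max_h12"] == 0.6


# ---------------------------------------------------------------------------
# Haplotype clustering

def test_exact_duplicate_cluster_recovered():
    rng = np.random.default_rng(2)
    core = np.tile(rng.integers(0, 2, 40), (25, 1))
    noise = rng.integers(0, 2, size=(10, 40))
    haps = np.concatenate([core, noise]).astype(np.int8)
    clusters = cluster_haplotypes(haps, make_panel(12, 6), max_distance=0.0,
                                  min_cluster=20)
    assert len(clusters) == 1
    assert clusters[0].size >= 25


def test_all_distinct_random_haplotypes_no_cluster():
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(30, 200)).astype(np.int8)
    clusters = cluster_haplotypes(haps, make_panel(10, 5), max_distance=0.01,
                                  min_cluster=2)
    assert clusters == []


def test_two_planted_cores_recovered_with_sizes():
    rng = np.random.default_rng(4)
    core1 = np.tile(rng.integers(0, 2, 60), (22, 1))
    core2 = np.tile(rng.integers(0, 2, 60), (21, 1))
    noise = rng.integers(0, 2, size=(13, 60))
    haps = np.concatenate([core1, core2, noise]).astype(np.int8)
    clusters = cluster_haplotypes(haps, make_panel(20, 8), max_distance=0.0,
                                  min_cluster=20)
    assert sorted(c.size for c in clusters) == [21, 22]


def test_empty_window_rejected():
    with pytest.raises(ValueError):
        cluster_haplotypes(np.zeros((0, 0)), make_panel(2, 2))


def test_cluster_association_exact_hypergeometric():
    """All-resistant cluster of 20 among 46 R + 20 S haplotypes: two-sided
    Fisher p matches the hypergeometric tail and is significant."""
    panel = make_panel(23, 10)
    cluster = HaplotypeCluster(members=np.arange(20), size=20,
                               phenotype_counts={"resistant": 20})
    result = cluster_phenotype_association(cluster, panel)
    # two-sided exact p: sum of hypergeometric point masses no larger than
    # the observed table's (cluster draws 20 of the 46 resistant out of 66)
    observed = hypergeom.pmf(20, 66, 46, 20)
    masses = hypergeom.pmf(np.arange(0, 21), 66, 46, 20)
    p_exact = masses[masses <= observed * (1 + 1e-9)].sum()
    assert result["p_value"] == pytest.approx(p_exact, rel=1e-6)
    assert result["p_value"] < 0.05


def test_cluster_association_balanced_nonsignificant():
    panel = make_panel(10, 10)
    members = np.concatenate([np.arange(8), 20 + np.arange(8)])
    cluster = HaplotypeCluster(members=members, size=16,
                               phenotype_counts={"resistant": 8,
                                                 "susceptible": 8})
    result = cluster_phenotype_association(cluster, panel)
    assert result["p_value"] == pytest.approx(1.0)


def test_cluster_association_degenerate_flagged():
    panel = make_panel(5, 0, 3)  # no susceptible samples at all
    cluster = HaplotypeCluster(members=np.arange(4), size=4,
                               phenotype_counts={"resistant": 4})
    result = cluster_phenotype_association(cluster, panel)
    assert not result["defined"] and np.isnan(result["p_value"])


def test_association_table_bh_adjustment():
    panel = make_panel(23, 10)
    clusters = [
        HaplotypeCluster(np.arange(20), 20, {"resistant": 20}),
        HaplotypeCluster(np.concatenate([np.arange(6), 46 + np.arange(6)]),
                         12, {"resistant": 6, "susceptible": 6}),
    ]
    table = cluster_association_table(clusters, panel)
    assert len(table) == 2
    assert (table["q_value"] >= table["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# Gene overlap

GFF = """##gff-version 3
2L\tsrc\tgene\t500\t1500\t.\t+\t.\tID=AGAP000001;description=inside
2L\tsrc\tgene\t2000\t2050\t.\t-\t.\tID=AGAP000002;description=abutting
2L\tsrc\tmRNA\t500\t1500\t.\t+\t.\tID=not_a_gene
X\tsrc\tgene\t10\t20\t.\t+\t.\tID=AGAP000003
"""


def test_gff3_gene_reader(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    genes = read_gff3_genes(path)
    assert genes["gene_id"].tolist() == ["AGAP000001", "AGAP000002",
                                         "AGAP000003"]
    assert genes["description"].iloc[0] == "inside"


def test_gene_overlap_half_open_boundary(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    genes = read_gff3_genes(path)
    windows = pd.DataFrame({"chrom": ["2L"], "win_start": [1000],
                            "win_end": [2000], "fst": [0.5]})
    out = genes_in_windows(windows, genes)
    # gene 1 overlaps; gene 2 starts exactly at win_end (half-open) -> excluded
    assert out["gene_id"].tolist() == ["AGAP000001"]


def test_gene_overlap_bruteforce_oracle(tmp_path):
    rng = np.random.default_rng(9)
    genes = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(10)],
        "chrom": "2L",
        "start": rng.integers(1, 5000, 10),
        "description": ""})
    genes["end"] = genes["start"] + rng.integers(50, 2000, 10)
    windows = pd.DataFrame({"chrom": ["2L"] * 3,
                            "win_start": [1, 2001, 4001],
                            "win_end": [1001, 3001, 5001],
                            "fst": [0.1, 0.2, 0.3]})
    out = genes_in_windows(windows, genes, top_k=None)
    expected = {(w.win_start, g.gene_id)
                for w in windows.itertuples()
                for g in genes.itertuples()
                if g.start < w.win_end and g.end >= w.win_start}
    got = set(zip(out["win_start"], out["gene_id"]))
    assert got == expected


def test_gene_overlap_chromosome_mismatch_error():
    genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr2L"],
                          "start": [1], "end": [10], "description": [""]})
    windows = pd.DataFrame({"chrom": ["2L"], "win_start": [1],
                            "win_end": [1001], "fst": [0.5]})
    with pytest.raises(ValueError, match="2L"):
        genes_in_windows(windows, genes)
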