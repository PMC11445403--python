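"""Synthetic-data generator: determinism, planted truth, fixture formats."""

import numpy as np
import pysam
import pytest

from vectorsweep import variant_qc
from vectorsweep.cnv import softclip_proportion
from vectorsweep.synthetic import (PlantedFeature, QcFieldModel,
                                   SimulationConfig, generate_bioassay_counts,
                                   generate_breakpoint_reads, generate_panel,
                                   write_vcf)
from vectorsweep.vcfio import read_vcf


def small_config(**kw):
    defaults = dict(n_resistant=4, n_susceptible=3, n_control=2,
                    chromosomes=(("2L", 10_000),), n_sites=50, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_same_seed_byte_identical():
    features = [PlantedFeature(kind="candidate_snp", chrom="2L", pos=5000,
                               freq_by_group={"resistant": 0.5})]
    _, m1, _ = generate_panel(small_config(), features)
    _, m2, _ = generate_panel(small_config(), features)
    assert np.array_equal(m1.genotypes, m2.genotypes)
    assert m1.sites.equals(m2.sites)
    _, m3, _ = generate_panel(small_config(seed=2), features)
    assert not np.array_equal(m1.genotypes, m3.genotypes)


def test_zero_planted_frequency_realizes_zero():
    features = [PlantedFeature(kind="candidate_snp", chrom="2L", pos=5000,
                               freq_by_group={"resistant": 0.0,
                                              "susceptible": 1.0})]
    _, matrix, truth = generate_panel(small_config(), features)
    counts = truth.feature_counts.set_index("group")
    assert counts.loc["resistant", "alt_count"] == 0
    assert counts.loc["susceptible", "alt_count"] == 6  # 2 * 3 haplotypes


def test_realized_frequency_follows_binomial_law():
    """Planted 0.25 over 2000 sites x 46 alleles: mean within 3 SE."""
    config = SimulationConfig(n_resistant=23, n_susceptible=2, n_control=0,
                              chromosomes=(("2L", 100_000),), n_sites=2000,
                              seed=11)
    features = [PlantedFeature(kind="diff_window", chrom="2L", start=1,
                               end=100_001, freq_by_group={"resistant": 0.25})]
    panel, matrix, _ = generate_panel(config, features)
    res = matrix.haplotypes()[:, panel.haplotype_indices("resistant")]
    per_site_freq = res.mean(axis=1)
    se_mean = np.sqrt(0.25 * 0.75 / 46) / np.sqrt(2000)
    assert abs(per_site_freq.mean() - 0.25) < 3 * se_mean


def test_positions_strictly_increasing_and_site_count():
    _, matrix, _ = generate_panel(small_config())
    pos = matrix.sites["pos"].to_numpy()
    assert np.all(np.diff(pos) > 0)
    assert matrix.n_sites == 50


def test_feature_outside_chromosome_rejected():
    bad = PlantedFeature(kind="candidate_snp", chrom="2L", pos=20_000,
                         freq_by_group={"resistant": 0.5})
    with pytest.raises(ValueError, match="outside"):
        generate_panel(small_config(), [bad])
    with pytest.raises(ValueError, match="overlap"):
        generate_panel(small_config(), [
            PlantedFeature(kind="sweep", chrom="2L", start=1, end=5000,
                           core_freq=0.5),
            PlantedFeature(kind="diff_window", chrom="2L", start=4000,
                           end=6000, freq_by_group={"resistant": 0.5})])


def test_missing_rate_plants_missing_genotypes():
    _, matrix, _ = generate_panel(small_config(missing_rate=0.3))
    frac = (matrix.genotypes == -1).any(axis=2).mean()
    assert 0.15 < frac < 0.45


def test_vcf_roundtrip_identical_matrix(tmp_path):
    panel, matrix, _ = generate_panel(small_config(missing_rate=0.1))
    path = tmp_path / "panel.vcf"
    write_vcf(panel, matrix, QcFieldModel(), path)
    data = read_vcf(path)
    assert data.sample_ids == panel.sample_ids
    assert np.array_equal(data.matrix.genotypes, matrix.genotypes)
    assert data.matrix.sites.equals(matrix.sites)


def test_vcf_small_fixed_fields(tmp_path):
    config = small_config(n_resistant=1, n_susceptible=1, n_control=0,
                          n_sites=3)
    panel, matrix, _ = generate_panel(config)
    path = tmp_path / "three.vcf"
    write_vcf(panel, matrix, QcFieldModel(qd=12.5, qual=77.0), path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 3
    assert all("QD=12.5" in l and "GT:DP:GQ" in l and "|" in l for l in lines)


def test_planted_qd_failure_caught_downstream(tmp_path):
    panel, matrix, _ = generate_panel(small_config())
    model = QcFieldModel(site_overrides={4: {"QD": 4.0}})
    path = tmp_path / "qd.vcf"
    write_vcf(panel, matrix, model, path)
    data = read_vcf(path)
    passed, failed = variant_qc.site_filter(data.site_annotations.iloc[4])
    assert not passed and failed == ["QD"]
    assert variant_qc.site_filter(data.site_annotations.iloc[3])[0]


def cnv_feature():
    return PlantedFeature(kind="cnv", chrom="2R", start=5_000, end=9_000,
                          name="Dup_demo", clip_fraction=0.4)


def test_breakpoint_reads_clip_fraction_extremes(tmp_path):
    for frac, expected in ((0.0, 0.0), (1.0, 1.0)):
        path = tmp_path / f"reads_{frac}.sam"
        generate_breakpoint_reads(cnv_feature(), depth=40, clip_fraction=frac,
                                  read_len=100, seed=3, path=path)
        with pysam.AlignmentFile(path, check_sq=False) as sam:
            reads = list(sam)
        prof = softclip_proportion(reads, 5_000, "left")
        assert prof.proportion == expected


def test_breakpoint_reads_valid_sam(tmp_path):
    path = tmp_path / "reads.sam"
    n = generate_breakpoint_reads(cnv_feature(), depth=30, clip_fraction=0.5,
                                  read_len=100, seed=3, path=path)
    assert n == 60
    with pysam.AlignmentFile(path) as sam:
        reads = list(sam)
    assert len(reads) == 60
    for read in reads:
        assert read.infer_query_length() == 100
        assert len(read.query_sequence) == 100
    starts = [r.reference_start for r in reads]
    assert starts == sorted(starts)  # coordinate-sorted


def test_breakpoint_reads_input_validation(tmp_path):
    with pytest.raises(ValueError):
        generate_breakpoint_reads(cnv_feature(), depth=10, clip_fraction=0.5,
                                  read_len=0, seed=1, path=tmp_path / "x.sam")
    with pytest.raises(ValueError):
        generate_breakpoint_reads(cnv_feature(), depth=0, clip_fraction=0.5,
                                  read_len=100, seed=1, path=tmp_path / "y.sam")


def test_bioassay_counts_extremes_and_law():
    full = generate_bioassay_counts(100.0, 0.0, n_treated=60, n_control=30,
                                    seed=5)
    assert all(r.n_dead_24h == r.n_exposed
               for r in full["deltamethrin_0.05"])
    assert all(r.n_dead_24h == 0 for r in full["control"])

    big = generate_bioassay_counts(49.5, 5.0, n_treated=10_000, n_control=100,
                                   seed=5)
    dead = sum(r.n_dead_24h for r in big["deltamethrin_0.05"])
    se = np.sqrt(0.495 * 0.505 / 10_000)
    assert abs(dead / 10_000 - 0.495) < 3 * se
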