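"""Pipeline orchestration: run every stage from one YAML config.

Stage order is qc -> screen -> ld -> fst -> h12 -> clusters -> cnv ->
bioassay. A single seed fans out to per-stage streams (stage-name salted)
so toggling one stage never shifts another's randomness, and a fixed seed
makes every stochastic output byte-identical between runs. `make_demo`
writes a complete synthetic input bundle with known ground truth plus a
ready-to-run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bioassay, cnv, ld, screen, selection, synthetic, variant_qc, vcfio
from .panel import PhenotypedPanel

log = logging.getLogger("vectorsweep")

STAGES = ("qc", "screen", "ld", "fst", "h12", "clusters", "cnv", "bioassay")

COORDINATE_NOTE = ("# coordinates: 1-based positions; intervals half-open "
                   "[start, end) unless a column says otherwise\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str
    phenotypes: str
    outdir: str
    candidates: str | None = None
    gff3: str | None = None
    breakpoints: str | None = None
    sample_reads: dict[str, str] = field(default_factory=dict)  # sample -> SAM
    bioassay_counts: str | None = None
    bioassay_pairs: list = field(default_factory=list)  # [treatment, control, tier]
    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    fst_window_bp: int = 1000
    fst_n_perm: int = 200
    fst_centile: float = 99.0
    fst_noise_multiplier: float = 3.0
    h12_window_snps: int = 1000
    h12_n_iter: int = 200
    h12_subsample: int | None = None
    sweep_threshold: float = 0.2
    cluster_max_distance: float = 0.001
    cluster_min_size: int = 20
    cnv_threshold: float = 0.195
    cnv_mapq_min: int = 10
    cnv_tolerance_bp: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: v for k, v in self.__dict__.items()}, fh,
                           sort_keys=False)

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for label, path in (("vcf", self.vcf), ("phenotypes", self.phenotypes)):
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} input missing: {path}")


def stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage seed below 2**31, stable across stage toggles."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _write(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORDINATE_NOTE)
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict.

    Every stage writes its tables under ``outdir`` and contributes a
    summary block; failures abort with a :class:`StageError` naming the
    stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": {k: v for k, v in config.__dict__.items()
                                   if isinstance(v, (int, float, str, type(None)))},
                    "inputs": {}, "stages": {}}
    for label, path in (("vcf", config.vcf), ("phenotypes", config.phenotypes),
                        ("candidates", config.candidates), ("gff3", config.gff3),
                        ("breakpoints", config.breakpoints),
                        ("bioassay_counts", config.bioassay_counts)):
        if path and Path(path).exists():
            report["inputs"][label] = hashlib.md5(
                Path(path).read_bytes()).hexdigest()

    panel = PhenotypedPanel.from_tsv(config.phenotypes)
    data = vcfio.read_vcf(config.vcf)
    missing = [s for s in data.sample_ids if s not in set(panel.sample_ids)]
    if missing:
        raise StageError("qc", f"VCF samples without phenotype labels: {missing}")
    # align panel order to VCF sample order
    order = {s: i for i, s in enumerate(data.sample_ids)}
    panel = PhenotypedPanel(panel.samples.iloc[
        panel.samples["sample_id"].map(order).argsort()].reset_index(drop=True))

    filtered = data
    fst_flagged = pd.DataFrame()
    h12_windows = pd.DataFrame()

    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            if stage == "qc":
                filtered, ledger = variant_qc.apply_filters(data)
                _write(ledger, outdir / "qc_ledger.tsv")
                report["stages"]["qc"] = {
                    "n_input_sites": int(data.matrix.n_sites),
                    "n_retained_sites": int(filtered.matrix.n_sites)}
            elif stage == "screen":
                if not config.candidates:
                    raise ValueError("screen stage needs a candidates table")
                cands = screen.read_candidates_tsv(config.candidates)
                table = screen.screen_table(filtered.matrix, panel, cands)
                table["common"] = screen.highlight_common(table)
                ors = []
                for snp in cands:
                    try:
                        r = screen.odds_ratio_for_snp(filtered.matrix, panel,
                                                      snp.chrom, snp.pos)
                    except (KeyError, ValueError):
                        continue
                    ors.append({"label": snp.label, "odds_ratio": r.odds_ratio,
                                "ci_low": r.ci_low, "ci_high": r.ci_high,
                                "corrected": r.corrected,
                                "significant": r.significant})
                _write(table, outdir / "screen_frequencies.tsv")
                _write(pd.DataFrame(ors), outdir / "screen_odds_ratios.tsv")
                report["stages"]["screen"] = {
                    "n_candidates": len(cands),
                    "n_found": int(table["found"].sum()),
                    "n_common": int(table["common"].sum())}
            elif stage == "ld":
                if not config.candidates:
                    raise ValueError("ld stage needs a candidates table")
                cands = screen.read_candidates_tsv(config.candidates)
                present, labels = [], []
                for snp in cands:
                    try:
                        filtered.matrix.site_index(snp.chrom, snp.pos)
                    except KeyError:
                        continue
                    present.append((snp.chrom, snp.pos))
                    labels.append(snp.label)
                if len(present) < 2:
                    report["stages"]["ld"] = {"n_sites": len(present)}
                    continue
                ldm = ld.pairwise_r2(filtered.matrix, present, labels)
                _write(ldm.to_long_frame(), outdir / "ld_pairs.tsv")
                ldm.to_square_frame().to_csv(outdir / "ld_r2_matrix.tsv", sep="\t")
                report["stages"]["ld"] = {"n_sites": len(present)}
            elif stage == "fst":
                fst_flagged = selection.fst_permutation_significance(
                    filtered.matrix, panel, n_perm=config.fst_n_perm,
                    centile=config.fst_centile,
                    noise_multiplier=config.fst_noise_multiplier,
                    seed=stage_seed(config.seed, "fst"),
                    window_bp=config.fst_window_bp)
                _write(fst_flagged, outdir / "fst_windows.tsv")
                if config.gff3:
                    genes = selection.read_gff3_genes(config.gff3)
                    flagged = fst_flagged[fst_flagged["flagged"]]
                    if len(flagged):
                        _write(selection.genes_in_windows(flagged, genes),
                               outdir / "fst_genes.tsv")
                report["stages"]["fst"] = {
                    "n_windows": len(fst_flagged),
                    "n_flagged": int(fst_flagged["flagged"].sum()),
                    "max_fst": float(fst_flagged["fst"].max())}
            elif stage == "h12":
                h12_windows = selection.h12_scan(
                    filtered.matrix, panel, window_snps=config.h12_window_snps,
                    n_iter=config.h12_n_iter,
                    subsample_size=config.h12_subsample,
                    sweep_threshold=config.sweep_threshold,
                    seed=stage_seed(config.seed, "h12"))
                _write(h12_windows, outdir / "h12_windows.tsv")
                regions = selection.sweep_regions(h12_windows)
                _write(regions, outdir / "h12_sweeps.tsv")
                if config.gff3 and len(h12_windows):
                    genes = selection.read_gff3_genes(config.gff3)
                    flagged = h12_windows[h12_windows["is_sweep"]].rename(
                        columns={"start_pos": "win_start", "end_pos": "win_end"})
                    if len(flagged):
                        _write(selection.genes_in_windows(
                            flagged, genes, stat_column="mean_h12"),
                            outdir / "h12_genes.tsv")
                report["stages"]["h12"] = {
                    "n_windows": len(h12_windows),
                    "n_sweep_windows": int(h12_windows["is_sweep"].sum()),
                    "n_sweep_regions": len(regions)}
            elif stage == "clusters":
                windows = fst_flagged[fst_flagged["flagged"]] if len(fst_flagged) else pd.DataFrame()
                all_rows = []
                for win in windows.itertuples(index=False):
                    sites = filtered.matrix.sites
                    mask = ((sites["chrom"] == win.chrom)
                            & (sites["pos"] >= win.win_start)
                            & (sites["pos"] < win.win_end)).to_numpy()
                    block = filtered.matrix.haplotypes()[mask].T
                    clusters = selection.cluster_haplotypes(
                        block, panel, max_distance=config.cluster_max_distance,
                        min_cluster=config.cluster_min_size)
                    table = selection.cluster_association_table(clusters, panel)
                    table.insert(0, "win_start", win.win_start)
                    table.insert(0, "chrom", win.chrom)
                    all_rows.append(table)
                result = (pd.concat(all_rows, ignore_index=True)
                          if all_rows else pd.DataFrame())
                _write(result, outdir / "haplotype_clusters.tsv")
                report["stages"]["clusters"] = {
                    "n_windows_examined": len(windows),
                    "n_clusters": len(result)}
            elif stage == "cnv":
                if not config.breakpoints:
                    raise ValueError("cnv stage needs a breakpoint table")
                specs = cnv.read_breakpoints_tsv(config.breakpoints)
                calls = {}
                for sample, sam_path in config.sample_reads.items():
                    calls[sample] = cnv.screen_sample(
                        sam_path, specs, threshold=config.cnv_threshold,
                        mapq_min=config.cnv_mapq_min,
                        tolerance_bp=config.cnv_tolerance_bp)
                frame = cnv.calls_to_frame(calls)
                _write(frame, outdir / "cnv_calls.tsv")
                n_present = int((frame["call"] == "present").sum()) if len(frame) else 0
                report["stages"]["cnv"] = {
                    "n_samples": len(calls), "n_alleles": len(specs),
                    "n_present_calls": n_present}
            elif stage == "bioassay":
                if not config.bioassay_counts:
                    raise ValueError("bioassay stage needs a counts table")
                records = bioassay.read_records_tsv(config.bioassay_counts)
                summaries = []
                for treatment, control, tier in config.bioassay_pairs:
                    summaries.append(bioassay.summarise(
                        records[treatment], records[control], tier))
                frame = bioassay.summaries_to_frame(summaries)
                _write(frame, outdir / "bioassay_summary.tsv")
                report["stages"]["bioassay"] = {
                    "n_tests": len(summaries),
                    "classifications": [s.classification for s in summaries]}
        except StageError:
            raise
        except Exception as exc:  # halt with stage-named error
            raise StageError(stage, str(exc)) from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Demo bundle

#: Candidate SNPs echoing a West African resistance panel (group frequencies
#: planted exactly). gste2 position scaled to the demo chromosome length.
DEMO_CANDIDATES = [
    # gene, chrom, pos, ref, alt, label, (resistant, susceptible, control) freq
    ("vgsc", "2L", 2_416_980, "C", "T", "T791M", (0.0, 0.056, 0.056)),
    ("vgsc", "2L", 2_422_652, "T", "A", "L995F", (0.159, 0.15, 0.167)),
    ("vgsc", "2L", 2_429_745, "A", "T", "N1570Y", (0.109, 0.0, 0.063)),
    ("vgsc", "2L", 2_430_424, "G", "T", "A1746S", (0.0, 0.05, 0.063)),
    ("vgsc", "2L", 2_430_881, "C", "T", "P1874L", (0.043, 0.10, 0.063)),
    ("gste2", "3R", 598_062, "G", "C", "L119V", (0.068, 0.0, 0.0)),
]

DEMO_BIOASSAY = [
    # treatment label, per-replicate (n, dead), paired control, tier
    ("deltamethrin_0.05", [(21, 11), (20, 10), (20, 10), (20, 10), (20, 9)],
     "control_0.05", [(14, 1), (13, 1), (13, 1), (13, 1), (13, 1)],
     bioassay.DISCRIMINATING),
    ("deltamethrin_0.25", [(15, 14), (15, 14), (15, 14)],
     "control_0.25", [(13, 2), (12, 1), (12, 1)],
     bioassay.INTENSITY_5X),
]


def make_demo(outdir, seed: int = 0) -> RunConfig:
    """Write a study-shaped synthetic bundle and a ready RunConfig.

    The bundle plants: a 23/10/9 panel; six candidate SNPs at the
    frequencies above (exact counts); one FST-differentiated 1 kb window
    (0.9 vs 0.1) on 2R; one selective sweep (core frequency 0.8) on X;
    one CNV carrier sample; and tube-test counts whose pooled totals are
    101 exposed / 50 dead at the discriminating dose (control 66/5) and
    45/42 at 5x (control 37/4).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = stage_seed(seed, "demo")

    config = synthetic.SimulationConfig(
        n_resistant=23, n_susceptible=10, n_control=9,
        chromosomes=(("2L", 3_000_000), ("2R", 500_000),
                     ("3R", 1_000_000), ("X", 1_000_000)),
        n_sites={"2L": 1500, "2R": 5000, "3R": 1000, "X": 3000},
        seed=rng_seed)
    features = [
        synthetic.PlantedFeature(
            kind="candidate_snp", chrom=chrom, pos=pos, label=label,
            exact_counts=True,
            freq_by_group={"resistant": fr, "susceptible": fs, "control": fc})
        for _, chrom, pos, _, _, label, (fr, fs, fc) in DEMO_CANDIDATES
    ] + [
        synthetic.PlantedFeature(kind="diff_window", chrom="2R",
                                 start=250_001, end=251_001, label="diff_2R",
                                 freq_by_group={"resistant": 0.95,
                                                "susceptible": 0.05,
                                                "control": 0.5}),
        synthetic.PlantedFeature(kind="sweep", chrom="X", start=250_001,
                                 end=750_001, core_freq=0.8, label="sweep_X"),
        synthetic.PlantedFeature(kind="cnv", chrom="2R", start=358_000,
                                 end=362_000, name="Cyp6aap_Dup7",
                                 carriers=("R01",), clip_fraction=0.4,
                                 label="cnv_dup7"),
    ]
    panel, matrix, truth = synthetic.generate_panel(config, features)

    # fixture files
    vcf_path = outdir / "panel.vcf"
    synthetic.write_vcf(panel, matrix, vcfio.QcFieldModel(), vcf_path,
                        contigs=dict(config.chromosomes))
    panel.to_tsv(outdir / "phenotypes.tsv")
    truth.to_tsv(outdir / "truth_features.tsv")

    pd.DataFrame(
        [{"gene": g, "chrom": c, "pos": p, "ref": r, "alt": a, "label": l}
         for g, c, p, r, a, l, _ in DEMO_CANDIDATES]
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    cnv_feature = features[-1]
    pd.DataFrame([{"name": cnv_feature.name, "chrom": cnv_feature.chrom,
                   "start": cnv_feature.start, "end": cnv_feature.end}]
                 ).to_csv(outdir / "breakpoints.tsv", sep="\t", index=False)

    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    sample_reads = {}
    for k, sample in enumerate(["R01", "R02", "S01"]):
        frac = cnv_feature.clip_fraction if sample in cnv_feature.carriers else 0.02
        path = reads_dir / f"{sample}.sam"
        synthetic.generate_breakpoint_reads(
            cnv_feature, depth=60, clip_fraction=frac, read_len=150,
            seed=stage_seed(rng_seed + k, "reads"), path=path,
            chrom_length=500_000)
        sample_reads[sample] = str(path)

    rows = []
    for treatment, reps, control, creps, _tier in DEMO_BIOASSAY:
        for label, counts in ((treatment, reps), (control, creps)):
            for i, (n, dead) in enumerate(counts, start=1):
                rows.append({"treatment": label, "replicate": i,
                             "n_exposed": n, "n_dead_24h": dead})
    pd.DataFrame(rows).to_csv(outdir / "bioassay_counts.tsv", sep="\t",
                              index=False)

    genes = [
        ("AGAP002859", "2R", 249_500, 252_500, "cyp6aa1-like demo gene"),
        ("AGAP002860", "2R", 357_000, 363_000, "cyp6p3-like demo gene"),
        ("AGAP000818", "X", 400_000, 420_000, "cyp9k1-like demo gene"),
        ("AGAP000100", "X", 900_000, 950_000, "outside-sweep demo gene"),
        ("AGAP004707", "2L", 2_416_000, 2_431_500, "vgsc demo gene"),
        ("AGAP009194", "3R", 597_500, 599_500, "gste2 demo gene"),
    ]
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, chrom, start, end, desc in genes:
            fh.write(f"{chrom}\tdemo\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gid};description={desc}\n")

    run_config = RunConfig(
        vcf=str(vcf_path), phenotypes=str(outdir / "phenotypes.tsv"),
        outdir=str(outdir / "results"),
        candidates=str(outdir / "candidates.tsv"),
        gff3=str(outdir / "genes.gff3"),
        breakpoints=str(outdir / "breakpoints.tsv"),
        sample_reads=sample_reads,
        bioassay_counts=str(outdir / "bioassay_counts.tsv"),
        bioassay_pairs=[[t, c, tier] for t, _, c, _, tier in DEMO_BIOASSAY],
        seed=seed)
    run_config.to_yaml(outdir / "config.yaml")
    return run_config
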