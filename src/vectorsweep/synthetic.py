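"""Synthetic phenotyped panels with planted, known-truth genomic features.

Generates everything the downstream stages consume without any real
sequencing data: two phenotype groups (plus controls) of diploid phased
genotypes, candidate SNPs planted at group-specific frequencies, selective
sweeps (one core haplotype at elevated frequency over a contiguous
region), allele-frequency-differentiated windows, soft-clipped reads at
CNV breakpoints, and WHO tube-test replicate counts.

Background sites are unlinked: each haplotype draws independently from the
site's base allele frequency, so linkage exists only where a sweep is
planted. That is deliberate — it gives the LD, H12 and FST machinery a
null with known truth rather than coalescent realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .bioassay import TubeTestRecord
from .panel import MISSING, PHENOTYPES, GenotypeMatrix, PhenotypedPanel
from .vcfio import QcFieldModel, write_vcf  # noqa: F401  (re-exported: fixture writers live together)

GROUPS = ("resistant", "susceptible", "control")


@dataclass
class SimulationConfig:
    """Panel shape and background-site law.

    Defaults mirror a field study panel: 23 resistant, 10 susceptible and
    9 control mosquitoes (all diploid females). ``freq_law`` is
    ``("uniform", lo, hi)`` or ``("beta", a, b)`` on [0, 1] for the base
    alternate-allele frequency of background sites.
    """

    n_resistant: int = 23
    n_susceptible: int = 10
    n_control: int = 9
    chromosomes: tuple[tuple[str, int], ...] = (("2L", 1_000_000),)
    n_sites: int | dict = 1000  # scalar, or {chromosome: count}
    freq_law: tuple = ("uniform", 0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_resistant, self.n_susceptible, self.n_control) < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.freq_law[0] not in ("uniform", "beta"):
            raise ValueError(f"unknown frequency law {self.freq_law[0]!r}")
        for name, length in self.chromosomes:
            if length < self.sites_for(name):
                raise ValueError(f"chromosome {name} shorter than n_sites")

    def sites_for(self, chrom: str) -> int:
        if isinstance(self.n_sites, dict):
            return int(self.n_sites[chrom])
        return int(self.n_sites)

    @property
    def n_samples(self) -> int:
        return self.n_resistant + self.n_susceptible + self.n_control

    def group_sizes(self) -> dict[str, int]:
        return {"resistant": self.n_resistant, "susceptible": self.n_susceptible,
                "control": self.n_control}


@dataclass
class PlantedFeature:
    """A ground-truth feature to plant into the panel.

    kind: ``candidate_snp`` (single site, per-group alt frequency),
    ``diff_window`` (interval, per-group frequency at every site inside),
    ``sweep`` (interval; one core haplotype carried by a
    Bernoulli(core_freq) subset of haplotypes), or ``cnv`` (breakpoint
    pair + carrier samples; affects reads, not genotypes).

    Positions are 1-based; intervals half-open [start, end).
    With ``exact_counts`` the planted per-group alternate-allele count is
    ``round(freq * 2 * group size)`` exactly (carriers still chosen at
    random) instead of Bernoulli-sampled.
    """

    kind: str
    chrom: str
    pos: int | None = None
    start: int | None = None
    end: int | None = None
    freq_by_group: dict[str, float] = field(default_factory=dict)
    core_freq: float = 0.0
    exact_counts: bool = False
    label: str = ""
    # cnv-specific
    name: str = ""
    carriers: tuple[str, ...] = ()
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("candidate_snp", "sweep", "diff_window", "cnv"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        for f in self.freq_by_group.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("planted frequencies must be in [0, 1]")
        if not 0.0 <= self.core_freq <= 1.0:
            raise ValueError("core_freq must be in [0, 1]")
        if self.kind in ("sweep", "diff_window", "cnv"):
            if self.start is None or self.end is None or self.start >= self.end:
                raise ValueError(f"{self.kind} needs an interval with start < end")
        if self.kind == "candidate_snp" and self.pos is None:
            raise ValueError("candidate_snp needs a position")


@dataclass
class SyntheticTruth:
    """Realized ground truth: what actually went into the genotype arrays."""

    feature_counts: pd.DataFrame      # feature label/kind/site x group: realized alt counts
    sweep_members: dict[str, np.ndarray]  # feature label -> haplotype indices carrying the core
    cnv_carriers: dict[str, tuple[str, ...]]

    def to_tsv(self, path) -> None:
        self.feature_counts.to_csv(path, sep="\t", index=False)


def _check_bounds(features: list[PlantedFeature],
                  chrom_lengths: dict[str, int]) -> None:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.chrom not in chrom_lengths and f.kind != "cnv":
            raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
        length = chrom_lengths.get(f.chrom, np.inf)
        if f.kind == "candidate_snp":
            if not 1 <= f.pos <= length:
                raise ValueError(f"candidate_snp position {f.pos} outside {f.chrom}")
        elif f.kind in ("sweep", "diff_window"):
            if f.start < 1 or f.end > length + 1:
                raise ValueError(
                    f"{f.kind} interval [{f.start},{f.end}) outside {f.chrom}")
            for s, e in intervals.get(f.chrom, []):
                if f.start < e and s < f.end:
                    raise ValueError("sweep/diff_window intervals overlap")
            intervals.setdefault(f.chrom, []).append((f.start, f.end))


def _draw_base_freqs(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind, a, b = law
    if kind == "uniform":
        return rng.uniform(a, b, size=n)
    return rng.beta(a, b, size=n)


def _plant_group_alleles(rng, haps, site_idx, hap_cols, freq, exact):
    """Set alt alleles at one site for one group's haplotype columns."""
    n = hap_cols.size
    if exact:
        k = int(round(freq * n))
        carriers = rng.choice(n, size=k, replace=False)
        alleles = np.zeros(n, dtype=np.int8)
        alleles[carriers] = 1
    else:
        alleles = (rng.random(n) < freq).astype(np.int8)
    haps[site_idx, hap_cols] = alleles


def generate_panel(config: SimulationConfig,
                   features: list[PlantedFeature] | None = None
                   ) -> tuple[PhenotypedPanel, GenotypeMatrix, SyntheticTruth]:
    """Simulate the phenotyped panel with all requested features planted.

    Determinism: the same config (including seed) and feature list yield
    byte-identical outputs.
    """
    config.validate()
    features = list(features or [])
    chrom_lengths = {name: length for name, length in config.chromosomes}
    _check_bounds(features, chrom_lengths)
    rng = np.random.default_rng(config.seed)

    panel = PhenotypedPanel.from_groups(
        [f"R{i + 1:02d}" for i in range(config.n_resistant)],
        [f"S{i + 1:02d}" for i in range(config.n_susceptible)],
        [f"C{i + 1:02d}" for i in range(config.n_control)])
    n_hap = 2 * config.n_samples

    site_frames, hap_blocks = [], []
    for chrom, length in config.chromosomes:
        n_sites = config.sites_for(chrom)
        cand_pos = sorted({f.pos for f in features
                           if f.kind == "candidate_snp" and f.chrom == chrom})
        n_background = n_sites - len(cand_pos)
        pool = rng.choice(length, size=min(length, n_sites * 2),
                          replace=False) + 1
        pool = [p for p in pool if p not in set(cand_pos)][:n_background]
        positions = np.array(sorted(set(pool) | set(cand_pos)), dtype=np.int64)
        freqs = _draw_base_freqs(rng, config.freq_law, positions.size)
        haps = (rng.random((positions.size, n_hap)) < freqs[:, None]).astype(np.int8)

        ref = rng.choice(list("ACGT"), size=positions.size)
        alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
        site_frames.append(pd.DataFrame({"chrom": chrom, "pos": positions,
                                         "ref": ref, "alt": alt}))
        hap_blocks.append(haps)

    sites = pd.concat(site_frames, ignore_index=True)
    haps = np.concatenate(hap_blocks, axis=0)

    group_hap_cols = {g: panel.haplotype_indices(g) for g in PHENOTYPES}
    truth_rows: list[dict] = []
    sweep_members: dict[str, np.ndarray] = {}
    cnv_carriers: dict[str, tuple[str, ...]] = {}

    def site_rows_in(f: PlantedFeature) -> np.ndarray:
        mask = ((sites["chrom"] == f.chrom).to_numpy()
                & (sites["pos"].to_numpy() >= f.start)
                & (sites["pos"].to_numpy() < f.end))
        return np.flatnonzero(mask)

    for k, f in enumerate(features):
        label = f.label or f"{f.kind}_{k}"
        if f.kind == "candidate_snp":
            idx = int(np.flatnonzero(((sites["chrom"] == f.chrom)
                                      & (sites["pos"] == f.pos)).to_numpy())[0])
            for g in GROUPS:
                freq = f.freq_by_group.get(g, 0.0)
                _plant_group_alleles(rng, haps, idx, group_hap_cols[g],
                                     freq, f.exact_counts)
            for g in GROUPS:
                cols = group_hap_cols[g]
                truth_rows.append({
                    "label": label, "kind": f.kind, "chrom": f.chrom,
                    "pos": f.pos, "group": g,
                    "alt_count": int(haps[idx, cols].sum()),
                    "n_alleles": int(cols.size)})
        elif f.kind == "diff_window":
            rows = site_rows_in(f)
            if rows.size == 0:
                raise ValueError(f"diff_window {label} contains no sites")
            for idx in rows:
                for g in GROUPS:
                    freq = f.freq_by_group.get(g, 0.0)
                    _plant_group_alleles(rng, haps, idx, group_hap_cols[g],
                                         freq, f.exact_counts)
            for g in GROUPS:
                cols = group_hap_cols[g]
                truth_rows.append({
                    "label": label, "kind": f.kind, "chrom": f.chrom,
                    "pos": f.start, "group": g,
                    "alt_count": int(haps[np.ix_(rows, cols)].sum()),
                    "n_alleles": int(cols.size * rows.size)})
        elif f.kind == "sweep":
            rows = site_rows_in(f)
            if rows.size == 0:
                raise ValueError(f"sweep {label} contains no sites")
            core = (rng.random(rows.size) < 0.5).astype(np.int8)
            members = np.flatnonzero(rng.random(n_hap) < f.core_freq)
            haps[np.ix_(rows, members)] = core[:, None]
            sweep_members[label] = members
            truth_rows.append({
                "label": label, "kind": f.kind, "chrom": f.chrom,
                "pos": f.start, "group": "all",
                "alt_count": int(members.size), "n_alleles": n_hap})
        elif f.kind == "cnv":
            cnv_carriers[f.name or label] = tuple(f.carriers)

    genotypes = haps.reshape(len(sites), config.n_samples, 2)
    if config.missing_rate > 0:
        miss = rng.random((len(sites), config.n_samples)) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[miss] = MISSING

    matrix = GenotypeMatrix(genotypes, sites)
    truth = SyntheticTruth(
        feature_counts=pd.DataFrame(
            truth_rows, columns=["label", "kind", "chrom", "pos", "group",
                                 "alt_count", "n_alleles"]),
        sweep_members=sweep_members, cnv_carriers=cnv_carriers)
    return panel, matrix, truth


def generate_breakpoint_reads(cnv: PlantedFeature, depth: int,
                              clip_fraction: float, read_len: int, seed: int,
                              path, mapq: int | tuple[int, ...] = 60,
                              chrom_length: int | None = None) -> int:
    """Write SAM reads around a CNV's two breakpoints; returns read count.

    A Bernoulli(``clip_fraction``) subset of the reads spanning each
    breakpoint carries a CIGAR soft-clip whose clipped boundary equals the
    breakpoint: left-side clips at the start breakpoint (first aligned
    base = start) and right-side clips at the end breakpoint (last
    aligned base = end). The remainder are fully matched. MAPQ is either
    a constant or drawn uniformly from a tuple of values.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= clip_fraction <= 1.0:
        raise ValueError("clip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    length = chrom_length or (cnv.end + 10 * read_len)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": cnv.chrom, "LN": int(length)}]}

    reads = []  # (pos0, cigar, mapq, name)
    for side, bp in (("left", cnv.start), ("right", cnv.end)):
        clipped = rng.random(depth) < clip_fraction
        mapqs = (np.full(depth, mapq) if np.isscalar(mapq)
                 else rng.choice(np.asarray(mapq), size=depth))
        for r in range(depth):
            name = f"{cnv.name or 'cnv'}_{side}_{r}"
            clip_len = int(rng.integers(5, max(6, read_len // 2)))
            if clipped[r]:
                if side == "left":
                    pos0, cigar = bp - 1, f"{clip_len}S{read_len - clip_len}M"
                else:
                    m = read_len - clip_len
                    pos0, cigar = bp - m, f"{m}M{clip_len}S"
            else:
                offset = int(rng.integers(0, read_len))
                pos0 = max(0, bp - 1 - offset)
                cigar = f"{read_len}M"
            reads.append((pos0, cigar, int(mapqs[r]), name))

    reads.sort(key=lambda t: t[0])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pos0, cigar, mq, name in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = mq
            a.cigarstring = cigar
            a.query_sequence = "".join(rng.choice(list("ACGT"), size=read_len))
            a.flag = 0
            out.write(a)
    return len(reads)


def generate_bioassay_counts(true_mortality: float, control_mortality: float,
                             n_treated: int, n_control: int, seed: int,
                             n_replicates: int = 5, treatment: str = "deltamethrin_0.05",
                             ) -> dict[str, list[TubeTestRecord]]:
    """Binomial tube-test replicate counts at the stated mortality rates."""
    for p in (true_mortality, control_mortality):
        if not 0.0 <= p <= 100.0:
            raise ValueError("mortality percentages must be in [0, 100]")
    rng = np.random.default_rng(seed)

    def split(total: int, k: int) -> list[int]:
        base, extra = divmod(total, k)
        return [base + (1 if i < extra else 0) for i in range(k)]

    out: dict[str, list[TubeTestRecord]] = {treatment: [], "control": []}
    for label, total, rate in ((treatment, n_treated, true_mortality),
                               ("control", n_control, control_mortality)):
        for rep, n in enumerate(split(total, n_replicates), start=1):
            dead = int(rng.binomial(n, rate / 100.0))
            out[label].append(TubeTestRecord(label, rep, n, dead))
    return out
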