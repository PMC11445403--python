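"""Site, genotype, missingness and sample-coverage filters for a called VCF.

The thresholds follow GATK hard-filtering practice for SNPs as applied in
*Anopheles* resequencing workflows: site-level annotations must satisfy
QD > 5, QUAL > 30, SOR < 3, FS < 60, MQ > 40, MQRankSum > -12.5 and
ReadPosRankSum > -8 (all strict); genotypes are masked to missing unless
DP > 5 and GQ > 20; sites with > 20% missing genotypes are dropped; and
samples qualify only if at least 40% of the genome has > 10-fold coverage
(a fraction computed upstream and supplied as a table).

Absent INFO annotations pass their rule by default (the GATK convention —
rank-sum annotations are undefined for sites without both alleles in
reads); ``strict_missing_info`` flips that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING
from .vcfio import VcfData


@dataclass(frozen=True)
class FilterConfig:
    qd_min: float = 5.0
    qual_min: float = 30.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    dp_min: int = 5
    gq_min: int = 20
    max_missing: float = 0.20
    sample_cov_fraction: float = 0.40
    sample_cov_depth: int = 10
    strict_missing_info: bool = False


#: (annotation, config attr, comparison) — value must be strictly beyond threshold.
_SITE_RULES = (
    ("QD", "qd_min", "gt"),
    ("QUAL", "qual_min", "gt"),
    ("SOR", "sor_max", "lt"),
    ("FS", "fs_max", "lt"),
    ("MQ", "mq_min", "gt"),
    ("MQRankSum", "mqranksum_min", "gt"),
    ("ReadPosRankSum", "readpos_min", "gt"),
)


def site_filter(annotations: pd.Series | dict,
                config: FilterConfig = FilterConfig()) -> tuple[bool, list[str]]:
    """Evaluate the site-level hard filters on one record's annotations.

    Returns ``(passed, failed_rules)``; every rule uses a strict
    inequality, so a value exactly at its threshold fails.
    """
    failed = []
    for name, attr, op in _SITE_RULES:
        value = annotations.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if config.strict_missing_info:
                failed.append(name)
            continue
        threshold = getattr(config, attr)
        ok = value > threshold if op == "gt" else value < threshold
        if not ok:
            failed.append(name)
    return (not failed), failed


def site_filter_table(data: VcfData,
                      config: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Per-site filter ledger: chrom, pos, pass, comma-joined failed rules."""
    rows = []
    for i in range(data.matrix.n_sites):
        passed, failed = site_filter(data.site_annotations.iloc[i], config)
        rows.append({"chrom": data.matrix.sites["chrom"].iloc[i],
                     "pos": int(data.matrix.sites["pos"].iloc[i]),
                     "pass": passed, "failed_rules": ",".join(failed)})
    return pd.DataFrame(rows)


def genotype_mask(data: VcfData,
                  config: FilterConfig = FilterConfig()) -> VcfData:
    """Mask genotypes to missing where DP <= dp_min or GQ <= gq_min."""
    bad = (data.depth <= config.dp_min) | (data.genotype_quality <= config.gq_min)
    genotypes = data.matrix.genotypes.copy()
    genotypes[bad] = MISSING
    matrix = type(data.matrix)(genotypes, data.matrix.sites)
    return VcfData(matrix=matrix, sample_ids=data.sample_ids,
                   site_annotations=data.site_annotations,
                   depth=data.depth, genotype_quality=data.genotype_quality)


def missing_fraction(matrix) -> np.ndarray:
    """Per-site fraction of samples with any missing allele."""
    return (matrix.genotypes == MISSING).any(axis=2).mean(axis=1)


def missingness_filter(data: VcfData,
                       config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Boolean keep-mask over sites: missing-genotype fraction <= max_missing."""
    return missing_fraction(data.matrix) <= config.max_missing


def sample_coverage_filter(covered_fraction: pd.Series | dict,
                           config: FilterConfig = FilterConfig()) -> list[str]:
    """Samples retained: fraction of genome at > sample_cov_depth coverage >= 40%.

    ``covered_fraction`` maps sample id to that fraction (computed from
    alignments upstream of this package).
    """
    items = covered_fraction.items() if hasattr(covered_fraction, "items") else covered_fraction
    kept = []
    for sample, frac in items:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"coverage fraction {frac} for {sample} outside [0, 1]")
        if frac >= config.sample_cov_fraction:
            kept.append(sample)
    return kept


def apply_filters(data: VcfData, config: FilterConfig = FilterConfig()
                  ) -> tuple[VcfData, pd.DataFrame]:
    """Full QC: site filters, genotype masking, then missingness.

    The missingness filter must see masked genotypes, so genotype_mask
    always runs first of the two (site filters commute with both).
    Returns the filtered data and the per-site ledger (with a
    ``kept`` column covering all three stages).
    """
    ledger = site_filter_table(data, config)
    masked = genotype_mask(data, config)
    keep_missing = missingness_filter(masked, config)
    keep = ledger["pass"].to_numpy() & keep_missing
    ledger["missing_fraction"] = missing_fraction(masked.matrix)
    ledger["kept"] = keep
    idx = np.flatnonzero(keep)
    filtered = VcfData(matrix=masked.matrix.subset_sites(idx),
                       sample_ids=data.sample_ids,
                       site_annotations=data.site_annotations.iloc[idx].reset_index(drop=True),
                       depth=data.depth[idx], genotype_quality=data.genotype_quality[idx])
    return filtered, ledger
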