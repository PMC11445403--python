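"""Candidate and novel non-synonymous SNP tabulation by phenotype group.

Per SNP and group: alternate-allele counts over non-missing alleles,
frequencies as percentages, het/hom-alt genotype counts, flagging of SNPs
common in the pooled sample (> 5%), and allele-count odds ratios
(resistant vs susceptible, Haldane-Anscombe corrected, Woolf 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypeMatrix, PhenotypedPanel

GROUPS = ("resistant", "susceptible", "control")
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CandidateSnp:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str  # amino-acid change, e.g. L995F


def read_candidates_tsv(path) -> list[CandidateSnp]:
    frame = pd.read_csv(path, sep="\t")
    return [CandidateSnp(str(r.gene), str(r.chrom), int(r.pos),
                         str(r.ref), str(r.alt), str(r.label))
            for r in frame.itertuples(index=False)]


def _group_genotypes(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                     site: int, group: str) -> np.ndarray:
    return matrix.genotypes[site, panel.group_indices(group), :]


def allele_frequency_by_group(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                              chrom: str, pos: int) -> pd.DataFrame:
    """Alt-allele count, called-allele total and percent frequency per group.

    Missing alleles leave the denominator; a group with no called alleles
    gets NaN frequency (flagged by ``defined`` = False).
    """
    site = matrix.site_index(chrom, pos)
    rows = []
    for group in GROUPS:
        g = _group_genotypes(matrix, panel, site, group)
        called = g != MISSING
        total = int(called.sum())
        alt = int((g[called] == 1).sum())
        freq = 100.0 * alt / total if total else np.nan
        rows.append({"group": group, "alt_count": alt, "total_alleles": total,
                     "freq_pct": freq, "defined": total > 0})
    return pd.DataFrame(rows)


def genotype_counts_by_group(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                             chrom: str, pos: int) -> pd.DataFrame:
    """Heterozygous and homozygous-alternate diplotype counts per group."""
    site = matrix.site_index(chrom, pos)
    rows = []
    for group in GROUPS:
        g = _group_genotypes(matrix, panel, site, group)
        complete = (g != MISSING).all(axis=1)
        dosage = g[complete].sum(axis=1)
        rows.append({"group": group,
                     "het": int((dosage == 1).sum()),
                     "hom_alt": int((dosage == 2).sum()),
                     "n_called": int(complete.sum())})
    return pd.DataFrame(rows)


def screen_table(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                 candidates: list[CandidateSnp]) -> pd.DataFrame:
    """Wide per-SNP table over all groups; SNPs absent from the matrix are
    reported with ``found`` = False (a screen list routinely exceeds the
    variants actually segregating in a panel)."""
    rows = []
    for snp in candidates:
        row = {"gene": snp.gene, "chrom": snp.chrom, "pos": snp.pos,
               "ref": snp.ref, "alt": snp.alt, "label": snp.label}
        try:
            matrix.site_index(snp.chrom, snp.pos)
            row["found"] = True
        except KeyError:
            row["found"] = False
            rows.append(row)
            continue
        freqs = allele_frequency_by_group(matrix, panel, snp.chrom, snp.pos)
        gcounts = genotype_counts_by_group(matrix, panel, snp.chrom, snp.pos)
        for _, fr in freqs.iterrows():
            g = fr["group"]
            row[f"{g}_alt_count"] = fr["alt_count"]
            row[f"{g}_total_alleles"] = fr["total_alleles"]
            row[f"{g}_freq_pct"] = (round(fr["freq_pct"], 1)
                                    if np.isfinite(fr["freq_pct"]) else np.nan)
        for _, gc in gcounts.iterrows():
            row[f"{gc['group']}_het"] = gc["het"]
            row[f"{gc['group']}_hom_alt"] = gc["hom_alt"]
        rows.append(row)
    return pd.DataFrame(rows)


def highlight_common(table: pd.DataFrame, threshold_pct: float = 5.0) -> pd.Series:
    """Flag SNPs whose pooled-sample allele frequency exceeds the threshold.

    Pooled frequency is computed over all groups' called alleles; the
    comparison is strict ('over 5%'), so exactly 5% is not flagged.
    """
    count_cols = [f"{g}_alt_count" for g in GROUPS]
    total_cols = [f"{g}_total_alleles" for g in GROUPS]
    alt = table.reindex(columns=count_cols).fillna(0).sum(axis=1)
    tot = table.reindex(columns=total_cols).fillna(0).sum(axis=1)
    pooled = np.where(tot > 0, 100.0 * alt / np.where(tot > 0, tot, 1), 0.0)
    return pd.Series(pooled > threshold_pct, index=table.index, name="common")


@dataclass(frozen=True)
class OddsRatioResult:
    table: tuple[int, int, int, int]  # a, b, c, d (alt-R, ref-R, alt-S, ref-S)
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool
    significant: bool


def odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Allele-by-phenotype odds ratio with Woolf 95% confidence interval.

    Cells: a = alt alleles in resistant, b = ref in resistant, c = alt in
    susceptible, d = ref in susceptible. When any cell is zero the
    Haldane-Anscombe correction adds 0.5 to every cell. 'Significant'
    means the CI excludes 1.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin: odds ratio undefined")
    corrected = any(x == 0 for x in cells)
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if corrected else cells)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(or_) - Z_95 * se))
    ci_high = float(np.exp(np.log(or_) + Z_95 * se))
    return OddsRatioResult(cells, float(or_), ci_low, ci_high, corrected,
                           significant=not (ci_low <= 1.0 <= ci_high))


def odds_ratio_for_snp(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                       chrom: str, pos: int) -> OddsRatioResult:
    """Resistant-vs-susceptible allele-count OR for one SNP (controls excluded:
    their phenotype is unknown)."""
    freqs = allele_frequency_by_group(matrix, panel, chrom, pos).set_index("group")
    a = int(freqs.loc["resistant", "alt_count"])
    b = int(freqs.loc["resistant", "total_alleles"]) - a
    c = int(freqs.loc["susceptible", "alt_count"])
    d = int(freqs.loc["susceptible", "total_alleles"]) - c
    return odds_ratio(a, b, c, d)
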