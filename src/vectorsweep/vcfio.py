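"""VCF 4.2 input/output for phased biallelic panels.

Writing goes through :mod:`pysam` (header built programmatically, phased
GT, the GATK-style INFO annotations the quality filters consume); reading
goes through :mod:`cyvcf2`. The INFO/FORMAT field set mirrors what a
GATK joint-genotyping workflow emits: QD, SOR, FS, MQ, MQRankSum,
ReadPosRankSum per site and DP, GQ per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .panel import MISSING, GenotypeMatrix, PhenotypedPanel

INFO_FIELDS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass
class QcFieldModel:
    """Site/genotype QC annotations to stamp on a written VCF.

    Scalar defaults apply everywhere; ``site_overrides`` maps a site index
    to ``{field: value}`` replacements (``QUAL`` and any INFO field), and
    ``genotype_overrides`` maps ``(site_index, sample_index)`` to
    ``{"DP": v, "GQ": v}``. Setting an INFO override to ``None`` omits the
    annotation at that site.
    """

    qual: float = 100.0
    qd: float = 20.0
    sor: float = 1.0
    fs: float = 10.0
    mq: float = 60.0
    mq_rank_sum: float = 0.0
    read_pos_rank_sum: float = 0.0
    dp: int = 30
    gq: int = 99
    site_overrides: dict[int, dict] = field(default_factory=dict)
    genotype_overrides: dict[tuple[int, int], dict] = field(default_factory=dict)

    def site_values(self, i: int) -> dict:
        vals = {"QUAL": self.qual, "QD": self.qd, "SOR": self.sor, "FS": self.fs,
                "MQ": self.mq, "MQRankSum": self.mq_rank_sum,
                "ReadPosRankSum": self.read_pos_rank_sum}
        vals.update(self.site_overrides.get(i, {}))
        return vals

    def genotype_values(self, i: int, j: int) -> dict:
        vals = {"DP": self.dp, "GQ": self.gq}
        vals.update(self.genotype_overrides.get((i, j), {}))
        return vals


def _build_header(sample_ids: list[str],
                  contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={int(length)}>")
    descriptions = {
        "QD": "Variant Confidence/Quality by Depth",
        "SOR": "Symmetric Odds Ratio of 2x2 contingency table to detect strand bias",
        "FS": "Phred-scaled p-value using Fisher's exact test to detect strand bias",
        "MQ": "RMS Mapping Quality",
        "MQRankSum": "Z-score From Wilcoxon rank sum test of Alt vs. Ref read mapping qualities",
        "ReadPosRankSum": "Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias",
    }
    for name in INFO_FIELDS:
        header.add_meta("INFO", items=[("ID", name), ("Number", "1"),
                                       ("Type", "Float"),
                                       ("Description", descriptions[name])])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Read depth")])
    header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Genotype quality")])
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_vcf(panel: PhenotypedPanel, matrix: GenotypeMatrix,
              qc_model: QcFieldModel, path,
              contigs: dict[str, int] | None = None) -> None:
    """Write a sorted, phased VCF 4.2 file.

    ``contigs`` maps chromosome name to length; defaults to the maximum
    site position per chromosome. Sites must already be sorted (enforced
    by :class:`GenotypeMatrix`).
    """
    if matrix.n_samples != panel.n_samples:
        raise ValueError("panel and matrix sample counts differ")
    if contigs is None:
        contigs = {str(c): int(sub["pos"].max())
                   for c, sub in matrix.sites.groupby("chrom", sort=False)}
    header = _build_header(panel.sample_ids, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(matrix.n_sites):
            site = matrix.sites.iloc[i]
            vals = qc_model.site_values(i)
            rec = out.new_record(
                contig=str(site["chrom"]), start=int(site["pos"]) - 1,
                alleles=(str(site["ref"]), str(site["alt"])),
                qual=float(vals["QUAL"]))
            rec.id = "."
            for name in INFO_FIELDS:
                if vals[name] is not None:
                    rec.info[name] = float(vals[name])
            for j in range(matrix.n_samples):
                a, b = matrix.genotypes[i, j]
                gt = (None if a == MISSING else int(a),
                      None if b == MISSING else int(b))
                sample = rec.samples[j]
                sample["GT"] = gt
                sample.phased = True
                gvals = qc_model.genotype_values(i, j)
                sample["DP"] = int(gvals["DP"])
                sample["GQ"] = int(gvals["GQ"])
            out.write(rec)


@dataclass
class VcfData:
    """Parsed VCF: genotypes plus the annotations the QC filters consume."""

    matrix: GenotypeMatrix
    sample_ids: list[str]
    site_annotations: pd.DataFrame  # QUAL + INFO fields, NaN where absent
    depth: np.ndarray               # (n_sites, n_samples) int, -1 where absent
    genotype_quality: np.ndarray    # same shape


def read_vcf(path) -> VcfData:
    """Read a biallelic SNP VCF into arrays (multiallelic records rejected)."""
    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    genotypes, rows, ann_rows, dps, gqs = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; split upstream")
        gt = np.asarray(var.genotype.array())[:, :2].astype(np.int8)
        genotypes.append(gt)
        rows.append({"chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
        ann = {"QUAL": var.QUAL if var.QUAL is not None else np.nan}
        for name in INFO_FIELDS:
            value = var.INFO.get(name)
            ann[name] = np.nan if value is None else float(value)
        ann_rows.append(ann)
        dp = var.format("DP")
        gq = var.format("GQ")
        n = len(sample_ids)
        dps.append(np.full(n, -1) if dp is None else dp.reshape(-1).astype(int))
        gqs.append(np.full(n, -1) if gq is None else gq.reshape(-1).astype(int))
    vcf.close()
    if not genotypes:
        raise ValueError(f"no records in {path}")
    matrix = GenotypeMatrix(np.stack(genotypes), pd.DataFrame(rows))
    return VcfData(matrix=matrix, sample_ids=sample_ids,
                   site_annotations=pd.DataFrame(ann_rows),
                   depth=np.stack(dps), genotype_quality=np.stack(gqs))
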