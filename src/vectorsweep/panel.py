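"""Core in-memory containers: phenotyped sample panels and phased genotype matrices.

Coordinates are 1-based (VCF convention); intervals are half-open
``[start, end)`` unless a function documents otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing allele code in genotype arrays.
MISSING = -1

#: Recognised phenotype labels, in canonical order.
PHENOTYPES = ("resistant", "susceptible", "control")


@dataclass
class PhenotypedPanel:
    """Ordered set of samples with phenotype labels.

    Sample *i* owns haplotype columns ``2*i`` and ``2*i + 1`` of any
    haplotype-major array derived from the matching
    :class:`GenotypeMatrix`.
    """

    samples: pd.DataFrame  # columns: sample_id, phenotype

    def __post_init__(self) -> None:
        required = {"sample_id", "phenotype"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"panel frame needs columns {sorted(required)}")
        bad = set(self.samples["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in panel")
        self.samples = self.samples.reset_index(drop=True)

    @classmethod
    def from_groups(cls, resistant: list[str], susceptible: list[str],
                    control: list[str] | None = None) -> "PhenotypedPanel":
        control = control or []
        frame = pd.DataFrame({
            "sample_id": list(resistant) + list(susceptible) + list(control),
            "phenotype": (["resistant"] * len(resistant)
                          + ["susceptible"] * len(susceptible)
                          + ["control"] * len(control)),
        })
        return cls(frame)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypedPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_indices(self, phenotype: str) -> np.ndarray:
        """Sample indices (matrix column order) for one phenotype group."""
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return np.flatnonzero((self.samples["phenotype"] == phenotype).to_numpy())

    def haplotype_indices(self, phenotype: str) -> np.ndarray:
        """Haplotype column indices (2 per diploid sample) for one group."""
        idx = self.group_indices(phenotype)
        return np.stack([2 * idx, 2 * idx + 1], axis=1).reshape(-1)

    def phenotype_of_haplotype(self, hap_index: int) -> str:
        return str(self.samples["phenotype"].iloc[hap_index // 2])


@dataclass
class GenotypeMatrix:
    """Biallelic phased genotypes: ``(n_sites, n_samples, 2)`` allele indices.

    Allele values are 0 (ref), 1 (alt) or :data:`MISSING`. Site metadata
    lives in ``sites`` (columns chrom, pos, ref, alt), sorted by
    (chrom, pos) with strictly increasing positions per chromosome.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (sites, samples, 2)")
        if len(self.sites) != g.shape[0]:
            raise ValueError("site table length does not match genotype array")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.genotypes = g
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def haplotypes(self) -> np.ndarray:
        """View as ``(n_sites, 2 * n_samples)`` haplotype-major array."""
        return self.genotypes.reshape(self.n_sites, 2 * self.n_samples)

    def dosages(self) -> np.ndarray:
        """Per-sample alt-allele dosage, float with NaN where any allele missing."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        return g.sum(axis=2)

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.sites["chrom"] == chrom).to_numpy()
            & (self.sites["pos"] == pos).to_numpy()
        )
        if hit.size == 0:
            raise KeyError(f"site {chrom}:{pos} not in matrix")
        return int(hit[0])

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.genotypes[idx],
                              self.sites.iloc[idx].reset_index(drop=True))
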