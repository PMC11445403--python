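"""Rogers-Huff composite linkage disequilibrium from genotype dosages.

The Rogers-Huff estimator computes r directly from diploid alt-allele
dosages (0/1/2) as the Pearson product-moment correlation with
population (biased) variance denominators, so it needs no phasing.
Missing dosages are handled by pairwise-complete deletion. Sites with
zero dosage variance among the complete pairs have undefined r, reported
as NaN — never coerced to 0, which matters for small panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix


def rogers_huff_r(x, y) -> tuple[float, int]:
    """(r, n_complete) for two dosage vectors; NaN r when undefined.

    r = cov(x, y) / sqrt(var(x) var(y)) over pairwise-complete samples,
    with population-moment denominators.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    complete = ~(np.isnan(x) | np.isnan(y))
    n = int(complete.sum())
    if n < 2:
        return float("nan"), n
    xc, yc = x[complete], y[complete]
    vx = np.mean(xc * xc) - np.mean(xc) ** 2
    vy = np.mean(yc * yc) - np.mean(yc) ** 2
    if vx <= 0 or vy <= 0:
        return float("nan"), n
    cov = np.mean(xc * yc) - np.mean(xc) * np.mean(yc)
    return float(cov / np.sqrt(vx * vy)), n


@dataclass
class LdMatrix:
    labels: list[str]
    r: np.ndarray        # signed r, NaN where undefined
    r2: np.ndarray       # r squared
    n_complete: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({"site_a": self.labels[i], "site_b": self.labels[j],
                             "r": self.r[i, j], "r2": self.r2[i, j],
                             "n": int(self.n_complete[i, j])})
        return pd.DataFrame(rows)

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.labels, columns=self.labels)


def pairwise_r2(matrix: GenotypeMatrix, sites: list[tuple[str, int]],
                labels: list[str] | None = None) -> LdMatrix:
    """Symmetric r² matrix over all unordered pairs of the named sites.

    The diagonal is 1 where the site is polymorphic and NaN otherwise
    (monomorphic sites have undefined correlation with anything,
    including themselves).
    """
    idx = [matrix.site_index(c, p) for c, p in sites]
    labels = labels or [f"{c}:{p}" for c, p in sites]
    dosages = matrix.dosages()[idx]
    k = len(idx)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            rij, nij = rogers_huff_r(dosages[i], dosages[j])
            r[i, j] = r[j, i] = rij
            n[i, j] = n[j, i] = nij
    return LdMatrix(labels=labels, r=r, r2=r * r, n_complete=n)
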