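"""Windowed differentiation and selection scans on phased panels.

Three complementary scans:

* **Windowed FST** between resistant and susceptible groups in
  non-overlapping 1 kb windows, using the Hudson two-population estimator
  with the ratio-of-sums form: per-site numerators and denominators are
  summed within a window before dividing, which is robust to low-diversity
  sites. Negative window values are retained (the estimator is unbiased
  around 0 under no differentiation).
* **Permutation significance** for FST peaks: phenotype labels are
  permuted genome-wide (group sizes preserved) and FST recomputed per
  window; a window is flagged when its observed value exceeds the 99th
  centile of its own permuted distribution AND exceeds a noise floor of
  three times the genome-wide permuted centile. The second criterion
  suppresses windows whose permuted distribution is inflated by local
  haplotype structure rather than phenotype.
* **Garud's H statistics** (H1, H12, H123, H2/H1) in windows of 1000
  consecutive SNPs, scanned per phenotype group with repeated haplotype
  subsampling to equalise group sizes; windows with mean H12 above 0.2
  mark candidate selective sweeps.

Haplotype clustering (single linkage, Hamming distance) identifies the
high-frequency haplotypes inside windows of interest, and a Fisher exact
test asks whether cluster membership tracks phenotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact, false_discovery_control

from .panel import MISSING, GenotypeMatrix, PhenotypedPanel

SWEEP_THRESHOLD = 0.2
FST_WINDOW_BP = 1000
H12_WINDOW_SNPS = 1000


# ---------------------------------------------------------------------------
# Hudson FST

def hudson_numden(ac1, n1, ac2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson FST numerator and denominator from allele counts.

    ``ac`` are alt-allele counts and ``n`` called-allele totals per group.
    Sites with fewer than 2 called alleles in either group get NaN.
    """
    ac1 = np.asarray(ac1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = ac1 / n1, ac2 / n2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def _group_allele_counts(haps: np.ndarray, cols: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    sub = haps[:, cols]
    called = sub != MISSING
    return (sub == 1).sum(axis=1), called.sum(axis=1)


def _window_ids(sites: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Assign each site a (chrom, window start) key; windows tile from 1."""
    start = ((sites["pos"] - 1) // window_bp) * window_bp + 1
    return pd.DataFrame({"chrom": sites["chrom"], "win_start": start})


def windowed_fst(matrix: GenotypeMatrix, group_a: np.ndarray, group_b: np.ndarray,
                 window_bp: int = FST_WINDOW_BP) -> pd.DataFrame:
    """Hudson FST per non-overlapping window (ratio of per-site sums).

    ``group_a``/``group_b`` are haplotype column indices. Windows without
    usable variants are omitted.
    """
    if group_a.size < 4 or group_b.size < 4:
        raise ValueError("each group needs at least 2 diploid samples")
    haps = matrix.haplotypes()
    ac1, n1 = _group_allele_counts(haps, group_a)
    ac2, n2 = _group_allele_counts(haps, group_b)
    num, den = hudson_numden(ac1, n1, ac2, n2)
    keys = _window_ids(matrix.sites, window_bp)
    frame = pd.DataFrame({"chrom": keys["chrom"], "win_start": keys["win_start"],
                          "num": num, "den": den}).dropna()
    grouped = frame.groupby(["chrom", "win_start"], sort=True).agg(
        num=("num", "sum"), den=("den", "sum"), n_variants=("num", "size"))
    grouped = grouped[grouped["den"] > 0]
    out = grouped.reset_index()
    out["fst"] = out["num"] / out["den"]
    out["win_end"] = out["win_start"] + window_bp
    return out[["chrom", "win_start", "win_end", "n_variants", "fst"]]


def fst_permutation_significance(matrix: GenotypeMatrix, panel: PhenotypedPanel,
                                 n_perm: int = 200, centile: float = 99.0,
                                 noise_multiplier: float = 3.0, seed: int = 0,
                                 window_bp: int = FST_WINDOW_BP,
                                 per_window_floor: bool = False) -> pd.DataFrame:
    """Flag FST windows against a phenotype-permutation null.

    Labels are permuted once per iteration genome-wide over the resistant
    and susceptible samples (controls excluded), preserving group sizes,
    so that the noise floor — ``noise_multiplier`` times the centile of
    the pooled permuted window values (or of each window's own values
    with ``per_window_floor``) — is coherent across windows. A window is
    flagged iff it exceeds both its per-window permuted centile and the
    noise floor.
    """
    import warnings
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: the {centile}th centile is unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    res = panel.group_indices("resistant")
    sus = panel.group_indices("susceptible")
    pool = np.concatenate([res, sus])

    def hap_cols(sample_idx: np.ndarray) -> np.ndarray:
        return np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).reshape(-1)

    observed = windowed_fst(matrix, hap_cols(res), hap_cols(sus), window_bp)
    win_index = observed.set_index(["chrom", "win_start"]).index
    perm_values = np.empty((n_perm, len(observed)))
    for it in range(n_perm):
        shuffled = rng.permutation(pool)
        pa, pb = shuffled[:res.size], shuffled[res.size:]
        perm = windowed_fst(matrix, hap_cols(pa), hap_cols(pb), window_bp)
        perm = perm.set_index(["chrom", "win_start"]).reindex(win_index)
        perm_values[it] = perm["fst"].to_numpy()

    obs = observed["fst"].to_numpy()
    with np.errstate(invalid="ignore"):
        window_centile = np.nanpercentile(perm_values, centile, axis=0)
        if per_window_floor:
            floor = noise_multiplier * window_centile
        else:
            floor = noise_multiplier * np.nanpercentile(perm_values, centile)
    out = observed.copy()
    out["perm_centile"] = window_centile
    out["noise_floor"] = floor
    out["above_centile"] = obs > window_centile
    out["above_noise_floor"] = obs > floor
    out["flagged"] = out["above_centile"] & out["above_noise_floor"]
    return out


# ---------------------------------------------------------------------------
# Garud's H

def garud_h(haplotypes: np.ndarray) -> tuple[float, float, float, float]:
    """(H1, H12, H123, H2/H1) from a (n_haplotypes, n_snps) 0/1 array.

    With sorted haplotype-class frequencies p1 >= p2 >= ...:
    H1 = sum pi^2; H12 = (p1+p2)^2 + sum_{i>=3} pi^2;
    H123 = (p1+p2+p3)^2 + sum_{i>=4} pi^2; H2/H1 = (H1 - p1^2)/H1.
    """
    haps = np.ascontiguousarray(np.asarray(haplotypes, dtype=np.int8))
    if haps.ndim != 2 or haps.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    if np.any(haps == MISSING):
        raise ValueError("missing alleles in window; drop masked haplotypes first")
    counts = np.sort(np.fromiter(
        Counter(h.tobytes() for h in haps).values(), dtype=float))[::-1]
    p = counts / haps.shape[0]
    h1 = float(np.sum(p ** 2))
    h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2)) if p.size >= 2 else h1
    if p.size >= 3:
        h123 = float((p[0] + p[1] + p[2]) ** 2 + np.sum(p[3:] ** 2))
    else:
        h123 = 1.0
    h2_h1 = float((h1 - p[0] ** 2) / h1)
    return h1, h12, h123, h2_h1


def _snp_windows(sites: pd.DataFrame, window_snps: int):
    """Yield (chrom, site index array) for consecutive SNP-count windows;
    terminal windows shorter than window_snps are dropped."""
    for chrom, sub in sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for w0 in range(0, idx.size - window_snps + 1, window_snps):
            yield str(chrom), idx[w0:w0 + window_snps]


def h12_scan(matrix: GenotypeMatrix, panel: PhenotypedPanel,
             window_snps: int = H12_WINDOW_SNPS, n_iter: int = 200,
             subsample_size: int | None = None,
             sweep_threshold: float = SWEEP_THRESHOLD, seed: int = 0,
             groups: tuple[str, ...] = ("resistant", "susceptible")) -> pd.DataFrame:
    """Mean H12 per SNP window and phenotype group, with sweep flags.

    Each window/group value is the mean of ``n_iter`` H12 evaluations on
    random subsamples of ``subsample_size`` haplotypes drawn without
    replacement — subsampling equalises group sizes so the groups' H12
    tracks are comparable. ``subsample_size`` defaults to the smallest
    scanned group's haplotype count. Sweep regions are maximal runs of
    windows with mean H12 > ``sweep_threshold``.
    """
    rng = np.random.default_rng(seed)
    haps = matrix.haplotypes()
    group_cols = {g: panel.haplotype_indices(g) for g in groups}
    if subsample_size is None:
        subsample_size = min(c.size for c in group_cols.values())
    for g, cols in group_cols.items():
        if subsample_size > cols.size:
            raise ValueError(
                f"subsample_size {subsample_size} exceeds {g} haplotype count {cols.size}")

    rows = []
    for chrom, win_idx in _snp_windows(matrix.sites, window_snps):
        span = matrix.sites.loc[win_idx, "pos"]
        for g in groups:
            block = haps[np.ix_(win_idx, group_cols[g])]
            complete = ~(block == MISSING).any(axis=0)
            block = np.ascontiguousarray(block[:, complete].T)  # hap-major
            if block.shape[0] < max(2, subsample_size):
                raise ValueError(
                    f"window {chrom}:{span.iloc[0]} has only {block.shape[0]} "
                    f"complete {g} haplotypes (< subsample {subsample_size})")
            if n_iter == 1 and subsample_size == block.shape[0]:
                mean_h12 = garud_h(block)[1]
            else:
                vals = np.empty(n_iter)
                for it in range(n_iter):
                    take = rng.choice(block.shape[0], size=subsample_size,
                                      replace=False)
                    vals[it] = garud_h(block[take])[1]
                mean_h12 = float(vals.mean())
            rows.append({"chrom": chrom, "start_pos": int(span.iloc[0]),
                         "end_pos": int(span.iloc[-1]) + 1,
                         "mid_pos": float(span.iloc[0] + span.iloc[-1]) / 2,
                         "n_snps": int(win_idx.size), "group": g,
                         "mean_h12": mean_h12,
                         "is_sweep": mean_h12 > sweep_threshold})
    return pd.DataFrame(rows)


def sweep_regions(scan: pd.DataFrame) -> pd.DataFrame:
    """Collapse flagged windows into maximal runs per chromosome and group."""
    regions = []
    for (chrom, group), sub in scan.groupby(["chrom", "group"], sort=False):
        sub = sub.sort_values("start_pos").reset_index(drop=True)
        run_start = None
        for i, row in sub.iterrows():
            if row["is_sweep"] and run_start is None:
                run_start = i
            closing = run_start is not None and (
                not row["is_sweep"] or i == len(sub) - 1)
            if closing:
                last = i if row["is_sweep"] else i - 1
                regions.append({
                    "chrom": chrom, "group": group,
                    "start_pos": int(sub.loc[run_start, "start_pos"]),
                    "end_pos": int(sub.loc[last, "end_pos"]),
                    "n_windows": int(last - run_start + 1),
                    "max_h12": float(sub.loc[run_start:last, "mean_h12"].max())})
                run_start = None
    return pd.DataFrame(regions)


# ---------------------------------------------------------------------------
# Haplotype clustering

@dataclass
class HaplotypeCluster:
    members: np.ndarray  # haplotype column indices
    size: int
    phenotype_counts: dict[str, int]


def cluster_haplotypes(haplotypes: np.ndarray, panel: PhenotypedPanel,
                       max_distance: float = 0.001,
                       min_cluster: int = 20) -> list[HaplotypeCluster]:
    """Single-linkage clusters of highly similar haplotypes in one window.

    ``haplotypes`` is (n_haplotypes, n_snps) in panel haplotype order.
    Pairwise distance is the normalized Hamming distance; the dendrogram
    is cut at ``max_distance`` and clusters with at least ``min_cluster``
    members are reported with per-phenotype membership counts.
    """
    haps = np.asarray(haplotypes)
    if haps.size == 0:
        raise ValueError("empty haplotype window")
    dist = pdist(haps, metric="hamming")
    assignment = fcluster(linkage(dist, method="single"),
                          t=max_distance, criterion="distance")
    clusters = []
    for label in np.unique(assignment):
        members = np.flatnonzero(assignment == label)
        if members.size < min_cluster:
            continue
        counts: dict[str, int] = {}
        for h in members:
            ph = panel.phenotype_of_haplotype(int(h))
            counts[ph] = counts.get(ph, 0) + 1
        clusters.append(HaplotypeCluster(members=members, size=int(members.size),
                                         phenotype_counts=counts))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_phenotype_association(cluster: HaplotypeCluster,
                                  panel: PhenotypedPanel) -> dict:
    """Two-sided Fisher exact test: cluster membership x phenotype.

    Controls are excluded (phenotype unknown). Returns the 2x2 table,
    odds ratio and p-value; degenerate margins give NaN p with
    ``defined`` False.
    """
    res = set(panel.haplotype_indices("resistant").tolist())
    sus = set(panel.haplotype_indices("susceptible").tolist())
    members = set(int(m) for m in cluster.members)
    in_r = len(members & res)
    in_s = len(members & sus)
    out_r = len(res) - in_r
    out_s = len(sus) - in_s
    table = np.array([[in_r, in_s], [out_r, out_s]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return {"table": table, "odds_ratio": float("nan"),
                "p_value": float("nan"), "defined": False}
    or_, p = fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(or_), "p_value": float(p),
            "defined": True}


def cluster_association_table(clusters: list[HaplotypeCluster],
                              panel: PhenotypedPanel) -> pd.DataFrame:
    """Association tests for all clusters with Benjamini-Hochberg q-values."""
    rows = []
    for k, cluster in enumerate(clusters):
        result = cluster_phenotype_association(cluster, panel)
        rows.append({"cluster": k, "size": cluster.size,
                     "resistant": cluster.phenotype_counts.get("resistant", 0),
                     "susceptible": cluster.phenotype_counts.get("susceptible", 0),
                     "control": cluster.phenotype_counts.get("control", 0),
                     "odds_ratio": result["odds_ratio"],
                     "p_value": result["p_value"], "defined": result["defined"]})
    frame = pd.DataFrame(rows)
    if len(frame):
        defined = frame["defined"] & frame["p_value"].notna()
        q = np.full(len(frame), np.nan)
        if defined.any():
            q[defined.to_numpy()] = false_discovery_control(
                frame.loc[defined, "p_value"].to_numpy(), method="bh")
        frame["q_value"] = q
    return frame


# ---------------------------------------------------------------------------
# Gene overlap

def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file: gene_id, chrom, start, end, description."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            rows.append({"gene_id": attrs.get("ID", attrs.get("Name", ".")),
                         "chrom": fields[0], "start": int(fields[3]),
                         "end": int(fields[4]),
                         "description": attrs.get("description", "")})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "description"])


def genes_in_windows(windows: pd.DataFrame, genes: pd.DataFrame,
                     top_k: int | None = 5,
                     stat_column: str = "fst") -> pd.DataFrame:
    """Genes overlapping flagged windows; per-chromosome top-k by statistic.

    Windows use 1-based half-open [win_start, win_end) bp spans; gene
    intervals are 1-based inclusive (GFF3). A gene overlaps iff
    gene.start < win_end and gene.end >= win_start, so a gene beginning
    exactly at win_end is not reported.
    """
    if len(windows):
        unmatched = sorted(set(windows["chrom"]) - set(genes["chrom"]))
        if unmatched:
            raise ValueError(
                f"window chromosomes absent from gene annotation: {unmatched}")
    selected = windows
    if top_k is not None and len(windows):
        selected = (windows.sort_values(stat_column, ascending=False)
                    .groupby("chrom", sort=False).head(top_k))
    rows = []
    for win in selected.itertuples(index=False):
        sub = genes[(genes["chrom"] == win.chrom)
                    & (genes["start"] < win.win_end)
                    & (genes["end"] >= win.win_start)]
        for gene in sub.itertuples(index=False):
            rows.append({"chrom": win.chrom, "win_start": win.win_start,
                         "win_end": win.win_end,
                         stat_column: getattr(win, stat_column),
                         "gene_id": gene.gene_id,
                         "description": gene.description})
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end",
                                       stat_column, "gene_id", "description"])
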