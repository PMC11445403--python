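"""CNV allele screening from soft-clipped reads at known breakpoints.

Whole-genome-amplified libraries distort read depth, so copy-number
alleles cannot be called from coverage. Instead, a duplication whose
breakpoints are already characterised leaves a diagnostic alignment
signature: reads spanning a breakpoint junction align only partially and
the aligner soft-clips the overhang (CIGAR 'S') at a reproducible
coordinate. The screen computes, per breakpoint, the proportion of
mapping-quality >= 10 reads whose soft-clip boundary sits exactly at the
breakpoint, and calls the CNV allele present when that proportion reaches
a threshold (19.5% by default, calibrated from a labelled verification
set) at the start, end, or both breakpoints.

Clip-boundary convention: a left-side clip's boundary is the 1-based
position of the first aligned base; a right-side clip's boundary is the
1-based position of the last aligned base. Hard clips ('H') never count.
This is a presence screen, not copy-number quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

MAPQ_MIN = 10
CLIP_THRESHOLD = 0.195

_SOFT = 4  # BAM_CSOFT_CLIP


@dataclass(frozen=True)
class BreakpointSpec:
    """One CNV allele's breakpoint pair (1-based coordinates, start < end)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: breakpoints must satisfy start < end")


@dataclass(frozen=True)
class SoftClipProfile:
    """Clip evidence at one breakpoint."""

    breakpoint: int
    side: str          # "left" | "right" — expected clip side
    n_reads: int
    n_clipped: int

    @property
    def proportion(self) -> float:
        return self.n_clipped / self.n_reads if self.n_reads else float("nan")


@dataclass(frozen=True)
class CnvCall:
    name: str
    call: str           # "present" | "absent" | "no_coverage"
    evidence_side: str  # "start" | "end" | "both" | "none"
    start_profile: SoftClipProfile
    end_profile: SoftClipProfile


def read_breakpoints_tsv(path) -> list[BreakpointSpec]:
    frame = pd.read_csv(path, sep="\t")
    return [BreakpointSpec(str(r.name), str(r.chrom), int(r.start), int(r.end))
            for r in frame.itertuples(index=False)]


def _clip_boundaries(read: pysam.AlignedSegment) -> tuple[int | None, int | None]:
    """(left clip boundary, right clip boundary), 1-based, None when unclipped."""
    cigar = read.cigartuples
    if not cigar:
        return None, None
    left = read.reference_start + 1 if cigar[0][0] == _SOFT else None
    right = read.reference_end if cigar[-1][0] == _SOFT else None
    return left, right


def softclip_proportion(reads, breakpoint: int, side: str,
                        mapq_min: int = MAPQ_MIN,
                        tolerance_bp: int = 0) -> SoftClipProfile:
    """Proportion of qualifying reads soft-clipped at one breakpoint.

    Denominator: mapped reads with MAPQ >= ``mapq_min`` whose aligned
    span covers the breakpoint (a read clipped exactly at the breakpoint
    abuts it and counts). Numerator: those whose clip boundary on the
    expected ``side`` lies within ``tolerance_bp`` of the breakpoint.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    n_reads = n_clipped = 0
    for read in reads:
        if read.is_unmapped or read.mapping_quality < mapq_min:
            continue
        first = read.reference_start + 1
        last = read.reference_end
        if last is None or not (first - tolerance_bp <= breakpoint
                                <= last + tolerance_bp):
            continue
        n_reads += 1
        left, right = _clip_boundaries(read)
        boundary = left if side == "left" else right
        if boundary is not None and abs(boundary - breakpoint) <= tolerance_bp:
            n_clipped += 1
    return SoftClipProfile(breakpoint=breakpoint, side=side,
                           n_reads=n_reads, n_clipped=n_clipped)


def profile_breakpoints(sam_path, spec: BreakpointSpec,
                        mapq_min: int = MAPQ_MIN, tolerance_bp: int = 0
                        ) -> tuple[SoftClipProfile, SoftClipProfile]:
    """Clip profiles at a CNV's start (left clips) and end (right clips)."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        if spec.chrom not in sam.references:
            raise ValueError(
                f"breakpoint chromosome {spec.chrom!r} not in alignment "
                f"references {list(sam.references)}")
        reads = [r for r in sam
                 if not r.is_unmapped and r.reference_name == spec.chrom]
    start = softclip_proportion(reads, spec.start, "left", mapq_min, tolerance_bp)
    end = softclip_proportion(reads, spec.end, "right", mapq_min, tolerance_bp)
    return start, end


def call_cnv(start_profile: SoftClipProfile, end_profile: SoftClipProfile,
             spec: BreakpointSpec, threshold: float = CLIP_THRESHOLD) -> CnvCall:
    """Presence call: clip proportion >= threshold at start, end or both."""
    sides = []
    covered = False
    for label, prof in (("start", start_profile), ("end", end_profile)):
        if prof.n_reads == 0:
            continue
        covered = True
        if prof.proportion >= threshold:
            sides.append(label)
    if not covered:
        return CnvCall(spec.name, "no_coverage", "none", start_profile, end_profile)
    evidence = {0: "none", 1: sides[0] if sides else "none", 2: "both"}[len(sides)]
    return CnvCall(spec.name, "present" if sides else "absent", evidence,
                   start_profile, end_profile)


def screen_sample(sam_path, specs: list[BreakpointSpec],
                  threshold: float = CLIP_THRESHOLD,
                  mapq_min: int = MAPQ_MIN, tolerance_bp: int = 0) -> list[CnvCall]:
    return [call_cnv(*profile_breakpoints(sam_path, s, mapq_min, tolerance_bp),
                     spec=s, threshold=threshold) for s in specs]


def calibrate_threshold(labelled: list[tuple[float, bool]]) -> dict:
    """Threshold from a labelled verification set of clip proportions.

    ``labelled`` pairs each sample's maximum breakpoint clip proportion
    with its known carrier status. When the classes separate, the
    threshold is the midpoint between the highest negative and lowest
    positive; otherwise it is the value maximising Youden's J over a
    sweep of all observed proportions. Returns the threshold with the
    sensitivity/specificity it achieves on the verification set.
    """
    positives = sorted(p for p, status in labelled if status)
    negatives = sorted(p for p, status in labelled if not status)
    if not positives or not negatives:
        raise ValueError("calibration needs both carrier and non-carrier samples")

    def perf(threshold: float) -> tuple[float, float]:
        sens = np.mean([p >= threshold for p in positives])
        spec = np.mean([p < threshold for p in negatives])
        return float(sens), float(spec)

    if negatives[-1] < positives[0]:
        threshold = (negatives[-1] + positives[0]) / 2.0
    else:
        candidates = sorted({p for p, _ in labelled})
        threshold = max(candidates, key=lambda t: sum(perf(t)))
    sens, spec = perf(threshold)
    return {"threshold": float(threshold), "sensitivity": sens,
            "specificity": spec, "youden_j": sens + spec - 1.0,
            "separated": negatives[-1] < positives[0]}


def calls_to_frame(calls_by_sample: dict[str, list[CnvCall]]) -> pd.DataFrame:
    """Sample x CNV-allele call matrix with per-side clip proportions."""
    rows = []
    for sample, calls in calls_by_sample.items():
        for c in calls:
            rows.append({"sample": sample, "cnv_allele": c.name, "call": c.call,
                         "evidence_side": c.evidence_side,
                         "start_prop": round(c.start_profile.proportion, 4)
                         if c.start_profile.n_reads else np.nan,
                         "end_prop": round(c.end_profile.proportion, 4)
                         if c.end_profile.n_reads else np.nan})
    return pd.DataFrame(rows)
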