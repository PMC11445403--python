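"""WHO tube-test bioassay summaries: Abbott's correction and resistance classification.

The tube test exposes adult female mosquitoes to an insecticide-treated
paper (here deltamethrin at the discriminating concentration 0.05% or the
5x intensity concentration 0.25%) alongside oil-treated control tubes, and
scores mortality 24 h post-exposure. When control mortality reaches 5% the
treatment mortality is corrected with Abbott's formula

    corrected = 100 * (T - C) / (100 - C)

where T and C are the treatment and control mortality percentages; a
control mortality above 20% invalidates the test. At the discriminating
concentration, corrected mortality < 90% confirms resistance, 90-97%
suggests it, and >= 98% indicates susceptibility. At the 5x concentration,
mortality >= 98% indicates low-intensity resistance and anything lower
moderate-to-high intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CONTROL_CORRECTION_MIN = 5.0   # percent; Abbott applied at or above
CONTROL_INVALID_ABOVE = 20.0   # percent; test discarded above

DISCRIMINATING = "discriminating"
INTENSITY_5X = "intensity_5x"


@dataclass(frozen=True)
class TubeTestRecord:
    """One replicate tube: exposure and 24 h mortality counts."""

    treatment: str
    replicate: int
    n_exposed: int
    n_dead_24h: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_dead_24h <= self.n_exposed:
            raise ValueError(
                f"dead count {self.n_dead_24h} outside [0, {self.n_exposed}]")


@dataclass(frozen=True)
class MortalitySummary:
    treatment: str
    n_exposed: int
    n_dead: int
    observed_mortality: float
    control_mortality: float
    corrected_mortality: float | None  # None when no correction applied
    validity: str                      # "valid" | "invalid"
    classification: str | None


def observed_mortality(records: list[TubeTestRecord]) -> float:
    """Pooled percent mortality over replicates: 100 * sum(dead)/sum(exposed)."""
    if not records:
        raise ValueError("no replicate records supplied")
    labels = {r.treatment for r in records}
    if len(labels) > 1:
        raise ValueError(f"mixed treatment labels pooled: {sorted(labels)}")
    exposed = sum(r.n_exposed for r in records)
    if exposed == 0:
        raise ValueError("zero mosquitoes exposed")
    return 100.0 * sum(r.n_dead_24h for r in records) / exposed


def abbott_correct(treatment_mortality: float, control_mortality: float) -> float:
    """Abbott's corrected mortality, 100*(T-C)/(100-C); clamped at 0 if T < C."""
    if not 0.0 <= control_mortality < 100.0:
        raise ValueError("control mortality must be in [0, 100)")
    if not 0.0 <= treatment_mortality <= 100.0:
        raise ValueError("treatment mortality must be in [0, 100]")
    corrected = 100.0 * (treatment_mortality - control_mortality) / (100.0 - control_mortality)
    return max(corrected, 0.0)


def classify(mortality: float, tier: str) -> str:
    """WHO classification from (corrected) percent mortality.

    ``discriminating``: < 90 confirmed_resistance, [90, 98) suspected_resistance,
    >= 98 susceptible. ``intensity_5x``: >= 98 low_intensity, else
    moderate_to_high_intensity.
    """
    if not 0.0 <= mortality <= 100.0:
        raise ValueError("mortality out of [0, 100]")
    if tier == DISCRIMINATING:
        if mortality < 90.0:
            return "confirmed_resistance"
        if mortality < 98.0:
            return "suspected_resistance"
        return "susceptible"
    if tier == INTENSITY_5X:
        return "low_intensity" if mortality >= 98.0 else "moderate_to_high_intensity"
    raise ValueError(f"unknown tier {tier!r}")


def validity_check(control_records: list[TubeTestRecord]) -> tuple[str, bool]:
    """(validity, correction_required) from the control tubes.

    Invalid above 20% control mortality; Abbott correction is required in
    the [5%, 20%] band.
    """
    c = observed_mortality(control_records)
    if c > CONTROL_INVALID_ABOVE:
        return "invalid", False
    return "valid", c >= CONTROL_CORRECTION_MIN


def summarise(treatment_records: list[TubeTestRecord],
              control_records: list[TubeTestRecord],
              tier: str = DISCRIMINATING) -> MortalitySummary:
    """Pool replicates, apply Abbott where required, classify.

    The correction is computed from the pooled mortalities at their
    reported precision (2 decimals), the convention used on WHO bioassay
    report forms where Abbott's formula is applied to the recorded
    percentages. Pooling itself always uses raw counts.
    """
    t = observed_mortality(treatment_records)
    c = observed_mortality(control_records)
    validity, needs_correction = validity_check(control_records)
    corrected = abbott_correct(round(t, 2), round(c, 2)) if needs_correction else None
    effective = corrected if corrected is not None else t
    classification = classify(effective, tier) if validity == "valid" else None
    return MortalitySummary(
        treatment=treatment_records[0].treatment,
        n_exposed=sum(r.n_exposed for r in treatment_records),
        n_dead=sum(r.n_dead_24h for r in treatment_records),
        observed_mortality=t,
        control_mortality=c,
        corrected_mortality=corrected,
        validity=validity,
        classification=classification,
    )


def read_records_tsv(path) -> dict[str, list[TubeTestRecord]]:
    """Read replicate counts from TSV (treatment, replicate, n_exposed, n_dead_24h)."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, list[TubeTestRecord]] = {}
    for row in frame.itertuples(index=False):
        rec = TubeTestRecord(str(row.treatment), int(row.replicate),
                             int(row.n_exposed), int(row.n_dead_24h))
        out.setdefault(rec.treatment, []).append(rec)
    return out


def summaries_to_frame(summaries: list[MortalitySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "treatment": s.treatment,
            "n_exposed": s.n_exposed,
            "n_dead": s.n_dead,
            "mortality_pct": round(s.observed_mortality, 2),
            "control_mortality_pct": round(s.control_mortality, 2),
            "corrected_mortality_pct": (None if s.corrected_mortality is None
                                        else round(s.corrected_mortality, 2)),
            "validity": s.validity,
            "classification": s.classification,
        })
    return pd.DataFrame(rows)
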