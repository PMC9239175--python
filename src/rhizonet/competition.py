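"""Interaction indices and competitive-outcome calls from colony counts.

The interaction index compares the observed coculture cell density with
the density expected under purely additive growth — the sum of the two
matched monoculture densities.  An index of 1 means no interaction;
values below 1 indicate antagonism and above 1 facilitation.  Outcomes
across the three initial-fraction treatments (1:1, 1:100, 100:1) are
called qualitatively from the final-cycle fractions, including the
invasion-from-rare criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .simulate import RATIO_LABELS, CompetitionRecord

INTERPRETATION_ANTAGONISTIC = "antagonistic"
INTERPRETATION_ADDITIVE = "additive"
INTERPRETATION_FACILITATIVE = "facilitative"

OUTCOME_FOCAL_EXCLUDES = "focal excludes competitor"
OUTCOME_COMPETITOR_EXCLUDES = "competitor excludes focal"
OUTCOME_COEXISTENCE = "stable coexistence"
OUTCOME_FOUNDER_CONTROL = "founder control"
OUTCOME_INDETERMINATE = "indeterminate"


@dataclass
class InteractionIndex:
    pair_id: str
    replicate: int
    value: float
    interpretation: str
    cycle: int | None = None


def interaction_index(coculture_total: float, monoculture_densities,
                      tolerance: float = 0.05, pair_id: str = "",
                      replicate: int = 0, cycle: int | None = None) -> InteractionIndex:
    """Observed coculture total over the sum of the matched monocultures.

    ``tolerance`` is the half-width of the additive band around 1:
    index < 1 - tolerance -> antagonistic, > 1 + tolerance ->
    facilitative, otherwise additive.
    """
    expected = float(np.sum(monoculture_densities))
    if expected <= 0:
        raise InputError("expected density (sum of monocultures) must be positive")
    if coculture_total < 0:
        raise InputError("observed density must be non-negative")
    if not 0 <= tolerance < 1:
        raise ParameterError("tolerance must lie in [0, 1)")
    value = coculture_total / expected
    if value < 1 - tolerance:
        interpretation = INTERPRETATION_ANTAGONISTIC
    elif value > 1 + tolerance:
        interpretation = INTERPRETATION_FACILITATIVE
    else:
        interpretation = INTERPRETATION_ADDITIVE
    return InteractionIndex(pair_id=pair_id, replicate=replicate, value=value,
                            interpretation=interpretation, cycle=cycle)


def interaction_indices(record: CompetitionRecord, tolerance: float = 0.05,
                        skip_cycle_zero: bool = True) -> list[InteractionIndex]:
    """Per-cycle interaction indices for one competition record (observed
    densities at the end of each cycle against the matched monocultures)."""
    focal, comp = record.focal, record.competitor
    out = []
    start = 1 if skip_cycle_zero else 0
    for i, cycle in enumerate(record.cycles):
        if i < start:
            continue
        observed = record.coculture[focal][i] + record.coculture[comp][i]
        mono = (record.monoculture[focal][i], record.monoculture[comp][i])
        out.append(interaction_index(observed, mono, tolerance=tolerance,
                                     pair_id=record.pair_id, replicate=record.replicate,
                                     cycle=cycle))
    return out


def fraction_trajectories(records: list[CompetitionRecord]) -> pd.DataFrame:
    """Focal-strain fraction per cycle for each record.

    Fractions are focal / (focal + competitor); exact 0 and 1 propagate
    from zero counts, and cycles where both strains are below detection
    are flagged (NaN fraction, undefined=True) rather than erroring.
    """
    rows = []
    for rec in records:
        if len(rec.cycles) < 2:
            raise InputError(f"record {rec.pair_id}/{rec.ratio_label}: need >= 2 cycles")
        f = np.asarray(rec.coculture[rec.focal], dtype=float)
        c = np.asarray(rec.coculture[rec.competitor], dtype=float)
        if (f < 0).any() or (c < 0).any():
            raise InputError("negative colony counts")
        total = f + c
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, f / np.where(total > 0, total, 1.0), np.nan)
        for cycle, fr, tot in zip(rec.cycles, frac, total):
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "replicate": rec.replicate,
                    "ratio": rec.ratio_label,
                    "cycle": cycle,
                    "fraction": fr,
                    "undefined": bool(tot == 0),
                }
            )
    return pd.DataFrame(rows)


def classify_outcome(fractions_by_ratio: dict[str, "np.ndarray | list[float]"],
                     extinction_threshold: float = 0.01,
                     coexistence_spread: float = 0.1) -> str:
    """Qualitative competitive outcome from the three initial-ratio series.

    Uses the final-cycle focal fractions: the focal strain excludes its
    competitor when its final fraction exceeds 1 - epsilon from all three
    starts (which includes invading from rare at 1:100); it is excluded
    when below epsilon from all three; stable coexistence requires all
    three finals inside (epsilon, 1 - epsilon) with pairwise spread below
    ``coexistence_spread``; founder control is called when the 1:100 and
    100:1 starts finish on opposite boundaries.  Anything else is
    'indeterminate' (e.g. dynamics unresolved at the last cycle).
    """
    eps = extinction_threshold
    if not 0 < eps < 0.5:
        raise ParameterError("extinction_threshold must lie in (0, 0.5)")
    missing = [r for r in RATIO_LABELS if r not in fractions_by_ratio]
    if missing:
        raise InputError(f"missing initial-ratio series: {missing}")
    finals = {}
    for ratio in RATIO_LABELS:
        series = np.asarray(fractions_by_ratio[ratio], dtype=float)
        series = series[~np.isnan(series)]
        if series.size == 0:
            raise InputError(f"ratio {ratio} has no defined fractions")
        finals[ratio] = float(series[-1])
    values = np.array([finals[r] for r in RATIO_LABELS])

    if (values > 1 - eps).all():
        return OUTCOME_FOCAL_EXCLUDES
    if (values < eps).all():
        return OUTCOME_COMPETITOR_EXCLUDES
    if finals["100:1"] > 1 - eps and finals["1:100"] < eps:
        return OUTCOME_FOUNDER_CONTROL
    interior = ((values > eps) & (values < 1 - eps)).all()
    if interior and values.max() - values.min() < coexistence_spread:
        return OUTCOME_COEXISTENCE
    return OUTCOME_INDETERMINATE


def records_to_long(records: list[CompetitionRecord]) -> pd.DataFrame:
    """Long-format frame (pair, replicate, ratio, cycle, strain, culture, count)."""
    rows = []
    for rec in records:
        for culture, counts in (("coculture", rec.coculture), ("monoculture", rec.monoculture)):
            for strain, series in counts.items():
                for cycle, count in zip(rec.cycles, series):
                    rows.append(
                        {
                            "pair": rec.pair_id,
                            "replicate": rec.replicate,
                            "ratio": rec.ratio_label,
                            "cycle": cycle,
                            "strain": strain,
                            "culture": culture,
                            "count": count,
                        }
                    )
    return pd.DataFrame(rows)


def records_from_long(df: pd.DataFrame) -> list[CompetitionRecord]:
    """Rebuild CompetitionRecords from the long format written by
    :func:`records_to_long`.  A missing ``culture`` column means all rows
    are coculture counts (monocultures absent -> no interaction indices)."""
    required = {"pair", "replicate", "ratio", "cycle", "strain", "count"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"competition table lacks columns: {sorted(missing)}")
    df = df.copy()
    if "culture" not in df.columns:
        df["culture"] = "coculture"
    records = []
    for (pair, rep, ratio), grp in df.groupby(["pair", "replicate", "ratio"]):
        strains = sorted(grp["strain"].unique())
        if len(strains) != 2:
            raise InputError(f"{pair}/{ratio}: expected 2 strains, found {strains}")
        cycles = sorted(grp["cycle"].unique())
        if cycles != list(range(len(cycles))):
            raise InputError(f"{pair}/{ratio}: cycles must be consecutive from 0")

        def series(culture: str, strain: str) -> list[float]:
            sub = grp[(grp["culture"] == culture) & (grp["strain"] == strain)]
            by_cycle = sub.set_index("cycle")["count"]
            return [float(by_cycle.get(c, np.nan)) for c in cycles]

        records.append(
            CompetitionRecord(
                pair_id=str(pair),
                focal=strains[0],
                competitor=strains[1],
                ratio_label=str(ratio),
                cycles=cycles,
                coculture={s: series("coculture", s) for s in strains},
                monoculture={s: series("monoculture", s) for s in strains},
                replicate=int(rep),
            )
        )
    return records


def classify_records(records: list[CompetitionRecord],
                     extinction_threshold: float = 0.01,
                     coexistence_spread: float = 0.1) -> pd.DataFrame:
    """Outcome per (pair, replicate) from a set of records covering all
    three initial ratios."""
    frames = fraction_trajectories(records)
    rows = []
    for (pair, rep), grp in frames.groupby(["pair_id", "replicate"]):
        series = {
            ratio: sub.sort_values("cycle")["fraction"].to_numpy()
            for ratio, sub in grp.groupby("ratio")
        }
        rows.append(
            {
                "pair_id": pair,
                "replicate": rep,
                "outcome": classify_outcome(series, extinction_threshold,
                                            coexistence_spread),
            }
        )
    return pd.DataFrame(rows)
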