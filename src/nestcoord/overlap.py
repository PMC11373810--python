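"""Pairwise partner overlap statistics.

Two statistics drive the whole analysis:

* ``opposite_activity_overlap`` — during incubation, the total time one
  partner is in the nest while the other forages (in either assignment);
* ``shortlong_overlap`` — during chick rearing, the total time one partner
  is on a short provisioning trip while the other is on a long trip.

Both are computed by an exact sweep over the merged bout breakpoints (no
sampling).  Intervals are half-open integer-second ``[start, end)``, so two
touching intervals contribute zero overlap and the result is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Bout, BoutSequence, CAT_CODE, Category, TripLabel, ValidationError


@dataclass(frozen=True)
class OverlapValue:
    """An overlap measured in seconds, with its share of the session."""

    seconds: int
    duration: int

    @property
    def proportion(self) -> float:
        return self.seconds / self.duration

    def __float__(self) -> float:
        return float(self.seconds)


def _step_overlap(
    ends_a: np.ndarray,
    codes_a: np.ndarray,
    ends_b: np.ndarray,
    codes_b: np.ndarray,
    pairs: Sequence[tuple[int, int]],
) -> int:
    """Total measure of {t : (code_a(t), code_b(t)) in pairs}.

    ``ends_*`` are strictly increasing bout end times sharing the same final
    value (the common span end); ``codes_*`` the per-bout integer labels.
    """
    t = np.union1d(ends_a, ends_b)
    starts = np.concatenate(([0], t[:-1]))
    widths = np.diff(np.concatenate(([0], t)))
    ca = codes_a[np.searchsorted(ends_a, starts, side="right")]
    cb = codes_b[np.searchsorted(ends_b, starts, side="right")]
    mask = np.zeros(len(t), dtype=bool)
    for pa, pb in pairs:
        mask |= (ca == pa) & (cb == pb)
    return int(widths[mask].sum())


_OPP = (
    (CAT_CODE[Category.NEST], CAT_CODE[Category.FORAGING]),
    (CAT_CODE[Category.FORAGING], CAT_CODE[Category.NEST]),
)


def opposite_activity_overlap(bouts_f: BoutSequence, bouts_m: BoutSequence) -> OverlapValue:
    """Time one partner spends in the NEST while the other is FORAGING.

    Symmetric in the partners; a partner's overlap with itself is zero
    (same activity never counts as opposite).
    """
    if bouts_f.duration != bouts_m.duration:
        raise ValidationError(
            f"partner sequences span different durations: "
            f"{bouts_f.duration} vs {bouts_m.duration}"
        )
    ef, cf = bouts_f.as_arrays()
    em, cm = bouts_m.as_arrays()
    sec = _step_overlap(ef, cf, em, cm, _OPP)
    return OverlapValue(sec, bouts_f.duration)


@dataclass(frozen=True)
class LabeledTrip:
    """One foraging trip carrying its SHORT/LONG classification."""

    start: int
    end: int
    label: TripLabel

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"trip must have end > start: [{self.start},{self.end})")


def shortlong_overlap(
    trips_f: Sequence[LabeledTrip], trips_m: Sequence[LabeledTrip], duration: int
) -> OverlapValue:
    """Time one partner is on a SHORT trip while the other is on a LONG one.

    Trips labeled EXCLUDED (long absences without a food-load return) never
    contribute.  Trips of one bird must not overlap each other.
    """
    for trips in (trips_f, trips_m):
        for tr in trips:
            if not isinstance(tr, LabeledTrip) or not isinstance(tr.label, TripLabel):
                raise ValidationError(f"unlabeled or malformed trip: {tr!r}")
        ordered = sorted(trips, key=lambda tr: tr.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"trips of one individual overlap at t={b.start}"
                )
    total = 0
    for a in trips_f:
        for b in trips_m:
            if {a.label, b.label} == {TripLabel.SHORT, TripLabel.LONG}:
                total += max(0, min(a.end, b.end) - max(a.start, b.start))
    return OverlapValue(total, duration)


def trips_from_bouts(seq: BoutSequence, labels: Sequence[TripLabel]) -> list[LabeledTrip]:
    """Attach labels (in timeline order) to the FORAGING bouts of ``seq``."""
    forage = [b for b in seq if b.category is Category.FORAGING]
    if len(labels) != len(forage):
        raise ValidationError(
            f"{len(labels)} labels for {len(forage)} foraging bouts"
        )
    return [LabeledTrip(b.start, b.end, TripLabel(l)) for b, l in zip(forage, labels)]
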