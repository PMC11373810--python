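"""Core domain types: behavioral categories, bouts, and recording sessions.

Timestamps are integer seconds from session start (the annotation has 1-s
precision) and every interval is half-open ``[start, end)``, so a bout
sequence that tiles a session satisfies ``sum of lengths == duration``
exactly and touching intervals never overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

import numpy as np

#: Nominal length of one recording session: 48 hours in seconds.
SESSION_48H = 172_800


class ValidationError(ValueError):
    """An input violates a structural invariant (ordering, tiling, alternation)."""


class Category(str, enum.Enum):
    """Behavioral category of an activity bout."""

    NEST = "NEST"          # inside the nest (incubating / brooding / feeding chick)
    COLONY = "COLONY"      # visible around the nest, or absent < foraging gap
    FORAGING = "FORAGING"  # at sea: absence >= gap (incubation) or a provisioning trip

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TripLabel(str, enum.Enum):
    """Short/long classification of a chick-rearing foraging trip."""

    SHORT = "SHORT"
    LONG = "LONG"
    #: foraging-labeled absence with no food-load return; kept on the timeline
    #: but excluded from the short x long statistic.
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Stage(str, enum.Enum):
    INCUBATION = "INCUBATION"
    CHICK_REARING = "CHICK_REARING"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


# integer codes used by the array-based fast paths
CAT_CODE = {Category.NEST: 0, Category.COLONY: 1, Category.FORAGING: 2}
CODE_CAT = {v: k for k, v in CAT_CODE.items()}


@dataclass(frozen=True)
class Bout:
    """One maximal interval of a single behavioral category.

    Parameters
    ----------
    category : Category
    start, end : int
        Seconds from session start; half-open ``[start, end)``, ``end > start``.
    food : bool, optional
        For chick-rearing FORAGING bouts: ``True`` when the bird returned
        with a full gular pouch (a provisioning trip), ``False`` when a long
        absence ended without food, ``None`` when not applicable.
    """

    category: Category
    start: int
    end: int
    food: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"bout must have end > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class BoutSequence:
    """A validated sequence of bouts tiling ``[0, duration)`` for one bird.

    Invariants enforced at construction:

    * bouts are contiguous — each starts where the previous ended;
    * the first bout starts at 0 and the last ends at ``duration``;
    * no two consecutive bouts share a category (equal neighbours must be
      merged with :meth:`merged` first, or pass ``merge=True``).
    """

    __slots__ = ("bouts", "duration")

    def __init__(self, bouts: Sequence[Bout], duration: int, merge: bool = False):
        bouts = list(bouts)
        if merge:
            bouts = _merge_adjacent(bouts)
        if not bouts:
            raise ValidationError("a bout sequence cannot be empty")
        if bouts[0].start != 0:
            raise ValidationError(f"first bout starts at {bouts[0].start}, not 0")
        if bouts[-1].end != duration:
            raise ValidationError(
                f"last bout ends at {bouts[-1].end}, session duration is {duration}"
            )
        for prev, cur in zip(bouts, bouts[1:]):
            if cur.start != prev.end:
                raise ValidationError(
                    f"bouts do not tile: gap/overlap at t={prev.end} vs {cur.start}"
                )
            if cur.category == prev.category:
                raise ValidationError(
                    f"adjacent bouts share category {cur.category} at t={cur.start}"
                )
        self.bouts = bouts
        self.duration = duration

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self) -> Iterator[Bout]:
        return iter(self.bouts)

    def __getitem__(self, i: int) -> Bout:
        return self.bouts[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoutSequence):
            return NotImplemented
        return self.duration == other.duration and self.bouts == other.bouts

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{b.category.value[0]}[{b.start},{b.end})" for b in self.bouts[:6]
        )
        more = "" if len(self.bouts) <= 6 else f", ... ({len(self.bouts)} bouts)"
        return f"BoutSequence({parts}{more}; duration={self.duration})"

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(ends, codes)``: bout end times and integer category codes."""
        ends = np.fromiter((b.end for b in self.bouts), dtype=np.int64, count=len(self.bouts))
        codes = np.fromiter(
            (CAT_CODE[b.category] for b in self.bouts), dtype=np.int8, count=len(self.bouts)
        )
        return ends, codes

    def time_in(self, category: Category) -> int:
        return sum(b.length for b in self.bouts if b.category is category)

    def category_at(self, t: int) -> Category:
        """Category of the bout containing second ``t`` (``0 <= t < duration``)."""
        if not 0 <= t < self.duration:
            raise ValueError(f"t={t} outside [0, {self.duration})")
        for b in self.bouts:
            if b.start <= t < b.end:
                return b.category
        raise AssertionError("unreachable: sequence tiles the session")


def _merge_adjacent(bouts: list[Bout]) -> list[Bout]:
    """Merge runs of consecutive bouts with equal category (food flags OR-ed)."""
    out: list[Bout] = []
    for b in bouts:
        if out and out[-1].category == b.category and out[-1].end == b.start:
            prev = out.pop()
            food = prev.food if b.food is None else (b.food if prev.food is None else prev.food or b.food)
            b = Bout(prev.category, prev.start, b.end, food)
        out.append(b)
    return out


Phase = Union[int, float, str]


@dataclass
class SessionRecord:
    """One continuous 48-h recording of a pair: metadata plus both partners' bouts.

    ``phase`` is the position inside the breeding stage: days before hatching
    (a number) during incubation, ``"EARLY"``/``"MID"`` during chick rearing.
    """

    session_id: str
    pair_id: str
    year: int
    stage: Stage
    phase: Phase
    duration: int
    bouts_f: BoutSequence
    bouts_m: BoutSequence
    #: True when a leading/trailing unobserved span was labeled by
    #: extrapolating the adjacent bout's category (per sex).
    extrapolated: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bouts_f.duration != self.duration or self.bouts_m.duration != self.duration:
            raise ValidationError(
                f"session {self.session_id}: partner bout sequences must tile "
                f"[0, {self.duration})"
            )
        stage = Stage(self.stage)
        self.stage = stage
        if stage is Stage.INCUBATION:
            try:
                self.phase = float(self.phase)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"session {self.session_id}: incubation phase must be numeric "
                    f"days before hatching, got {self.phase!r}"
                ) from None
        else:
            phase = str(self.phase).upper()
            if phase not in ("EARLY", "MID"):
                raise ValidationError(
                    f"session {self.session_id}: chick-rearing phase must be "
                    f"EARLY or MID, got {self.phase!r}"
                )
            self.phase = phase


def provisioning_trips(seq: BoutSequence) -> list[Bout]:
    """FORAGING bouts that ended with a food-load return (``food is not False``).

    During incubation all FORAGING bouts qualify (``food`` is ``None``); during
    chick rearing, long absences without a food return are excluded.
    """
    return [b for b in seq if b.category is Category.FORAGING and b.food is not False]
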