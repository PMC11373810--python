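"""Constrained Monte-Carlo randomization null for partner coordination.

Each 48-h session is tested separately.  A bird's observed timeline is an
alternating colony-sandwich structure ``C, A, C, A, ..., C`` where every
away bout ``A`` (NEST or FORAGING during incubation; a foraging trip during
chick rearing) is preceded and followed by a colony bout.  The null
hypothesis of no coordination is built by shuffling each partner's timeline
independently while preserving that structure exactly:

* the multiset of colony bout durations is permuted uniformly among the
  colony slots;
* the multiset of away bouts (each keeping its category / trip label and
  duration) is permuted uniformly among the away slots;
* the timeline is rebuilt cumulatively from t = 0.

Every shuffled timeline therefore has identical per-category bout counts
and total times as the observed one — only the ordering moves.  The overlap
statistic is recomputed on each of ``n_iter`` shuffled pairs of timelines;
the session p-value is the proportion of iterations whose null overlap
exceeds the observed one (strict inequality, ties not counted), and the
coordination index is (observed - expected) / expected with expected the
null mean.

A timeline that starts or ends with an away bout is normalized by a
zero-length sentinel colony slot at that edge; sentinels stay pinned to
their edge (moving an empty colony slot between two away bouts would break
the sandwich constraint), so only real colony bouts are permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import Bout, BoutSequence, CAT_CODE, Category, TripLabel, ValidationError
from .overlap import OverlapValue, _step_overlap, _OPP

#: integer codes for the provisioning (chick-rearing) shuffle representation
AT_COLONY, SHORT_CODE, LONG_CODE, EXCLUDED_CODE = 0, 1, 2, 3
_LABEL_CODE = {
    TripLabel.SHORT: SHORT_CODE,
    TripLabel.LONG: LONG_CODE,
    TripLabel.EXCLUDED: EXCLUDED_CODE,
}
_SL_PAIRS = ((SHORT_CODE, LONG_CODE), (LONG_CODE, SHORT_CODE))


@dataclass
class ShufflePattern:
    """Normalized colony-sandwich representation of one bird's timeline.

    ``colony_durs`` has one entry per colony slot (length = n_away + 1;
    zero-length entries are edge sentinels), ``away_durs``/``away_codes``
    one entry per away bout.  Rebuilding interleaves
    ``C0, A0, C1, A1, ..., Ck``.
    """

    colony_durs: np.ndarray
    away_durs: np.ndarray
    away_codes: np.ndarray
    duration: int
    mode: str  # "activity" | "provisioning"

    @property
    def movable_colony(self) -> np.ndarray:
        return np.flatnonzero(self.colony_durs > 0)


def _normalize(
    seq: BoutSequence,
    mode: str = "activity",
    trip_labels: Optional[Sequence[TripLabel]] = None,
) -> ShufflePattern:
    """Convert a bout sequence to its shuffle representation.

    mode="activity": COLONY bouts are colony slots; NEST and FORAGING bouts
    are away units carrying their category code (incubation analysis).

    mode="provisioning": NEST and COLONY merge into at-colony; FORAGING
    bouts are away units carrying their SHORT/LONG/EXCLUDED label
    (chick-rearing analysis). ``trip_labels`` must align with the FORAGING
    bouts in timeline order; unlabeled provisioning trips are an error.
    """
    if mode == "activity":
        units: list[tuple[bool, int, int]] = [
            (b.category is Category.COLONY, b.length, CAT_CODE[b.category]) for b in seq
        ]
    elif mode == "provisioning":
        merged: list[tuple[bool, int, int]] = []
        li = 0
        for b in seq:
            if b.category is Category.FORAGING:
                if b.food is False:
                    code = EXCLUDED_CODE
                else:
                    if trip_labels is None or li >= len(trip_labels):
                        raise ValidationError(
                            f"provisioning trip at t={b.start} has no SHORT/LONG label"
                        )
                    code = _LABEL_CODE[TripLabel(trip_labels[li])]
                    li += 1
                merged.append((False, b.length, code))
            else:
                # NEST + COLONY merge into at-colony time
                if merged and merged[-1][0]:
                    merged[-1] = (True, merged[-1][1] + b.length, AT_COLONY)
                else:
                    merged.append((True, b.length, AT_COLONY))
        if trip_labels is not None and li != len(trip_labels):
            raise ValidationError(
                f"{len(trip_labels)} trip labels for {li} provisioning trips"
            )
        units = merged
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown shuffle mode {mode!r}")

    colony, away_durs, away_codes = [], [], []
    expect_colony = True
    for is_colony, length, code in units:
        if is_colony:
            if not expect_colony:  # two adjacent colony units cannot happen post-merge
                raise ValidationError("adjacent colony bouts in normalized sequence")
            colony.append(length)
            expect_colony = False
        else:
            if expect_colony:
                colony.append(0)  # edge or missing sandwich slot
                if away_durs:  # an away bout directly follows another
                    raise ValidationError(
                        "sequence violates the colony-sandwich constraint: "
                        "two away bouts with no colony between"
                    )
            away_durs.append(length)
            away_codes.append(code)
            expect_colony = True
    if expect_colony:
        colony.append(0)  # trailing sentinel (sequence ended on an away bout)
    assert len(colony) == len(away_durs) + 1
    return ShufflePattern(
        colony_durs=np.asarray(colony, dtype=np.int64),
        away_durs=np.asarray(away_durs, dtype=np.int64),
        away_codes=np.asarray(away_codes, dtype=np.int8),
        duration=seq.duration,
        mode=mode,
    )


def _shuffled_arrays(
    pat: ShufflePattern, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One uniform constrained shuffle, returned as (ends, codes) arrays."""
    k = len(pat.away_durs)
    colony = pat.colony_durs.copy()
    movable = pat.movable_colony
    if len(movable) > 1:
        colony[movable] = colony[movable][rng.permutation(len(movable))]
    if k > 1:
        perm = rng.permutation(k)
        away_durs = pat.away_durs[perm]
        away_codes = pat.away_codes[perm]
    else:
        away_durs, away_codes = pat.away_durs, pat.away_codes
    durs = np.empty(2 * k + 1, dtype=np.int64)
    codes = np.empty(2 * k + 1, dtype=np.int8)
    durs[0::2] = colony
    codes[0::2] = CAT_CODE[Category.COLONY] if pat.mode == "activity" else AT_COLONY
    durs[1::2] = away_durs
    codes[1::2] = away_codes
    keep = durs > 0
    ends = np.cumsum(durs[keep])
    return ends, codes[keep]


def _identity_arrays(pat: ShufflePattern) -> tuple[np.ndarray, np.ndarray]:
    k = len(pat.away_durs)
    durs = np.empty(2 * k + 1, dtype=np.int64)
    codes = np.empty(2 * k + 1, dtype=np.int8)
    durs[0::2] = pat.colony_durs
    codes[0::2] = CAT_CODE[Category.COLONY] if pat.mode == "activity" else AT_COLONY
    durs[1::2] = pat.away_durs
    codes[1::2] = pat.away_codes
    keep = durs > 0
    return np.cumsum(durs[keep]), codes[keep]


def constrained_shuffle(
    seq: BoutSequence,
    rng: Union[int, np.random.Generator],
    mode: str = "activity",
    trip_labels: Optional[Sequence[TripLabel]] = None,
) -> BoutSequence:
    """Return one uniformly shuffled timeline preserving the sandwich structure.

    The multiset of (category, duration) bouts of the output equals the
    input's exactly; only the ordering of colony bouts among colony slots
    and of away bouts among away slots changes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pat = _normalize(seq, mode=mode, trip_labels=trip_labels)
    ends, codes = _shuffled_arrays(pat, rng)
    if mode == "activity":
        inv = {v: k for k, v in CAT_CODE.items()}
        cats = [inv[int(c)] for c in codes]
    else:
        cats = [
            Category.COLONY if int(c) == AT_COLONY else Category.FORAGING for c in codes
        ]
    bouts, start = [], 0
    for cat, end in zip(cats, ends.tolist()):
        bouts.append(Bout(cat, start, end))
        start = end
    return BoutSequence(bouts, seq.duration, merge=(mode == "provisioning"))


@dataclass
class RandomizationResult:
    """Observed statistic, constrained-shuffle null, and derived quantities.

    ``p_value`` is the proportion of null iterations strictly exceeding the
    observed overlap; ``index`` is (observed - expected)/expected, ``None``
    when the null mean is zero.
    """

    observed: OverlapValue
    null_seconds: np.ndarray
    p_value: float
    n_iter: int
    seed: Optional[int] = None
    statistic: str = "opposite_activity"

    @property
    def expected(self) -> float:
        return float(np.mean(self.null_seconds))

    @property
    def index(self) -> Optional[float]:
        exp = self.expected
        if exp <= 0:
            return None
        return coordination_index(self.observed.seconds, exp)

    def smoothed_p_value(self) -> float:
        """Add-one smoothed variant: (count + 1) / (n_iter + 1)."""
        count = int(np.sum(self.null_seconds > self.observed.seconds))
        return (count + 1) / (self.n_iter + 1)

    def is_coordinated(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def coordination_index(observed: float, expected: float) -> float:
    """(observed - expected) / expected; requires a positive null mean."""
    if expected <= 0:
        raise ValueError(
            f"coordination index undefined for expected={expected} (must be > 0)"
        )
    return (observed - expected) / expected


def mc_null(
    bouts_f: BoutSequence,
    bouts_m: BoutSequence,
    n_iter: int = 10_000,
    rng: Union[int, np.random.Generator, None] = None,
    mode: str = "activity",
    trip_labels_f: Optional[Sequence[TripLabel]] = None,
    trip_labels_m: Optional[Sequence[TripLabel]] = None,
) -> RandomizationResult:
    """Monte-Carlo null distribution of the partner overlap statistic.

    Both partners' timelines are shuffled independently on every iteration
    and the statistic recomputed (opposite-activity seconds for
    mode="activity", short x long trip seconds for mode="provisioning").

    Parameters
    ----------
    n_iter : int
        Number of shuffle iterations (the study used 10,000).
    rng : int or numpy Generator
        Session-level seed; identical seed gives an identical result.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if bouts_f.duration != bouts_m.duration:
        raise ValidationError("partner sequences span different durations")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    pat_f = _normalize(bouts_f, mode=mode, trip_labels=trip_labels_f)
    pat_m = _normalize(bouts_m, mode=mode, trip_labels=trip_labels_m)
    pairs = _OPP if mode == "activity" else _SL_PAIRS
    stat_name = "opposite_activity" if mode == "activity" else "shortlong"

    ef, cf = _identity_arrays(pat_f)
    em, cm = _identity_arrays(pat_m)
    observed = OverlapValue(_step_overlap(ef, cf, em, cm, pairs), bouts_f.duration)

    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        ef, cf = _shuffled_arrays(pat_f, gen)
        em, cm = _shuffled_arrays(pat_m, gen)
        null[i] = _step_overlap(ef, cf, em, cm, pairs)

    p_value = float(np.mean(null > observed.seconds))
    result = RandomizationResult(
        observed=observed,
        null_seconds=null,
        p_value=p_value,
        n_iter=n_iter,
        seed=int(seed) if seed is not None else None,
        statistic=stat_name,
    )
    if result.expected <= 0:
        warnings.warn(
            "null mean overlap is zero: coordination index undefined for this session",
            RuntimeWarning,
            stacklevel=2,
        )
    return result
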