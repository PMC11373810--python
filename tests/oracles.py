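"""Independent brute-force oracles used to verify the fast implementations.

Everything here favors transparency over speed: second-by-second scans,
exhaustive enumeration of permutations and partitions.  Nothing imports the
code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from nestcoord.core import BoutSequence, CAT_CODE, Category


def second_scan_codes(seq: BoutSequence) -> np.ndarray:
    """Per-second integer category codes (length = duration)."""
    out = np.empty(seq.duration, dtype=np.int8)
    for b in seq:
        out[b.start : b.end] = CAT_CODE[b.category]
    return out


def scan_opposite_overlap(seq_f: BoutSequence, seq_m: BoutSequence) -> int:
    """Opposite-activity seconds by scanning the timeline one second at a time."""
    f = second_scan_codes(seq_f)
    m = second_scan_codes(seq_m)
    nest, forage = CAT_CODE[Category.NEST], CAT_CODE[Category.FORAGING]
    return int(np.sum(((f == nest) & (m == forage)) | ((f == forage) & (m == nest))))


def scan_label_overlap(labels_f: np.ndarray, labels_m: np.ndarray, a: int, b: int) -> int:
    """Seconds where one stream is label ``a`` and the other ``b`` (either way)."""
    return int(np.sum(((labels_f == a) & (labels_m == b)) | ((labels_f == b) & (labels_m == a))))


def sandwich_pattern(seq: BoutSequence):
    """Decompose into (colony durations incl. zero edge sentinels, away bouts).

    Away bouts are (duration, category-code) pairs; mirrors the constrained
    shuffle's normalization but written independently.
    """
    colony, away = [], []
    expect_colony = True
    for b in seq:
        if b.category is Category.COLONY:
            colony.append(b.length)
            expect_colony = False
        else:
            if expect_colony:
                colony.append(0)
            away.append((b.length, CAT_CODE[b.category]))
            expect_colony = True
    if expect_colony:
        colony.append(0)
    return colony, away


def enumerate_arrangements(seq: BoutSequence) -> list[np.ndarray]:
    """Every distinct admissible rearrangement, as per-second code arrays.

    Colony bouts permute among colony slots (zero-length sentinels stay at
    their edges), away bouts among away slots; duplicates collapse.
    """
    colony, away = sandwich_pattern(seq)
    movable = [d for d in colony if d > 0]
    zero_mask = [d == 0 for d in colony]
    colony_orders = sorted(set(itertools.permutations(movable)))
    away_orders = sorted(set(itertools.permutations(away)))
    out = []
    seen = set()
    for corder in colony_orders:
        for aorder in away_orders:
            cs = iter(corder)
            rebuilt = []
            for i, z in enumerate(zero_mask):
                rebuilt.append((0 if z else next(cs), CAT_CODE[Category.COLONY]))
                if i < len(aorder):
                    rebuilt.append(aorder[i])
            arr = np.empty(seq.duration, dtype=np.int8)
            t = 0
            for dur, code in rebuilt:
                arr[t : t + dur] = code
                t += dur
            assert t == seq.duration
            key = arr.tobytes()
            if key not in seen:
                seen.add(key)
                out.append(arr)
    return out


def exact_null_mean_opposite(seq_f: BoutSequence, seq_m: BoutSequence) -> float:
    """Exact mean opposite-activity overlap over all constrained arrangements.

    Uses per-second occupancy probabilities of each bird (uniform over its
    own arrangements; partners independent), integrating
    P_f(N)P_m(F) + P_f(F)P_m(N) over the session.
    """
    nest, forage = CAT_CODE[Category.NEST], CAT_CODE[Category.FORAGING]
    probs = []
    for seq in (seq_f, seq_m):
        arrs = np.stack(enumerate_arrangements(seq))
        probs.append(
            ((arrs == nest).mean(axis=0), (arrs == forage).mean(axis=0))
        )
    (pfn, pff), (pmn, pmf) = probs
    return float(np.sum(pfn * pmf + pff * pmn))


def exhaustive_trip_split(durations) -> tuple[float, int]:
    """Minimum summed within-group population variance over all ordered
    2-partitions of the sorted log durations (>= 2 per side).

    Returns (objective, short-group size at the optimum).
    """
    s = np.sort(np.log(np.asarray(durations, dtype=float)))
    n = len(s)
    best = (np.inf, -1)
    for k in range(2, n - 1):
        if s[k - 1] == s[k]:
            continue
        obj = float(np.var(s[:k]) + np.var(s[k:]))
        if obj < best[0]:
            best = (obj, k)
    return best
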