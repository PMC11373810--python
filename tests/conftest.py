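import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nestcoord.core import Bout, BoutSequence, Category

CATS = [Category.NEST, Category.COLONY, Category.FORAGING]


def random_tiling_sequence(
    rng: np.random.Generator, duration: int = 200, max_bouts: int = 12
) -> BoutSequence:
    """A random valid bout sequence tiling [0, duration): arbitrary categories,
    no adjacent repeats, integer breakpoints."""
    n = int(rng.integers(1, max_bouts + 1))
    if n >= duration:
        n = duration - 1
    cuts = np.sort(rng.choice(np.arange(1, duration), size=n - 1, replace=False)) if n > 1 else np.array([], dtype=int)
    bounds = [0, *cuts.tolist(), duration]
    bouts, prev = [], None
    for s, e in zip(bounds, bounds[1:]):
        choices = [c for c in CATS if c is not prev]
        cat = choices[int(rng.integers(len(choices)))]
        bouts.append(Bout(cat, s, e))
        prev = cat
    return BoutSequence(bouts, duration)


def random_sandwich_sequence(
    rng: np.random.Generator, duration: int = 200, max_away: int = 4
) -> BoutSequence:
    """A random valid colony-sandwich sequence: C,A,C,...,C with optional
    missing edge colonies, away categories random NEST/FORAGING."""
    n_away = int(rng.integers(1, max_away + 1))
    n_bouts = 2 * n_away + 1
    # lengths for all slots; edge colony slots may be zero
    while True:
        cuts = np.sort(rng.choice(np.arange(1, duration), size=n_bouts - 1, replace=False))
        lens = np.diff([0, *cuts.tolist(), duration])
        break
    bouts, t = [], 0
    for i, ln in enumerate(lens):
        if i % 2 == 0:
            cat = Category.COLONY
        else:
            cat = Category.NEST if rng.random() < 0.5 else Category.FORAGING
        bouts.append(Bout(cat, t, t + int(ln)))
        t += int(ln)
    # randomly strip edge colonies to exercise the zero-sentinel path
    if rng.random() < 0.3 and len(bouts) > 2:
        first = bouts.pop(0)
        shift = first.length
        bouts = [Bout(b.category, b.start - shift, b.end - shift, b.food) for b in bouts]
        duration -= shift
    if rng.random() < 0.3 and len(bouts) > 2:
        last = bouts.pop()
        duration -= last.length
    return BoutSequence(bouts, duration)


@pytest.fixture
def rng():
    return np.random.default_rng(20240904)
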