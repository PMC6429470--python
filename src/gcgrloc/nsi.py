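"""Interval statistics of the three-letter hydropathy encoding (NSI).

For each reduced letter k in {F, D, S} the 1-based occurrence
positions W(k) are recorded; the gaps between consecutive occurrences
form the interval sequence N(k).  Treating the interval as a random
variable x with empirical pmf p(x), the features are the index of
dispersion inverted:

    E(k) = sum_x x p(x)          (mean interval)
    D(k) = E(x^2) - E(x)^2       (population variance, no Bessel term)
    I(k) = E(k) / D(k)           (mean-to-variance ratio)

I(k) is large when a letter recurs at near-constant spacing and small
when its spacing is erratic, so the triple (I_F, I_D, I_S) carries
positional information that plain composition cannot.  When D(k) = 0
(fewer than two intervals, or all intervals equal) the ratio is
undefined and a configurable sentinel (default 0) is reported.

Intervals are plain consecutive differences with no wrap-around term:
a letter occurring at m positions yields m - 1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gcgrloc.encoding import ThreeLetterSequence

REDUCED_LETTERS = ("F", "D", "S")


@dataclass(frozen=True)
class NSIProfile:
    """Positions, intervals and statistics per reduced letter."""

    positions: dict[str, tuple[int, ...]]
    intervals: dict[str, tuple[int, ...]]
    pmf: dict[str, dict[int, float]]
    mean: dict[str, float]
    variance: dict[str, float]
    info: dict[str, float]

    def feature_vector(self) -> np.ndarray:
        return np.array([self.info[k] for k in REDUCED_LETTERS])


def position_sequences(encoded: ThreeLetterSequence) -> dict[str, tuple[int, ...]]:
    """1-based occurrence positions of each reduced letter, in order.

    The three lists partition {1..len}; letters absent from the
    sequence map to empty tuples.
    """
    if not encoded.symbols:
        raise ValueError("empty encoded sequence")
    out: dict[str, list[int]] = {k: [] for k in REDUCED_LETTERS}
    for pos, symbol in enumerate(encoded.symbols, start=1):
        out[symbol].append(pos)
    return {k: tuple(v) for k, v in out.items()}


def interval_sequences(positions: dict[str, tuple[int, ...]]) -> dict[str, tuple[int, ...]]:
    """Consecutive differences of each position list.

    Fewer than two occurrences yield an empty interval list.
    """
    return {
        k: tuple(b - a for a, b in zip(w, w[1:]))
        for k, w in positions.items()
    }


def interval_statistics(
    intervals: tuple[int, ...] | list[int],
    degenerate_info: float = 0.0,
) -> tuple[float, float, float]:
    """Mean E, population variance D and ratio I = E/D of an interval list.

    With an empty list E = D = 0 and I is the degenerate sentinel; with
    zero variance (constant intervals) I is the sentinel as well.
    """
    if len(intervals) == 0:
        return 0.0, 0.0, degenerate_info
    x = np.asarray(intervals, dtype=float)
    values, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    e = float(np.sum(values * p))
    d = float(np.sum(values**2 * p) - e**2)
    d = max(d, 0.0)  # clip the tiny negative round-off of E(x^2)-E(x)^2
    info = e / d if d > 0 else degenerate_info
    return e, d, info


def nsi_profile(encoded: ThreeLetterSequence, degenerate_info: float = 0.0) -> NSIProfile:
    """Full per-letter profile: W(k), N(k), pmf, E, D, I."""
    w = position_sequences(encoded)
    n = interval_sequences(w)
    pmf: dict[str, dict[int, float]] = {}
    mean: dict[str, float] = {}
    var: dict[str, float] = {}
    info: dict[str, float] = {}
    for k in REDUCED_LETTERS:
        iv = n[k]
        if iv:
            values, counts = np.unique(np.asarray(iv), return_counts=True)
            pmf[k] = {int(v): float(c) / len(iv) for v, c in zip(values, counts)}
        else:
            pmf[k] = {}
        mean[k], var[k], info[k] = interval_statistics(iv, degenerate_info)
    return NSIProfile(positions=w, intervals=n, pmf=pmf, mean=mean, variance=var, info=info)


def nsi_features(encoded: ThreeLetterSequence, degenerate_info: float = 0.0) -> np.ndarray:
    """The 3-D feature vector (I_F, I_D, I_S)."""
    return nsi_profile(encoded, degenerate_info).feature_vector()
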