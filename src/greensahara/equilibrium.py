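"""Equilibrium-potential analysis, threshold times and the sensitivity metric.

In the absence of noise the model is gradient-like, with equilibrium
potential

    U(v; r, d) = v^2/2 - ln(cosh(r + d*v)) / d,

where r = a + b*P + c*F is the background rainfall.  The minima of U are the
stable states; if the noiseless system were left to equilibrate it would end
in the state of minimum potential.  A *threshold time* t* is a time at which
the global minimum of U changes side of v = 0.  Because U is exactly
antisymmetric under (v, r) -> (-v, -r), the global minimiser carries the
sign of r, so t* reduces to a sign change of the background rainfall:

    sgn(r(t*)) != sgn(r(t* - dt)).

The *simulated sensitivity* SS(t) counts, per century, the not-implausible
ensemble members whose threshold time falls in that century; its peaks mark
when the system is most susceptible to a state change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import ModelParams, background_rainfall, stable_equilibrium
from .forcing import ForcingSeries

__all__ = [
    "ThresholdEvent",
    "SensitivitySeries",
    "potential",
    "min_potential_state",
    "threshold_times",
    "select_collapse_time",
    "sensitivity",
]

ONSET = "onset"        # yellow -> green, r crosses negative -> positive
COLLAPSE = "collapse"  # green -> yellow, r crosses positive -> negative


@dataclass(frozen=True)
class ThresholdEvent:
    """A sign change of the minimum-potential state.

    t_star : years BP, on the forcing grid.
    direction : 'onset' (yellow->green) or 'collapse' (green->yellow).
    """

    t_star: float
    direction: str

    def __post_init__(self):
        if self.direction not in (ONSET, COLLAPSE):
            raise ValueError(f"direction must be {ONSET!r} or {COLLAPSE!r}")


@dataclass(frozen=True)
class SensitivitySeries:
    """Per-century member counts of threshold times, with 3-point smoothing.

    Bins are left-closed on the older edge: a t* belongs to the bin labelled
    ``bin_start`` when ``bin_start >= t* > bin_start - bin_width``.
    """

    bin_start: np.ndarray
    count: np.ndarray
    smoothed: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_start[0] - self.bin_start[1])

    def peak_bin(self, use_smoothed: bool = True) -> float:
        """Older edge (years BP) of the bin with the largest count."""
        y = self.smoothed if use_smoothed else self.count
        return float(self.bin_start[int(np.argmax(y))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_yrBP": self.bin_start, "count": self.count, "smoothed": self.smoothed}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# potential landscape
# ----------------------------------------------------------------------

def _log_cosh(x):
    # overflow-safe ln(cosh(x)) = |x| + log1p(exp(-2|x|)) - ln 2
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - math.log(2.0)


def potential(v, r, d):
    """Equilibrium potential U(v) = v^2/2 - ln(cosh(r + d*v))/d.

    Elementwise over arrays; undefined (and rejected) for d = 0.  Exactly
    satisfies U(v; r, d) = U(-v; -r, d) since cosh is even.
    """
    if np.any(np.asarray(d) == 0):
        raise ValueError("potential is undefined for d = 0")
    v = np.asarray(v, dtype=float)
    out = v * v / 2.0 - _log_cosh(np.asarray(r, dtype=float) + d * v) / d
    return float(out) if out.ndim == 0 else out


def min_potential_state(r: float, d: float) -> float:
    """Global minimiser of U(., r, d) over [-1.5, 1.5].

    For r != 0 the global minimum sits in the well selected by sign(r); it is
    the stable fixed point of v = tanh(r + d*v) on that side.  The r < 0
    branch is computed as the mirror image of the r > 0 branch, so the
    antisymmetry min_potential_state(-r, d) == -min_potential_state(r, d)
    holds to the last bit.
    """
    if d <= 0:
        raise ValueError("min_potential_state requires d > 0")
    return stable_equilibrium(float(r), float(d))


# ----------------------------------------------------------------------
# threshold times
# ----------------------------------------------------------------------

def _sign(r: np.ndarray) -> np.ndarray:
    # sgn(0) := +1; exact zeros of r are vanishingly rare on float forcing
    return np.where(r >= 0.0, 1, -1)


def threshold_times(params: ModelParams, forcing: ForcingSeries) -> List[ThresholdEvent]:
    """All times where the background rainfall r = a+bP+cF changes sign.

    Returns one event per grid time t where sgn(r(t)) != sgn(r(t - dt)),
    labelled 'onset' when r turns positive and 'collapse' when it turns
    negative.  Equivalent to the sign changes of the argmin of the potential
    (antisymmetry argument); empty if r never changes sign.
    """
    r = np.asarray(background_rainfall(params, forcing.P, forcing.F), dtype=float)
    s = _sign(r)
    flip = np.nonzero(s[1:] != s[:-1])[0] + 1
    return [
        ThresholdEvent(float(forcing.time[i]), ONSET if s[i] > 0 else COLLAPSE)
        for i in flip
    ]


def select_collapse_time(
    events: Sequence[ThresholdEvent],
    window: Optional[Tuple[float, float]] = None,
) -> Optional[float]:
    """A member's single collapse date: first collapse after its last onset.

    When the background rainfall wiggles across zero several times, the
    member's collapse is dated to the first collapse-direction crossing that
    follows the most recent onset (or the first collapse in the window when
    no onset occurs there).  Returns ``None`` if no such crossing exists —
    e.g. a member that never leaves the green state.

    window : (oldest, youngest) years BP, optional restriction.
    """
    evs = list(events)
    if window is not None:
        old, young = window
        evs = [e for e in evs if old >= e.t_star >= young]
    onsets = [e.t_star for e in evs if e.direction == ONSET]
    collapses = sorted((e.t_star for e in evs if e.direction == COLLAPSE), reverse=True)
    if not collapses:
        return None
    if onsets:
        last_onset = min(onsets)  # most recent = smallest years BP
        after = [t for t in collapses if t < last_onset]
        return after[0] if after else None
    return collapses[0]


# ----------------------------------------------------------------------
# simulated sensitivity
# ----------------------------------------------------------------------

def _running_mean3(y: np.ndarray) -> np.ndarray:
    # 3-point running mean; edges averaged over the available neighbours
    kernel = np.ones(3)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def sensitivity(
    events_per_member: Iterable[Sequence[ThresholdEvent]],
    window: Tuple[float, float] = (15000.0, 0.0),
    direction: str = COLLAPSE,
    bin_width: float = 100.0,
    selection: str = "auto",
) -> SensitivitySeries:
    """SS(t): members per century bin with a threshold time in that bin.

    Each member contributes at most one t* (its *selected* threshold time)
    unless ``selection='all'``, in which case every matching-direction
    crossing in the window is counted.

    Parameters
    ----------
    events_per_member : iterable of per-member ThresholdEvent lists.
    window : (oldest, youngest) years BP; bin_width must divide its length.
    direction : 'collapse' or 'onset'.
    selection : 'auto' (collapse: first collapse after the last onset;
        onset: first onset in the window), 'first', or 'all'.
    """
    old, young = float(window[0]), float(window[1])
    span = old - young
    nbin = span / bin_width
    if abs(nbin - round(nbin)) > 1e-9 or span <= 0:
        raise ValueError("bin_width must divide the window length")
    nbin = int(round(nbin))
    bin_start = old - bin_width * np.arange(nbin)

    counts = np.zeros(nbin, dtype=int)
    for events in events_per_member:
        if selection == "all":
            ts = [e.t_star for e in events
                  if e.direction == direction and old >= e.t_star > young]
        elif direction == COLLAPSE and selection == "auto":
            t = select_collapse_time(events, (old, young))
            ts = [] if t is None else [t]
        else:  # first matching-direction crossing in the window
            cand = sorted(e.t_star for e in events
                          if e.direction == direction and old >= e.t_star > young)
            ts = [cand[-1]] if cand else []  # oldest = first in time
        for t in ts:
            i = int(math.floor((old - t) / bin_width))
            if t == old:
                i = 0
            if 0 <= i < nbin:
                counts[i] += 1
    return SensitivitySeries(bin_start, counts, _running_mean3(counts.astype(float)))
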