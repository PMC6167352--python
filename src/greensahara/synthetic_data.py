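"""Synthetic study conditions: forcing, truth trajectories, proxy tables.

Everything needed to exercise the full pipeline without external downloads:

* quasi-periodic climatic precession built from two fixed quasi-periods near
  23.7 and 22.4 kyr under a 100-kyr eccentricity-like amplitude modulation
  (a full orbital solution is deliberately not computed — the beat structure
  that creates discrete humid windows is what matters; real series can be
  supplied as CSV);
* a glacial-interglacial CO2 cycle as an asymmetric 100-kyr sawtooth between
  190 and 280 ppm — slow glacial decline, fast deglacial rise ending at the
  synthetic interglacial peak;
* a "truth study": a known parameter vector whose rainfall offset is tuned
  (by bisection on the green-episode count) until the truth member shows a
  prescribed number of green episodes in the screening window, together with
  its noisy proxy trace (truth vegetation plus white noise, standing in for
  a Ba/Al record) and a 500-yr-binned wet/moderate/dry state table with
  known transition dates.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .dynamics import ModelParams, SimulationConfig, Trajectory, simulate
from .ensemble import detect_green_events
from .equilibrium import select_collapse_time, threshold_times
from .forcing import ForcingSeries, co2_to_forcing
from .observations import date_collapse

__all__ = [
    "SyntheticForcingSpec",
    "TruthStudy",
    "DEFAULT_TRUTH_PARAMS",
    "make_forcing",
    "make_truth_study",
    "make_proxy_state_table",
]


@dataclass(frozen=True)
class SyntheticForcingSpec:
    """Recipe for a synthetic forcing pair.

    precession_terms : (period yr, amplitude, phase rad) triples; the two
        defaults sit near the 23.7- and 22.4-kyr precession quasi-periods,
        phased so both are at their minimum (wettest North Africa) near
        11 ka BP, and sum to a realistic ±0.06 envelope.
    modulation : (period yr, depth in [0, 1)); the amplitude factor varies
        between 1 and 1-depth with the given period, peaking (full
        amplitude) at ``modulation_peak_bp``.
    co2_cycle : (period yr, low ppm, high ppm, rise fraction of the period);
        sawtooth peaking at ``interglacial_peak_bp`` — with the defaults CO2
        sits at its 190-ppm glacial floor at 20 ka BP and reaches 280 ppm at
        10 ka BP, a deglaciation-like ramp.
    """

    window: Tuple[float, float] = (230000.0, 0.0)
    precession_terms: Tuple[Tuple[float, float, float], ...] = (
        (23700.0, 0.032, 1.796),
        (22400.0, 0.028, 1.626),
    )
    modulation: Tuple[float, float] = (100000.0, 0.5)
    modulation_peak_bp: float = 11000.0
    co2_cycle: Tuple[float, float, float, float] = (100000.0, 190.0, 280.0, 0.1)
    interglacial_peak_bp: float = 10000.0
    timestep: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.window[0] <= self.window[1]:
            raise ValueError("window must be (oldest, youngest) with oldest > youngest")
        if any(amp < 0 for _, amp, _ in self.precession_terms):
            raise ValueError("precession amplitudes must be non-negative")
        T, lo, hi, f = self.co2_cycle
        if not (0 < lo < hi):
            raise ValueError("CO2 cycle needs 0 < low < high")
        if not (0 < f < 1):
            raise ValueError("CO2 rise fraction must lie in (0, 1)")
        if not (0 <= self.modulation[1] < 1):
            raise ValueError("modulation depth must lie in [0, 1)")


def _precession(spec: SyntheticForcingSpec, t: np.ndarray) -> np.ndarray:
    T_mod, depth = spec.modulation
    mod = (1.0 - depth) + depth * 0.5 * (
        1.0 + np.cos(2.0 * math.pi * (t - spec.modulation_peak_bp) / T_mod)
    )
    p = np.zeros_like(t)
    for T, amp, phase in spec.precession_terms:
        p += amp * np.sin(2.0 * math.pi * t / T + phase)
    return mod * p


def _co2(spec: SyntheticForcingSpec, t: np.ndarray) -> np.ndarray:
    T, lo, hi, f = spec.co2_cycle
    tau = np.mod(t - spec.interglacial_peak_bp, T)  # 0 at each peak, grows with age
    rise = tau <= f * T
    co2 = np.where(
        rise,
        hi - (hi - lo) * tau / (f * T),              # deglacial ramp (going back in time)
        lo + (hi - lo) * (tau - f * T) / ((1 - f) * T),  # slow glacial decline
    )
    return co2


def make_forcing(spec: Optional[SyntheticForcingSpec] = None) -> ForcingSeries:
    """Deterministic synthetic precession + CO2 forcing on the recipe's grid."""
    spec = spec or SyntheticForcingSpec()
    old, young = spec.window
    n = int(round((old - young) / spec.timestep)) + 1
    t = old - spec.timestep * np.arange(n)
    P = _precession(spec, t)
    F = co2_to_forcing(_co2(spec, t))
    return ForcingSeries(t, P, F)


# ----------------------------------------------------------------------
# truth study
# ----------------------------------------------------------------------

#: A plausible "truth" member; its rainfall offset a is retuned by
#: :func:`make_truth_study` and should be read from the returned study.
DEFAULT_TRUTH_PARAMS = ModelParams(
    a=-0.45, b=-12.0, c=0.35, d=1.0, tau_v=20.0, tau_N=5.0, sigma=0.6
)


@dataclass
class TruthStudy:
    """A synthetic experiment with fully known ground truth."""

    forcing: ForcingSeries
    params: ModelParams          # truth parameters, with the tuned offset a
    seed: int                    # seed of the truth member's noise stream
    trajectory: Trajectory       # truth run over the full window
    proxy: pd.DataFrame          # columns time_yrBP, value: noisy stand-in trace
    state_table: pd.DataFrame    # 500-yr wet/moderate/dry classification
    collapse_date: Optional[float]    # ground-truth proxy collapse (years BP)
    collapse_t_star: Optional[float]  # truth member's threshold time (years BP)
    n_green_events: int          # green episodes in the screening window


def _count_events(
    params: ModelParams,
    forcing: ForcingSeries,
    window: Tuple[float, float],
    seed: int,
    detector_kwargs: dict,
) -> Tuple[int, Trajectory]:
    traj = simulate(params, forcing, SimulationConfig(seed=seed))
    mask = (traj.time <= window[0]) & (traj.time >= window[1])
    sub = Trajectory(traj.time[mask], traj.v[mask], traj.N[mask])
    return len(detect_green_events(sub, **detector_kwargs)), traj


def make_truth_study(
    spec: Optional[SyntheticForcingSpec] = None,
    truth_params: ModelParams = DEFAULT_TRUTH_PARAMS,
    n_events_target: int = 6,
    *,
    seed: int = 0,
    proxy_noise_sd: float = 0.2,
    proxy_step: float = 100.0,
    screening_window: Tuple[float, float] = (230000.0, 20000.0),
    table_window: Tuple[float, float] = (15000.0, 500.0),
    wet_threshold: float = 0.3,
    dry_threshold: float = -0.3,
    detector_kwargs: Optional[dict] = None,
    max_iter: int = 60,
) -> TruthStudy:
    """Tune the truth member to a prescribed green-episode count and emit fixtures.

    The rainfall offset ``a`` of ``truth_params`` is adjusted — coarse scan
    over the admissible range, then bisection on the (stepwise) event count —
    until the truth member's simulation shows exactly ``n_events_target``
    green episodes inside ``screening_window``.  The returned study carries
    the tuned parameters, the truth trajectory, a noisy proxy trace
    (truth v sampled every ``proxy_step`` years plus N(0, proxy_noise_sd)
    white noise), and a 500-yr state table classifying boxcar-smoothed truth
    v as wet (> ``wet_threshold``), dry (< ``dry_threshold``) or moderate,
    with its ground-truth collapse date attached.

    Raises
    ------
    RuntimeError
        If no offset reaching the target count is found within ``max_iter``
        event-count evaluations (infeasible spec).
    """
    spec = spec or SyntheticForcingSpec()
    forcing = make_forcing(spec)
    det = detector_kwargs or {}

    # --- tune the offset a ------------------------------------------------
    evals = 0

    def count_at(a: float) -> int:
        nonlocal evals
        evals += 1
        if evals > max_iter:
            raise RuntimeError(
                f"no offset with exactly {n_events_target} green episodes "
                f"found in {max_iter} evaluations"
            )
        n, _ = _count_events(
            truth_params.replace(a=a), forcing, screening_window, seed, det
        )
        return n

    grid = np.linspace(-1.6, 0.4, 21)
    counts = []
    a_star = None
    for a in grid:
        n = count_at(float(a))
        counts.append(n)
        if n == n_events_target:
            a_star = float(a)
            break
    if a_star is None:
        # bisect between adjacent scan points straddling the target
        lo = hi = n_lo = None
        for (a0, n0), (a1, n1) in zip(zip(grid, counts), zip(grid[1:], counts[1:])):
            if (n0 - n_events_target) * (n1 - n_events_target) < 0:
                lo, hi, n_lo = float(a0), float(a1), n0
                break
        if lo is None:
            raise RuntimeError(
                f"event count never reaches {n_events_target} over the scanned offsets"
            )
        while True:
            mid = 0.5 * (lo + hi)
            n = count_at(mid)
            if n == n_events_target:
                a_star = mid
                break
            if (n - n_events_target) * (n_lo - n_events_target) > 0:
                lo = mid
            else:
                hi = mid

    params = truth_params.replace(a=a_star)
    n_green, traj = _count_events(params, forcing, screening_window, seed, det)

    # --- proxy trace ------------------------------------------------------
    k = max(1, int(round(proxy_step / spec.timestep)))
    t_proxy = traj.time[::k]
    rng = np.random.default_rng(seed + 1)
    noise = rng.standard_normal(t_proxy.size) * proxy_noise_sd
    proxy = pd.DataFrame({"time_yrBP": t_proxy, "value": traj.v[::k] + noise})

    # --- state table ------------------------------------------------------
    smooth = int(round(det.get("smooth_window", 1000.0) / spec.timestep))
    sm = uniform_filter1d(traj.v, size=max(1, smooth), mode="nearest")
    bins = np.arange(table_window[0], table_window[1] - 1e-9, -500.0)
    idx = np.searchsorted(-traj.time, -bins)
    states = np.where(sm[idx] > wet_threshold, "wet",
                      np.where(sm[idx] < dry_threshold, "dry", "moderate"))
    state_table = pd.DataFrame(
        {
            "record_id": "truth",
            "region": "Central Sahara",
            "lat": 20.0,
            "lon": 10.0,
            "bin_start_yrBP": bins,
            "state": states,
        }
    )
    collapse_date = date_collapse(state_table) if "wet" in states else None

    holocene = forcing.slice(20000.0, forcing.youngest)
    t_star = select_collapse_time(
        threshold_times(params, holocene), (holocene.oldest, holocene.youngest)
    )
    return TruthStudy(
        forcing=forcing,
        params=params,
        seed=seed,
        trajectory=traj,
        proxy=proxy,
        state_table=state_table,
        collapse_date=collapse_date,
        collapse_t_star=t_star,
        n_green_events=n_green,
    )


# ----------------------------------------------------------------------
# proxy-state tables with prescribed collapse dates
# ----------------------------------------------------------------------

def make_proxy_state_table(
    collapse_dates: Dict[str, float],
    window: Tuple[float, float] = (12000.0, 500.0),
    latitudes: Optional[Dict[str, float]] = None,
    regions: Optional[Dict[str, str]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A multi-record state table whose collapse dates are known exactly.

    Each record is wet from the oldest bin up to (but excluding) its
    prescribed collapse date, then non-wet onward — the first non-wet bin
    alternates deterministically between 'moderate' and 'dry' per record, the
    rest are 'dry'.  Applying the first-non-wet dating rule therefore
    recovers ``collapse_dates`` exactly (ground truth by construction).

    collapse_dates : record_id -> collapse bin start (years BP, on the
        500-yr grid, strictly inside the window).
    """
    old, young = window
    bins = np.arange(old, young - 1e-9, -500.0)
    rows = []
    for i, (rid, cdate) in enumerate(sorted(collapse_dates.items())):
        if cdate not in bins or cdate == old:
            raise ValueError(
                f"collapse date {cdate} for {rid!r} must be a 500-yr bin inside the window"
            )
        first_nonwet_state = "moderate" if i % 2 == 0 else "dry"
        for b in bins:
            if b > cdate:
                state = "wet"
            elif b == cdate:
                state = first_nonwet_state
            else:
                state = "dry"
            rows.append(
                {
                    "record_id": rid,
                    "region": (regions or {}).get(rid, "Central Sahara"),
                    "lat": (latitudes or {}).get(rid, 20.0),
                    "lon": 10.0,
                    "bin_start_yrBP": float(b),
                    "state": state,
                }
            )
    return pd.DataFrame(rows)
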