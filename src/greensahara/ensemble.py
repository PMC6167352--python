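"""Large-ensemble parameter screening and the sensitivity pipeline.

The seven model parameters cannot be constrained individually, so a large
ensemble is drawn from uniform ranges and screened against the one robust
observation of the past two glacial cycles: the number of green (humid)
episodes, counted from Mediterranean sapropels.  Members are run over
230-20 ka; a member is retained as "not implausible" exactly when its
simulated vegetation exhibits the required number of green episodes
(six, by default).  Retained members are then integrated forward to the
present day on the same noise stream, their Holocene green episode and
collapse threshold time recorded, and the per-century sensitivity SS(t)
assembled.

Screening matches only the *number* of prior humid periods, never their
timing — dating errors on pre-Holocene humid periods are of order millennia,
so event counts are the only defensible constraint.

An alternative conditioning is provided by :func:`correlation_subset`,
which ranks members by squared Pearson correlation against a proxy trace
(e.g. sapropel Ba/Al) and keeps the top k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter1d

from .dynamics import ModelParams, SimulationConfig, Trajectory, simulate
from .equilibrium import (
    COLLAPSE,
    ONSET,
    SensitivitySeries,
    ThresholdEvent,
    select_collapse_time,
    sensitivity,
    threshold_times,
)
from .forcing import ForcingSeries

__all__ = [
    "ParamRanges",
    "GreenEvent",
    "MemberRecord",
    "DEFAULT_RANGES",
    "sample_params",
    "detect_green_events",
    "screen_ensemble",
    "extend_holocene",
    "run_pipeline",
    "sensitivity_from_records",
    "replicate_experiment",
    "correlation_subset",
    "records_to_frame",
]

logger = logging.getLogger("greensahara")

_PARAM_NAMES = ("a", "b", "c", "d", "tau_v", "tau_N", "sigma")


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling interval (low, high) for each model parameter.

    The defaults are engineering choices, not published values: signs are
    chosen so that precession minima and high CO2 favour the green state
    (b < 0, c > 0), the background rainfall a + bP + cF is generally below
    zero (a mostly negative), and the feedback range brackets the 0.8-1.2
    band used in earlier work.  All ranges are configuration and can be
    loaded from YAML (one ``low``/``high`` pair per parameter).
    """

    a: Tuple[float, float] = (-2.0, 0.5)
    b: Tuple[float, float] = (-40.0, 0.0)
    c: Tuple[float, float] = (0.0, 1.0)
    d: Tuple[float, float] = (0.5, 1.5)
    tau_v: Tuple[float, float] = (5.0, 100.0)
    tau_N: Tuple[float, float] = (1.0, 20.0)
    sigma: Tuple[float, float] = (0.1, 2.0)

    def __post_init__(self):
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"range for {name} must satisfy low < high")
        if self.tau_v[0] <= 0 or self.tau_N[0] <= 0:
            raise ValueError("timescale ranges must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ParamRanges":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kw = {k: (float(v["low"]), float(v["high"])) for k, v in raw.items()}
        return cls(**kw)

    def to_yaml(self, path) -> None:
        raw = {k: {"low": getattr(self, k)[0], "high": getattr(self, k)[1]}
               for k in _PARAM_NAMES}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


DEFAULT_RANGES = ParamRanges()


@dataclass(frozen=True)
class GreenEvent:
    """A green (humid) episode: start is the older bound, in years BP."""

    start: float
    end: float

    def __post_init__(self):
        if self.start <= self.end:
            raise ValueError("start must be older (larger years BP) than end")

    @property
    def duration(self) -> float:
        return self.start - self.end


@dataclass
class MemberRecord:
    """One ensemble member and everything screening learned about it."""

    member_id: int
    params: ModelParams
    seed: int
    green_events: List[GreenEvent] = field(default_factory=list)
    plausible: bool = False
    holocene_green_event: Optional[GreenEvent] = None
    collapse_t_star: Optional[float] = None
    never_leaves_green: bool = False
    holocene_events: List[ThresholdEvent] = field(default_factory=list)
    trajectory: Optional[Trajectory] = None  # thinned, if requested
    # continuation state: (v, N) at the end of screening, plus the live RNG
    state: Optional[Tuple[float, float]] = field(default=None, repr=False)
    rng: Optional[np.random.Generator] = field(default=None, repr=False)


# ----------------------------------------------------------------------
# parameter sampling
# ----------------------------------------------------------------------

def sample_params(
    n: int,
    ranges: ParamRanges = DEFAULT_RANGES,
    seed: Optional[int] = None,
) -> List[ModelParams]:
    """Draw n independent parameter vectors, each coordinate uniform on its range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in _PARAM_NAMES:
        lo, hi = getattr(ranges, name)
        cols[name] = rng.uniform(lo, hi, size=n)
    return [ModelParams(**{k: float(cols[k][i]) for k in _PARAM_NAMES}) for i in range(n)]


# ----------------------------------------------------------------------
# green-episode detection
# ----------------------------------------------------------------------

def detect_green_events(
    traj: Trajectory,
    smooth_window: float = 1000.0,
    min_duration: float = 2000.0,
    merge_gap: float = 2000.0,
) -> List[GreenEvent]:
    """Millennial green episodes of a trajectory.

    The vegetation series is boxcar-smoothed over ``smooth_window`` years,
    times with smoothed v > 0 are marked green, green intervals separated by
    gaps shorter than ``merge_gap`` are merged, and events shorter than
    ``min_duration`` are dropped.  The defaults (1, 2 and 2 kyr) treat humid
    episodes as millennial features, like sapropels, and suppress
    noise-flicker crossings.
    """
    t = traj.time
    if t.size < 2:
        raise ValueError("trajectory too short for event detection")
    dt = float(t[0] - t[1])
    size = max(1, int(round(smooth_window / dt)))
    if size > t.size:
        raise ValueError("smooth_window longer than the trajectory")
    sm = uniform_filter1d(np.asarray(traj.v, dtype=float), size=size, mode="nearest")
    green = sm > 0.0

    # runs of consecutive green samples, as index pairs [i, j] inclusive
    starts = list(np.flatnonzero(np.diff(np.r_[0, green.astype(np.int8)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[green.astype(np.int8), 0]) == -1))
    runs = list(zip(starts, ends))

    # merge runs separated by short gaps
    merged: List[List[int]] = []
    gap_steps = merge_gap / dt
    for i, j in runs:
        if merged and (i - merged[-1][1] - 1) < gap_steps:
            merged[-1][1] = j
        else:
            merged.append([i, j])

    min_steps = min_duration / dt
    return [
        GreenEvent(float(t[i]), float(t[j]))
        for i, j in merged
        if (j - i) >= min_steps
    ]


# ----------------------------------------------------------------------
# screening and Holocene extension
# ----------------------------------------------------------------------

def screen_ensemble(
    members: Sequence[ModelParams],
    forcing: ForcingSeries,
    required_events: int = 6,
    base_seed: int = 0,
    *,
    config: Optional[SimulationConfig] = None,
    member_seeds: Optional[Sequence[int]] = None,
    detector_kwargs: Optional[dict] = None,
    thin: int = 0,
    log_every: int = 10000,
) -> List[MemberRecord]:
    """Run every member over the screening window and flag the plausible ones.

    Each member is simulated once with its own seed (``base_seed +
    member_id`` unless ``member_seeds`` is given), green episodes are counted
    on the simulated vegetation, and the member is plausible exactly when the
    count equals ``required_events``.  The result is independent of member
    evaluation order.

    thin : if > 0, keep every ``thin``-th trajectory sample on the record
        (for later correlation against proxy traces); 0 stores nothing.
    """
    config = config or SimulationConfig()
    det = detector_kwargs or {}
    records: List[MemberRecord] = []
    retained = 0
    for mid, params in enumerate(members):
        seed = int(member_seeds[mid]) if member_seeds is not None else base_seed + mid
        rng = np.random.default_rng(seed)
        traj = simulate(params, forcing, config, rng=rng)
        events = detect_green_events(traj, **det)
        plausible = len(events) == required_events
        retained += plausible
        rec = MemberRecord(
            member_id=mid,
            params=params,
            seed=seed,
            green_events=events,
            plausible=plausible,
            state=(float(traj.v[-1]), float(traj.N[-1])),
            rng=rng,
        )
        if thin:
            rec.trajectory = traj.thin(thin)
        records.append(rec)
        if log_every and (mid + 1) % log_every == 0:
            logger.info("screened %d members, %d retained", mid + 1, retained)
    return records


def extend_holocene(
    records: Sequence[MemberRecord],
    forcing: ForcingSeries,
    *,
    config: Optional[SimulationConfig] = None,
    detector_kwargs: Optional[dict] = None,
    thin: int = 0,
) -> List[MemberRecord]:
    """Integrate plausible members forward over the Holocene forcing.

    Each plausible member continues from its stored end state on the *same*
    noise stream (no re-randomisation).  Records gain the member's Holocene
    green episode (the oldest detected one), its collapse threshold time
    (first collapse-direction crossing of the background rainfall after the
    last onset), and the never-leaves-green flag (green to the end of the
    window with no collapse crossing).  Implausible members pass through
    unchanged.
    """
    config = config or SimulationConfig()
    det = dict(detector_kwargs or {})
    smooth = det.get("smooth_window", 1000.0)
    for rec in records:
        if not rec.plausible:
            continue
        if rec.state is None or rec.rng is None:
            raise ValueError(f"member {rec.member_id} carries no continuation state")
        traj = simulate(rec.params, forcing, config, rng=rec.rng, initial=rec.state)
        h_events = detect_green_events(traj, **det)
        rec.holocene_green_event = h_events[0] if h_events else None
        rec.holocene_events = threshold_times(rec.params, forcing)
        rec.collapse_t_star = select_collapse_time(
            rec.holocene_events, (forcing.oldest, forcing.youngest)
        )
        green_to_end = bool(h_events) and h_events[-1].end <= forcing.youngest + smooth
        rec.never_leaves_green = green_to_end and rec.collapse_t_star is None
        rec.state = (float(traj.v[-1]), float(traj.N[-1]))
        if thin and rec.trajectory is not None:
            ext = traj.thin(thin)
            rec.trajectory = Trajectory(
                np.concatenate([rec.trajectory.time, ext.time[1:]]),
                np.concatenate([rec.trajectory.v, ext.v[1:]]),
                np.concatenate([rec.trajectory.N, ext.N[1:]]),
            )
        elif thin:
            rec.trajectory = traj.thin(thin)
    return list(records)


def run_pipeline(
    forcing: ForcingSeries,
    n_members: int,
    *,
    ranges: ParamRanges = DEFAULT_RANGES,
    base_seed: int = 0,
    split: float = 20000.0,
    required_events: int = 6,
    config: Optional[SimulationConfig] = None,
    detector_kwargs: Optional[dict] = None,
    thin: int = 0,
    params_override: Optional[Mapping[int, ModelParams]] = None,
) -> List[MemberRecord]:
    """Sample, screen over [oldest, split] ka BP, and extend over [split, 0].

    Convenience wrapper chaining :func:`sample_params`,
    :func:`screen_ensemble` and :func:`extend_holocene` on a forcing series
    that covers both windows.  ``params_override`` replaces selected members'
    parameters (e.g. to plant a known truth member) before screening.
    """
    params = sample_params(n_members, ranges, seed=base_seed)
    if params_override:
        for mid, p in params_override.items():
            params[mid] = p
    screening = forcing.slice(forcing.oldest, split)
    holocene = forcing.slice(split, forcing.youngest)
    records = screen_ensemble(
        params, screening, required_events, base_seed,
        config=config, detector_kwargs=detector_kwargs, thin=thin,
    )
    return extend_holocene(
        records, holocene, config=config, detector_kwargs=detector_kwargs, thin=thin
    )


def sensitivity_from_records(
    records: Sequence[MemberRecord],
    window: Tuple[float, float] = (15000.0, 0.0),
    direction: str = COLLAPSE,
    bin_width: float = 100.0,
    selection: str = "auto",
) -> SensitivitySeries:
    """SS(t) over the plausible members of a screened-and-extended ensemble."""
    events = [r.holocene_events for r in records if r.plausible]
    return sensitivity(events, window, direction, bin_width, selection)


def replicate_experiment(
    forcing: ForcingSeries,
    n_members: int,
    n_replicates: int = 20,
    base_seed: int = 0,
    *,
    ranges: ParamRanges = DEFAULT_RANGES,
    window: Tuple[float, float] = (15000.0, 0.0),
    bin_width: float = 100.0,
    **pipeline_kwargs,
) -> Tuple[List[SensitivitySeries], List[float]]:
    """Re-run the whole pipeline with fresh random parameter draws.

    Each replicate uses an independent seed block, so parameter draws and
    noise streams never overlap between replicates, and identical
    ``base_seed`` reproduces identical output.  Returns the per-replicate
    collapse-direction sensitivity series and the list of their peak-century
    locations (years BP), whose spread measures the robustness of the timing.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    series: List[SensitivitySeries] = []
    peaks: List[float] = []
    for rep in range(n_replicates):
        rep_seed = base_seed + rep * (n_members + 1)
        records = run_pipeline(
            forcing, n_members, ranges=ranges, base_seed=rep_seed, **pipeline_kwargs
        )
        ss = sensitivity_from_records(records, window, COLLAPSE, bin_width)
        series.append(ss)
        peaks.append(ss.peak_bin())
        logger.info("replicate %d/%d: peak century %.0f yr BP", rep + 1, n_replicates, peaks[-1])
    return series, peaks


# ----------------------------------------------------------------------
# best-correlated subset (Ba/Al conditioning)
# ----------------------------------------------------------------------

def correlation_subset(
    trajectories: Mapping[int, Trajectory],
    observed: Union[pd.DataFrame, Tuple[np.ndarray, np.ndarray]],
    k: int = 1500,
) -> List[int]:
    """IDs of the k members best correlated (highest R^2) with a proxy trace.

    Each member's vegetation series is linearly interpolated onto the
    observation grid (restricted to the overlap) and the squared Pearson
    correlation computed; a constant member series has R^2 defined as 0.
    Ties are broken by member id.
    """
    if isinstance(observed, pd.DataFrame):
        t_obs = observed.iloc[:, 0].to_numpy(dtype=float)
        y_obs = observed.iloc[:, 1].to_numpy(dtype=float)
    else:
        t_obs, y_obs = (np.asarray(x, dtype=float) for x in observed)
    if k > len(trajectories):
        raise ValueError("k exceeds the number of member trajectories")

    scored = []
    for mid, traj in trajectories.items():
        lo, hi = traj.time[-1], traj.time[0]
        mask = (t_obs >= lo) & (t_obs <= hi)
        if mask.sum() < 3:
            raise ValueError(f"member {mid} does not overlap the observations")
        tt, yy = t_obs[mask], y_obs[mask]
        v = np.interp(tt[::-1], traj.time[::-1], traj.v[::-1])[::-1]
        if np.std(v) == 0.0 or np.std(yy) == 0.0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(v, yy)[0, 1]) ** 2
        scored.append((-r2, mid))
    scored.sort()
    return [mid for _, mid in scored[:k]]


# ----------------------------------------------------------------------
# tabular output
# ----------------------------------------------------------------------

def records_to_frame(records: Sequence[MemberRecord]) -> pd.DataFrame:
    """Flatten records to the members table (one row per member)."""
    rows = []
    for r in records:
        row = {"member_id": r.member_id}
        row.update({k: getattr(r.params, k) for k in _PARAM_NAMES})
        row.update(
            seed=r.seed,
            n_green_230_20=len(r.green_events),
            plausible=r.plausible,
            collapse_t_star_yrBP=r.collapse_t_star,
            never_leaves_green=r.never_leaves_green,
        )
        rows.append(row)
    return pd.DataFrame(rows)
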