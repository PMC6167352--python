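"""Dating the end of the humid period from proxy-state compilations.

Palaeoclimate compilations for northern Africa classify each record's
hydroclimate state — wet, moderate or dry — at 500-year intervals (the
classification itself is subjective and done upstream; it is consumed here,
never re-derived).  The collapse of the humid period is dated, per record,
as the first time at which humid conditions are no longer present: scanning
forward in time from the record's earliest wet bin, the start of the first
bin whose state is not wet.  'Humid' means the state 'wet' only by default —
'moderate' reads as semi-arid — but the humid vocabulary is configurable.

A histogram of per-record collapse dates on the 500-year grid is the
observational counterpart of the model's simulated-sensitivity series.
Records south of a latitude cut (13.42 degrees N by default, the most
southerly archaeological site in the population reconstruction the
histogram is compared against) can be excluded.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "SOUTHERN_LATITUDE_CUT",
    "date_collapse",
    "collapse_histogram",
    "validate_state_table",
]

STATES = ("wet", "moderate", "dry")

#: Default southern exclusion latitude (degrees N).
SOUTHERN_LATITUDE_CUT = 13.42


def validate_state_table(table: pd.DataFrame, bin_width: float = 500.0) -> None:
    """Check a proxy-state table: vocabulary and per-record uniform grid.

    Expected columns: record_id, region, lat, lon, bin_start_yrBP, state
    (region/lat/lon optional unless filtering is requested).
    """
    required = {"record_id", "bin_start_yrBP", "state"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"state table missing columns: {sorted(missing)}")
    bad = set(table["state"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown states {sorted(bad)}; allowed: {STATES}")
    for rid, grp in table.groupby("record_id"):
        bins = np.sort(grp["bin_start_yrBP"].to_numpy(dtype=float))
        if bins.size > 1 and not np.allclose(np.diff(bins), bin_width):
            raise ValueError(f"record {rid!r} is not on a uniform {bin_width}-yr grid")


def date_collapse(
    record: Union[pd.DataFrame, Sequence[Tuple[float, str]]],
    humid_states: Iterable[str] = ("wet",),
) -> Optional[float]:
    """Collapse date of one record: first non-humid bin after the first humid bin.

    ``record`` is either a DataFrame with columns ``bin_start_yrBP`` and
    ``state`` or a sequence of (bin_start, state) pairs; it is sorted
    oldest -> youngest internally, so input order does not matter.  Scanning
    forward in time from the earliest humid bin, the returned date is the
    ``bin_start`` of the first bin whose state is not humid.  Returns
    ``None`` (with a warning for the no-humid case) when the record never
    shows humid conditions, or never leaves them.

    The result is insensitive to anything after the first non-humid bin
    found, and idempotent under re-application.
    """
    if isinstance(record, pd.DataFrame):
        pairs = list(zip(record["bin_start_yrBP"].astype(float), record["state"]))
    else:
        pairs = [(float(t), s) for t, s in record]
    pairs.sort(key=lambda p: -p[0])  # oldest first
    humid = set(humid_states)

    first_wet = next((i for i, (_, s) in enumerate(pairs) if s in humid), None)
    if first_wet is None:
        warnings.warn("record contains no humid bin; no collapse date defined")
        return None
    for t, s in pairs[first_wet:]:
        if s not in humid:
            return t
    return None  # humid to the end of the record


def collapse_histogram(
    table: pd.DataFrame,
    bin_width: float = 500.0,
    region: Optional[str] = None,
    min_latitude: Optional[float] = None,
    humid_states: Iterable[str] = ("wet",),
) -> pd.Series:
    """Per-bin counts of record collapse dates.

    Returns a Series indexed by ``bin_start_yrBP`` (oldest first, zero-filled
    between the extreme dates); its sum equals the number of records with a
    defined collapse date after filtering.

    region : keep only records with this region label.
    min_latitude : drop records south of this latitude (requires a ``lat``
        column); pass :data:`SOUTHERN_LATITUDE_CUT` for the default cut.
    """
    validate_state_table(table, bin_width)
    df = table
    if region is not None:
        df = df[df["region"] == region]
    if min_latitude is not None:
        if "lat" not in df.columns:
            raise ValueError("latitude filtering requires a 'lat' column")
        df = df[df["lat"] >= min_latitude]

    dates = []
    for rid, grp in df.groupby("record_id"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = date_collapse(grp, humid_states)
        if d is not None:
            dates.append(d)
    if not dates:
        return pd.Series(dtype=int, name="n_collapses").rename_axis("bin_start_yrBP")
    dates = np.asarray(dates, dtype=float)
    oldest, youngest = dates.max(), dates.min()
    index = np.arange(oldest, youngest - bin_width / 2, -bin_width)
    counts = pd.Series(0, index=pd.Index(index, name="bin_start_yrBP"), name="n_collapses")
    for d in dates:
        counts.loc[d] += 1
    return counts
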