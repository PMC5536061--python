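"""Real-time cell-index (impedance) analytics.

The cell index (CI) from an xCELLigence-style analyzer reflects electrode
surface occupancy — cell number, size and adhesion combined.  This module
computes the standard derived quantities:

* delta cell index, ``(CI(t) - CI(t_treat)) / CI(t_treat)``, which
  normalizes each well to its own state at treatment time and is invariant
  to uniform rescaling of the trace;
* the linear-phase proliferation slope (CI units per hour) with an
  automatic window search, and the doubling time under either a linear
  convention (reference CI / slope) or an exponential one
  (ln 2 / log-scale slope);
* dose-response summaries of delta CI across replicate wells (mean ± SEM,
  Student t-test against the vehicle group);
* AdipoRed/Hoechst fluorescence ratios for triglyceride storage,
  normalized per well so common multiplicative well effects cancel.

Time is in hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationError, ValidationError


@dataclass(frozen=True)
class RtcaTrace:
    """Time-aligned cell-index traces for the replicate wells of one condition."""

    times: np.ndarray           # hours since plating, strictly increasing
    cell_index: np.ndarray      # shape (n_wells, n_times)
    well_ids: tuple[str, ...]
    condition: str = ""
    dose_uM: float = 0.0
    t_treat: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ci = np.atleast_2d(np.asarray(self.cell_index, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cell_index", ci)
        object.__setattr__(self, "well_ids", tuple(self.well_ids))
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("trace needs at least two time points")
        if np.any(times < 0):
            raise ValidationError("negative times are not allowed")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if ci.shape != (len(self.well_ids), times.size):
            raise ValidationError(
                f"cell_index shape {ci.shape} does not match "
                f"{len(self.well_ids)} wells x {times.size} times"
            )
        if not np.all(np.isfinite(ci)):
            raise ValidationError("cell index values must be finite")

    @property
    def n_wells(self) -> int:
        return len(self.well_ids)

    def mean_ci(self) -> np.ndarray:
        """Mean cell index across wells at each time point."""
        return self.cell_index.mean(axis=0)

    @classmethod
    def from_long(cls, df: pd.DataFrame, condition: str = "", dose_uM: float = 0.0,
                  t_treat: float | None = None) -> "RtcaTrace":
        """Build a trace from a long table with columns time_h, well, cell_index."""
        required = {"time_h", "well", "cell_index"}
        if not required.issubset(df.columns):
            raise ValidationError(f"trace table needs columns {sorted(required)}")
        wide = df.pivot(index="well", columns="time_h", values="cell_index").sort_index()
        if wide.isna().any().any():
            raise ValidationError("trace table has missing well/time combinations")
        return cls(
            times=wide.columns.to_numpy(dtype=float),
            cell_index=wide.to_numpy(dtype=float),
            well_ids=tuple(str(w) for w in wide.index),
            condition=condition,
            dose_uM=dose_uM,
            t_treat=t_treat,
        )


@dataclass(frozen=True)
class DeltaTrace:
    """Treatment-normalized cell index; delta is exactly 0 at t_treat."""

    times: np.ndarray
    delta: np.ndarray           # shape (n_wells, n_times)
    well_ids: tuple[str, ...]
    t_treat: float
    condition: str = ""
    dose_uM: float = 0.0

    def at(self, t: float) -> np.ndarray:
        """Per-well delta at the nearest sampled time at or before t."""
        i = _index_at_or_before(self.times, t)
        return self.delta[:, i]


def _index_at_or_before(times: np.ndarray, t: float) -> int:
    """RTCA sampling is discrete; map a requested time to the nearest
    sample at or before it."""
    i = int(np.searchsorted(times, t, side="right")) - 1
    if i < 0 or t > times[-1]:
        raise ValidationError(f"time {t} h is outside the trace span "
                              f"[{times[0]}, {times[-1]}] h")
    return i


def delta_cell_index(trace: RtcaTrace, t_treat: float | None = None) -> DeltaTrace:
    """Delta cell index per well: (CI(t) - CI(t0)) / CI(t0) with t0 the
    nearest sample at or before the treatment time."""
    if t_treat is None:
        t_treat = trace.t_treat
    if t_treat is None:
        raise ValidationError("treatment time is required for delta cell index")
    i0 = _index_at_or_before(trace.times, t_treat)
    ci0 = trace.cell_index[:, i0]
    bad = np.isclose(ci0, 0.0)
    if np.any(bad):
        wells = [trace.well_ids[j] for j in np.flatnonzero(bad)]
        raise ValidationError(
            f"cell index at treatment time is zero for wells {wells}; delta undefined"
        )
    delta = (trace.cell_index - ci0[:, None]) / ci0[:, None]
    return DeltaTrace(
        times=trace.times, delta=delta, well_ids=trace.well_ids,
        t_treat=float(trace.times[i0]), condition=trace.condition, dose_uM=trace.dose_uM,
    )


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares line on the well-averaged CI over a time window."""

    slope: float                # CI units per hour
    intercept: float
    window: tuple[float, float]
    r2: float
    n_points: int
    mean_ci: float              # mean CI over the fit window (linear doubling reference)
    log_scale: bool = False


def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) @ (y - y.mean())))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), min(max(r2, 0.0), 1.0)


def linear_phase_slope(
    trace: RtcaTrace,
    window: tuple[float, float] | None = None,
    min_length_h: float = 12.0,
    r2_min: float = 0.98,
    log_scale: bool = False,
) -> SlopeFit:
    """Proliferation-rate slope of the linear phase of the mean CI.

    With an explicit ``window`` the line is fit there directly.  Otherwise
    the longest window of at least ``min_length_h`` hours whose fit reaches
    ``r2_min`` is selected (ties broken by the better fit).  With
    ``log_scale`` the fit is on ln(CI) (for the exponential doubling-time
    convention); all CI values in the window must then be positive.
    """
    t = trace.times
    y = trace.mean_ci()
    if log_scale:
        if np.any(y <= 0):
            raise ValidationError("log-scale fit requires positive cell index")
        yfit = np.log(y)
    else:
        yfit = y

    def make_fit(i: int, j: int) -> SlopeFit:
        slope, intercept, r2 = _fit_line(t[i:j + 1], yfit[i:j + 1])
        return SlopeFit(
            slope=slope, intercept=intercept, window=(float(t[i]), float(t[j])),
            r2=r2, n_points=j - i + 1, mean_ci=float(y[i:j + 1].mean()),
            log_scale=log_scale,
        )

    if window is not None:
        t0, t1 = window
        if t0 >= t1:
            raise ValidationError("window start must precede window end")
        mask = (t >= t0) & (t <= t1)
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            raise ValidationError("at least 3 samples are needed in the fit window")
        return make_fit(int(idx[0]), int(idx[-1]))

    best: SlopeFit | None = None
    m = t.size
    for i in range(m):
        for j in range(m - 1, i + 1, -1):
            if t[j] - t[i] < min_length_h:
                break
            if best is not None and (t[j] - t[i]) < (best.window[1] - best.window[0]):
                break
            fit = make_fit(i, j)
            if fit.r2 < r2_min:
                continue
            length = fit.window[1] - fit.window[0]
            if best is None or length > (best.window[1] - best.window[0]) or (
                length == (best.window[1] - best.window[0]) and fit.r2 > best.r2
            ):
                best = fit
    if best is None:
        raise ComputationError(
            f"no window of >= {min_length_h} h reaches r2 >= {r2_min}; "
            "supply an explicit window"
        )
    return best


def doubling_time(fit: SlopeFit, convention: str = "linear",
                  ref_ci: float | None = None) -> float:
    """Doubling time in hours from a slope fit.

    ``linear``: time for the line to add one reference CI (ref_ci/slope;
    default reference is the mean CI over the fit window — the reference
    is explicit because the same slope maps to different doubling times
    depending on where it is read).  ``exponential``: ln2 / slope of a
    log-scale fit.
    """
    if convention == "linear":
        if fit.log_scale:
            raise ValidationError("linear doubling time needs a linear-scale fit")
        if fit.slope <= 0:
            raise ComputationError("non-positive slope: no doubling")
        ref = fit.mean_ci if ref_ci is None else ref_ci
        if ref <= 0:
            raise ValidationError("reference cell index must be positive")
        return ref / fit.slope
    if convention == "exponential":
        if not fit.log_scale:
            raise ValidationError("exponential doubling time needs a log-scale fit")
        if fit.slope <= 0:
            raise ComputationError("non-positive growth rate: no doubling")
        return float(np.log(2.0) / fit.slope)
    raise ValidationError(f"unknown doubling-time convention {convention!r}")


def dose_response_summary(
    traces_by_dose: Mapping[float, RtcaTrace],
    t_eval: float,
    t_treat: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-dose mean ± SEM of delta CI at ``t_eval`` with Student t-tests
    against the vehicle (dose 0) group.

    Every dose group needs at least two wells; a missing vehicle group is
    an error.
    """
    if 0.0 not in traces_by_dose:
        raise ValidationError("dose-response summary requires a vehicle (dose 0) group")
    deltas: dict[float, np.ndarray] = {}
    for dose, trace in traces_by_dose.items():
        if trace.n_wells < 2:
            raise ValidationError(f"dose {dose}: at least 2 wells are required")
        deltas[dose] = delta_cell_index(trace, t_treat).at(t_eval)
    vehicle = deltas[0.0]
    rows = []
    for dose in sorted(deltas):
        d = deltas[dose]
        if dose == 0.0:
            p = 1.0
        else:
            _, p = stats.ttest_ind(d, vehicle, equal_var=True)
            p = float(p)
        rows.append(
            {
                "dose_uM": dose,
                "n_wells": d.size,
                "mean_delta": float(d.mean()),
                "sem": float(d.std(ddof=1) / np.sqrt(d.size)),
                "p_value": p,
                "significant": bool(dose != 0.0 and p < alpha),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FluorWell:
    """AdipoRed (triglyceride) and Hoechst (nuclei) readings for one well."""

    well: str
    dose_uM: float
    adipored: float
    hoechst: float

    def __post_init__(self) -> None:
        if self.hoechst <= 0:
            raise ValidationError(f"well {self.well}: Hoechst signal must be positive")

    @property
    def ratio(self) -> float:
        return self.adipored / self.hoechst


def tg_storage(wells: Iterable[FluorWell], alpha: float = 0.05) -> pd.DataFrame:
    """Triglyceride storage per dose: AdipoRed/Hoechst ratio per well,
    aggregated as mean ± SEM and fold versus the vehicle (dose 0) group."""
    by_dose: dict[float, list[float]] = {}
    for w in wells:
        by_dose.setdefault(w.dose_uM, []).append(w.ratio)
    if 0.0 not in by_dose:
        raise ValidationError("triglyceride summary requires a vehicle (dose 0) group")
    vehicle_mean = float(np.mean(by_dose[0.0]))
    if vehicle_mean <= 0:
        raise ValidationError("vehicle mean ratio must be positive to express folds")
    rows = []
    for dose in sorted(by_dose):
        r = np.asarray(by_dose[dose], dtype=float)
        sem = float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else 0.0
        rows.append(
            {
                "dose_uM": dose,
                "n_wells": r.size,
                "mean_ratio": float(r.mean()),
                "sem": sem,
                "fold_vs_vehicle": float(r.mean() / vehicle_mean),
            }
        )
    return pd.DataFrame(rows)
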