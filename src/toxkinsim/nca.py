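"""Non-compartmental estimation of exposure from sparse profiles.

Composite analysis pools observations across animals and averages them
per scheduled time point (arithmetic or geometric mean); serial
analysis computes exposure per animal and averages the per-animal
values.  AUC uses the linear-logarithmic trapezoidal rule: linear
trapezoids on rising or flat segments, logarithmic trapezoids
(dC / ln(C1/C2) * dt) on strictly decreasing positive segments.  TAT
mirrors that convention — linear interpolation on rising segments,
log-linear on falling positive segments — with crossing times solved
analytically per segment.

A window anchor at t=0 is prepended when absent: zero for day-1
profiles, and the profile's own 24-h (trough) value for steady-state
days, where the end of the previous interval equals the start of the
current one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .design import Role
from .errors import InputError, InsufficientDataError
from .trial import TKDataset

__all__ = [
    "SummaryKind", "ProfileSummary", "NCAResult",
    "composite_mean_profile", "individual_profile",
    "nca_auc_linlog", "nca_cmax", "nca_tat",
    "composite_nca_summary", "serial_nca_summary",
]


class SummaryKind(str, Enum):
    ARITHMETIC = "ARITHMETIC"
    GEOMETRIC = "GEOMETRIC"
    INDIVIDUAL = "INDIVIDUAL"


@dataclass
class ProfileSummary:
    """A single summarized concentration-time profile (times in h
    relative to the evaluation day's dose)."""

    times: np.ndarray
    conc: np.ndarray
    summary_kind: SummaryKind
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InputError("profile times must be strictly increasing")
        if np.any(self.conc < 0):
            raise InputError("profile concentrations must be >= 0")


@dataclass
class NCAResult:
    """NCA-derivable exposure measures (no extrapolation beyond the
    observed window, so no 6-month quantities)."""

    auc24: float
    cmax24: float
    tat24: float
    n_animals: int
    summary_kind: SummaryKind


def _summarize(values: np.ndarray, kind: SummaryKind) -> tuple[float, int]:
    """Mean of one time point's concentrations.  The geometric mean is
    taken over positive values only (zeros excluded, count reported);
    all-zero points return 0."""
    values = np.asarray(values, dtype=float)
    if kind is SummaryKind.ARITHMETIC:
        return float(values.mean()), values.size
    pos = values[values > 0]
    if pos.size == 0:
        return 0.0, 0
    return float(np.exp(np.mean(np.log(pos)))), int(pos.size)


def _obs_for_day(ds: TKDataset, dose_group: float, day: int, role: Role) -> pd.DataFrame:
    obs = ds.observations()
    t0, t1 = 24.0 * (day - 1), 24.0 * day
    m = ((obs["DOSEGRP"] == dose_group) & (obs["ROLE"] == role.value)
         & (obs["TIME"] > t0) & (obs["TIME"] <= t1))
    return obs[m]


def _anchor(times: list[float], conc: list[float], n: list[int], day: int) -> None:
    """Prepend the t=0 window anchor in place (see module docstring)."""
    if times and times[0] == 0.0:
        return
    if day == 1:
        c0 = 0.0
    elif times and times[-1] == 24.0:
        c0 = conc[-1]  # steady state: previous interval's trough
    else:
        return  # no trough available: AUC spans the surviving grid only
    times.insert(0, 0.0)
    conc.insert(0, c0)
    n.insert(0, 0)


def composite_mean_profile(
    ds: TKDataset, dose_group: float, day: int,
    summary_kind: SummaryKind = SummaryKind.ARITHMETIC,
    role: Role = Role.TOXICITY,
) -> ProfileSummary:
    """Pooled mean profile for one dose group and evaluation day."""
    if summary_kind is SummaryKind.INDIVIDUAL:
        raise InputError("composite profiles need ARITHMETIC or GEOMETRIC summary")
    obs = _obs_for_day(ds, dose_group, day, role)
    if obs.empty:
        raise InsufficientDataError(
            f"no observations for dose {dose_group} on day {day} ({role.value})")
    rel = obs["TIME"] - 24.0 * (day - 1)
    times, conc, n = [], [], []
    for t, grp in obs.assign(_rel=rel).groupby("_rel"):
        m, k = _summarize(grp["DV"].to_numpy(), summary_kind)
        if summary_kind is SummaryKind.GEOMETRIC and k == 0:
            continue  # all-zero point dropped under the geometric rule
        times.append(float(t)); conc.append(m); n.append(k)
    _anchor(times, conc, n, day)
    return ProfileSummary(np.array(times), np.array(conc), summary_kind, np.array(n))


def individual_profile(ds: TKDataset, animal_id: int, day: int) -> ProfileSummary:
    """One animal's serial profile on an evaluation day."""
    obs = ds.observations()
    t0, t1 = 24.0 * (day - 1), 24.0 * day
    m = (obs["ID"] == animal_id) & (obs["TIME"] > t0) & (obs["TIME"] <= t1)
    sub = obs[m].sort_values("TIME")
    if sub.empty:
        raise InsufficientDataError(f"animal {animal_id} has no day-{day} samples")
    times = list((sub["TIME"] - t0).astype(float))
    conc = list(sub["DV"].astype(float))
    n = [1] * len(times)
    _anchor(times, conc, n, day)
    return ProfileSummary(np.array(times), np.array(conc),
                          SummaryKind.INDIVIDUAL, np.array(n))


# ---------------------------------------------------------------------------
# Profile-level estimators
# ---------------------------------------------------------------------------

def nca_auc_linlog(profile: ProfileSummary,
                   window: tuple[float, float] = (0.0, 24.0)) -> float:
    """Linear-logarithmic trapezoidal AUC over the observed points inside
    ``window`` (no extrapolation beyond observed points)."""
    t0, t1 = window
    m = (profile.times >= t0) & (profile.times <= t1)
    t, c = profile.times[m], profile.conc[m]
    if t.size < 2:
        raise InsufficientDataError("need at least two points in the AUC window")
    total = 0.0
    for j in range(t.size - 1):
        dt = t[j + 1] - t[j]
        c1, c2 = c[j], c[j + 1]
        if c2 < c1 and c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    return total


def nca_cmax(profile: ProfileSummary) -> tuple[float, float]:
    """Peak summarized concentration and its time (earliest on ties)."""
    if profile.times.size == 0:
        raise InsufficientDataError("empty profile")
    i = int(np.argmax(profile.conc))  # argmax returns the first maximum
    return float(profile.conc[i]), float(profile.times[i])


def _segment_time_above(t1, t2, c1, c2, thr) -> float:
    """Time above thr within one segment under the lin-up/log-down
    interpolation convention."""
    dt = t2 - t1
    falling_log = c2 < c1 and c2 > 0
    if falling_log:
        # c(t) = c1 * (c2/c1)^((t-t1)/dt): crosses thr iff thr between c2, c1
        if c1 <= thr:
            return 0.0
        if c2 > thr:
            return dt
        tc = t1 + dt * math.log(thr / c1) / math.log(c2 / c1)
        return tc - t1
    # linear interpolation (rising, flat, or falling-to-zero)
    lo, hi = min(c1, c2), max(c1, c2)
    if hi < thr or (hi == thr and lo < thr):
        return 0.0
    if lo > thr:
        return dt
    if c1 == c2:
        return dt if c1 > thr else 0.0
    tc = t1 + dt * (thr - c1) / (c2 - c1)
    return (t2 - tc) if c2 > c1 else (tc - t1)


def nca_tat(profile: ProfileSummary, threshold: float,
            window: tuple[float, float] = (0.0, 24.0)) -> float:
    """Time above ``threshold`` within the window, interpolating between
    samples with the same lin-up/log-down convention as the AUC rule."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    t0, t1 = window
    m = (profile.times >= t0) & (profile.times <= t1)
    t, c = profile.times[m], profile.conc[m]
    if t.size < 2:
        raise InsufficientDataError("need at least two points in the TAT window")
    return float(sum(
        _segment_time_above(t[j], t[j + 1], c[j], c[j + 1], threshold)
        for j in range(t.size - 1)
    ))


# ---------------------------------------------------------------------------
# Dataset-level summaries
# ---------------------------------------------------------------------------

def composite_nca_summary(
    ds: TKDataset, dose_group: float, day: int,
    summary_kind: SummaryKind, threshold: float,
    role: Role = Role.TOXICITY,
) -> NCAResult:
    """NCA on the pooled composite mean profile."""
    prof = composite_mean_profile(ds, dose_group, day, summary_kind, role)
    auc = nca_auc_linlog(prof)
    cmax, _ = nca_cmax(prof)
    tat = nca_tat(prof, threshold)
    n = len(ds.animals(dose=dose_group, role=role))
    return NCAResult(auc, cmax, tat, n, summary_kind)


def serial_nca_summary(
    ds: TKDataset, dose_group: float, day: int,
    summary_kind: SummaryKind, threshold: float,
    role: Role = Role.SATELLITE,
) -> NCAResult:
    """Per-animal NCA on serial profiles, averaged across the cohort."""
    if summary_kind is SummaryKind.INDIVIDUAL:
        raise InputError("serial summary needs ARITHMETIC or GEOMETRIC")
    animals = ds.animals(dose=dose_group, role=role)
    if not animals:
        raise InsufficientDataError(f"no {role.value} animals at dose {dose_group}")
    aucs, cmaxs, tats = [], [], []
    for aid in animals:
        prof = individual_profile(ds, aid, day)
        aucs.append(nca_auc_linlog(prof))
        cmaxs.append(nca_cmax(prof)[0])
        tats.append(nca_tat(prof, threshold))

    def avg(vals):
        return _summarize(np.array(vals), summary_kind)[0]

    return NCAResult(avg(aucs), avg(cmaxs), avg(tats), len(animals), summary_kind)
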