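"""Two-sample log-linear regression (LLR), the clinical-standard method.

A peak and a trough concentration from (or around) one dosing interval are
fit to a one-compartment steady-state infusion model:

    k  = ln(C1/C2) / dt          (dt = elapsed decay time, C1 the peak)
    Vd = D (1 - e^{-k tinf}) e^{-k (t1 - tinf)}
         / [tinf k C1 (1 - e^{-k tinterval})]
    CL = k Vd
    AUC24 = daily dose / CL

Sample classification follows the usual aminoglycoside TDM convention: a
peak is drawn within 3 h of the end of the infusion, a trough 4+ h after it.
Below-LOQ samples cannot be used and make a group not evaluable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .pk import DoseEvent, Regimen

__all__ = [
    "Observation",
    "SampleGroup",
    "LLREstimate",
    "classify_sample",
    "group_samples",
    "llr_fit",
    "llr_exposure",
    "steady_state_conc_1cmt",
    "TwoSampleLLR",
]

PEAK_WINDOW_H = 3.0  # h after end of infusion
TROUGH_MIN_H = 4.0  # h after end of infusion


@dataclass
class Observation:
    """One concentration sample; ``value`` is None when below the LOQ."""

    time: float
    value: float | None
    bloq: bool = False
    loq: float | None = None
    kind: str | None = None  # peak | trough | other | invalid; assigned

    def __post_init__(self) -> None:
        if self.bloq:
            if self.value is not None and self.loq is not None and self.value >= self.loq:
                raise ValueError("BLOQ observation with value at or above the LOQ")
        else:
            if self.value is None:
                raise ValueError("quantified observation requires a value")
            if self.loq is not None and self.value < self.loq:
                raise ValueError("quantified observation below the LOQ")


@dataclass(frozen=True)
class SampleGroup:
    """An ordered peak/trough pair anchored to a dose event.

    ``configuration`` is ``peak-then-trough`` (both samples in one dosing
    interval) or ``trough-dose-peak`` (a pre-dose trough, the dose, then its
    peak).
    """

    observations: tuple[Observation, Observation]
    anchor: DoseEvent
    configuration: str

    def __post_init__(self) -> None:
        if len(self.observations) != 2:
            raise ValueError("a sample group holds exactly two observations")
        if self.configuration not in ("peak-then-trough", "trough-dose-peak"):
            raise ValueError(f"unknown configuration {self.configuration!r}")


@dataclass(frozen=True)
class LLREstimate:
    """One-compartment (k, Vd, CL) estimate, or the reason none was possible."""

    k: float | None
    vd: float | None
    cl: float | None
    status: str  # evaluable | not-evaluable
    reason: str | None = None  # bloq-sample | mistimed | insufficient-samples | nonpositive-k

    @property
    def evaluable(self) -> bool:
        return self.status == "evaluable"


def _not_evaluable(reason: str) -> LLREstimate:
    return LLREstimate(None, None, None, "not-evaluable", reason)


def classify_sample(
    obs: Observation,
    regimen: Regimen,
    peak_window: float = PEAK_WINDOW_H,
    trough_min: float = TROUGH_MIN_H,
) -> str:
    """Classify by offset from the end of the latest prior infusion.

    Offsets in (0, peak_window] are peaks; >= trough_min are troughs; the gap
    between is "other". A sample during (or before) the infusion is
    "invalid" — such courses are excluded from LLR analysis.
    """
    dose = regimen.latest_dose_before(obs.time)
    if dose is None:
        return "invalid"
    offset = obs.time - dose.end
    if offset <= 0:
        return "invalid"
    if offset <= peak_window:
        return "peak"
    if offset >= trough_min:
        return "trough"
    return "other"


def group_samples(
    observations: Sequence[Observation], regimen: Regimen
) -> list[SampleGroup]:
    """Pair peaks with troughs into LLR groups, greedily and chronologically.

    Two configurations are recognised: a peak followed by a trough within the
    same dosing interval, and a trough followed by exactly one dose and its
    peak. Each observation joins at most one group. BLOQ samples are grouped
    on timing alone; the fit stage rejects them with a machine-readable
    reason so courses lost to censoring can be tallied.
    """
    obs = sorted(observations, key=lambda o: o.time)
    for o in obs:
        if o.kind is None:
            o.kind = classify_sample(o, regimen)
    doses = list(regimen.doses)
    anchor_of = {id(o): regimen.latest_dose_before(o.time) for o in obs}
    used: set[int] = set()
    groups: list[SampleGroup] = []
    for i, first in enumerate(obs):
        if id(first) in used:
            continue
        if first.kind == "peak":
            d = anchor_of[id(first)]
            for second in obs[i + 1 :]:
                if id(second) in used or second.kind != "trough":
                    continue
                if anchor_of[id(second)] is d:
                    groups.append(
                        SampleGroup((first, second), d, "peak-then-trough")
                    )
                    used.update((id(first), id(second)))
                    break
        elif first.kind == "trough":
            d = anchor_of[id(first)]
            if d is None:
                continue
            later = [dd for dd in doses if dd.time > first.time]
            if not later:
                continue
            nxt = later[0]
            for second in obs[i + 1 :]:
                if id(second) in used or second.kind != "peak":
                    continue
                if anchor_of[id(second)] is nxt:
                    groups.append(
                        SampleGroup((first, second), nxt, "trough-dose-peak")
                    )
                    used.update((id(first), id(second)))
                    break
    return groups


def llr_fit(group: SampleGroup, regimen: Regimen | None = None) -> LLREstimate:
    """Fit the one-compartment steady-state model to a peak/trough pair.

    For the trough-dose-peak configuration the pre-dose trough is carried
    forward one dosing interval by steady-state periodicity, so the decay
    time is tinterval - (peak offset) - (trough lead time before the dose).
    """
    first, second = group.observations
    if first.bloq or second.bloq:
        return _not_evaluable("bloq-sample")
    dose = group.anchor
    if group.configuration == "peak-then-trough":
        peak, trough = first, second
        t1 = peak.time - dose.time
        dt = trough.time - peak.time
    else:
        trough, peak = first, second
        t1 = peak.time - dose.time
        lead = dose.time - trough.time  # h the trough precedes the dose
        dt = dose.tinterval - t1 - lead
    if dt <= 0 or t1 <= 0:
        return _not_evaluable("mistimed")
    c1, c2 = peak.value, trough.value
    if c1 is None or c2 is None:
        return _not_evaluable("bloq-sample")
    if c1 <= c2:
        return _not_evaluable("nonpositive-k")
    k = math.log(c1 / c2) / dt
    tinf, tau = dose.tinf, dose.tinterval
    vd = (
        dose.amount
        * -math.expm1(-k * tinf)
        * math.exp(-k * (t1 - tinf))
        / (tinf * k * c1 * -math.expm1(-k * tau))
    )
    return LLREstimate(k=k, vd=vd, cl=k * vd, status="evaluable")


def steady_state_conc_1cmt(
    k: float,
    cl: float,
    dose: float,
    tinf: float,
    tinterval: float,
    t_offsets,
) -> np.ndarray:
    """Steady-state infusion concentrations at offsets from dose start."""
    t = np.asarray(t_offsets, dtype=float) % tinterval
    r = dose / tinf
    denom = -np.expm1(-k * tinterval)
    post = r / cl * -np.expm1(-k * tinf) * np.exp(-k * (t - tinf)) / denom
    during = r / cl * (
        -np.expm1(-k * t)
        + -np.expm1(-k * tinf) * np.exp(-k * (tinterval + t - tinf)) / denom
    )
    return np.where(t >= tinf, post, during)


def llr_exposure(
    estimate: LLREstimate,
    regimen: Regimen,
    conc_offsets: Sequence[float] = (),
) -> tuple[float, np.ndarray]:
    """AUC24 (= daily dose / CL) and steady-state predicted concentrations.

    ``conc_offsets`` are hours after a dose start at steady state.
    """
    if not estimate.evaluable:
        raise ValueError(f"estimate is not evaluable ({estimate.reason})")
    auc24 = regimen.daily_dose() / estimate.cl
    last = regimen.doses[-1]
    conc = steady_state_conc_1cmt(
        estimate.k, estimate.cl, last.amount, last.tinf, last.tinterval, conc_offsets
    ) if len(tuple(conc_offsets)) else np.array([])
    return auc24, conc


class TwoSampleLLR(BaseEstimator):
    """Two-sample log-linear regression as an estimator.

    fit() takes a treatment course (any object with ``observations`` and
    ``regimen`` attributes, or an (observations, regimen) tuple), forms
    peak/trough groups and fits each one.

    Attributes set by fit: ``groups_``, ``estimates_`` (one per group),
    ``k_``, ``vd_``, ``cl_`` (from the first evaluable group), ``status_``
    and ``reason_`` (course-level evaluability).
    """

    def __init__(self, peak_window: float = PEAK_WINDOW_H, trough_min: float = TROUGH_MIN_H):
        self.peak_window = peak_window
        self.trough_min = trough_min

    def fit(self, course, y=None):
        if isinstance(course, tuple):
            observations, regimen = course
        else:
            observations, regimen = course.observations, course.regimen
        self.regimen_ = regimen
        for o in observations:
            o.kind = classify_sample(o, regimen, self.peak_window, self.trough_min)
        self.groups_ = group_samples(observations, regimen)
        self.estimates_ = [llr_fit(g, regimen) for g in self.groups_]
        best = next((e for e in self.estimates_ if e.evaluable), None)
        if best is not None:
            self.k_, self.vd_, self.cl_ = best.k, best.vd, best.cl
            self.status_, self.reason_ = "evaluable", None
        else:
            self.k_ = self.vd_ = self.cl_ = None
            self.status_ = "not-evaluable"
            self.reason_ = self._course_reason(observations)
        return self

    def _course_reason(self, observations) -> str:
        reasons = {e.reason for e in self.estimates_}
        if "nonpositive-k" in reasons:
            return "nonpositive-k"
        if "bloq-sample" in reasons:
            return "bloq-sample"
        n_usable = sum(1 for o in observations if not o.bloq)
        if len(list(observations)) < 2 or n_usable < 2:
            return "insufficient-samples"
        return "mistimed"

    def predict(self, t_offsets):
        """Steady-state concentrations at offsets (h) from a dose start."""
        if self.status_ != "evaluable":
            raise ValueError(f"course not evaluable by LLR ({self.reason_})")
        last = self.regimen_.doses[-1]
        return steady_state_conc_1cmt(
            self.k_, self.cl_, last.amount, last.tinf, last.tinterval, t_offsets
        )

    def predict_auc24(self) -> float:
        if self.status_ != "evaluable":
            raise ValueError(f"course not evaluable by LLR ({self.reason_})")
        return self.regimen_.daily_dose() / self.cl_
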