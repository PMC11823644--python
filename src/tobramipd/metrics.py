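"""Predictive-performance metrics and patient-level bootstrap comparison.

    RMSE  = sqrt(mean((pred - obs)^2))
    nRMSE = RMSE / mean(obs)          (reported as %)
    MPE   = mean((pred - obs)/obs) * 100%

Clinical accuracy is metric-specific: peak and AUC predictions are accurate
within 20% of the reference value (boundary inclusive); a trough prediction
is accurate when predicted and reference values agree on which side of
1 mg/L they fall (exactly 1 counts as above). Sampling variability is
assessed with a patient-level bootstrap (resampling patients with all their
prediction pairs) and 2.5th-97.5th empirical percentiles; two methods are
called statistically distinguishable when those intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "error_metrics",
    "accuracy",
    "bootstrap_metrics",
    "compare_methods",
]

METRIC_KINDS = ("peak", "trough", "auc")
ACCURACY_TOL = 0.20
TROUGH_CUT = 1.0  # mg/L


def error_metrics(pred, obs) -> tuple[float, float, float]:
    """(RMSE, nRMSE %, MPE %) over paired predictions and references."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size == 0:
        raise ValueError("error metrics require at least one pair")
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must align")
    bad = np.nonzero(~(obs > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive reference value at pair index {bad[0]}")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    nrmse = 100.0 * rmse / float(np.mean(obs))
    mpe = 100.0 * float(np.mean((pred - obs) / obs))
    return rmse, nrmse, mpe


def _accurate(pred, obs, kind: str, obs_bloq=None) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    if kind in ("peak", "auc"):
        obs = np.asarray(obs, dtype=float)
        return np.abs(pred - obs) / obs <= ACCURACY_TOL + 1e-12
    if kind == "trough":
        # exactly 1 mg/L ties break upward for both sides
        obs = np.asarray(
            [np.nan if o is None else o for o in np.atleast_1d(obs)], dtype=float
        )
        if obs_bloq is None:
            obs_bloq = np.zeros(pred.shape, dtype=bool)
        obs_bloq = np.asarray(obs_bloq, dtype=bool)
        obs_above = np.where(obs_bloq, False, obs >= TROUGH_CUT)
        pred_above = pred >= TROUGH_CUT
        return obs_above == pred_above
    raise ValueError(f"unknown metric kind {kind!r}")


def accuracy(pred, obs, kind: str, obs_bloq=None) -> float:
    """Percent of pairs meeting the kind-specific accuracy rule."""
    if kind not in METRIC_KINDS:
        raise ValueError(f"unknown metric kind {kind!r}")
    acc = _accurate(pred, obs, kind, obs_bloq)
    return 100.0 * float(np.mean(acc))


@dataclass(frozen=True)
class MetricsReport:
    """Point estimates with bootstrap percentile intervals for one
    method/design/weight cell."""

    accuracy: float
    mpe: float
    nrmse: float
    intervals: dict[str, tuple[float, float]]
    n_pairs: int
    n_patients: int
    labels: dict[str, object] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = dict(self.labels)
        row.update(
            accuracy=self.accuracy,
            mpe=self.mpe,
            nrmse=self.nrmse,
            n_pairs=self.n_pairs,
            n_patients=self.n_patients,
        )
        for m, (lo, hi) in self.intervals.items():
            row[f"{m}_lo"] = lo
            row[f"{m}_hi"] = hi
        return row


def _point_metrics(df: pd.DataFrame, kind: str) -> tuple[float, float, float]:
    bloq = df["obs_bloq"].to_numpy(bool) if "obs_bloq" in df else np.zeros(len(df), bool)
    acc = accuracy(
        df["pred"].to_numpy(float),
        df["obs"].to_numpy(),
        kind,
        obs_bloq=bloq,
    )
    quant = df.loc[~bloq]
    if len(quant):
        _, nrmse, mpe = error_metrics(
            quant["pred"].to_numpy(float), quant["obs"].to_numpy(float)
        )
    else:
        nrmse = mpe = float("nan")
    return acc, mpe, nrmse


def bootstrap_metrics(
    pairs: pd.DataFrame,
    kind: str,
    b: int = 1000,
    seed: int = 0,
    labels: dict | None = None,
) -> MetricsReport:
    """Metrics with patient-level bootstrap percentile intervals.

    ``pairs`` needs columns patient_id, pred, obs (optionally obs_bloq).
    Patients are resampled with replacement, carrying all their pairs, B
    times; the 2.5th and 97.5th empirical percentiles (linear, "type 7"
    interpolation) of each metric form the interval.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    pairs = pairs.reset_index(drop=True)
    patients = pairs["patient_id"].unique()
    if len(patients) < 2:
        warnings.warn(
            "bootstrap over a single patient gives a degenerate interval",
            RuntimeWarning,
        )
    point = _point_metrics(pairs, kind)
    idx_of = {p: np.flatnonzero(pairs["patient_id"].to_numpy() == p) for p in patients}
    rng = np.random.default_rng(seed)
    reps = np.empty((b, 3))
    for i in range(b):
        chosen = rng.choice(patients, size=len(patients), replace=True)
        rows = np.concatenate([idx_of[p] for p in chosen])
        reps[i] = _point_metrics(pairs.iloc[rows], kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanquantile(reps, 0.025, axis=0)
        hi = np.nanquantile(reps, 0.975, axis=0)
    names = ("accuracy", "mpe", "nrmse")
    intervals = {m: (float(lo[j]), float(hi[j])) for j, m in enumerate(names)}
    return MetricsReport(
        accuracy=point[0],
        mpe=point[1],
        nrmse=point[2],
        intervals=intervals,
        n_pairs=len(pairs),
        n_patients=len(patients),
        labels=labels or {},
    )


_BETTER = {
    "accuracy": lambda a, b: a > b,
    "mpe": lambda a, b: abs(a) < abs(b),
    "nrmse": lambda a, b: a < b,
}


def compare_methods(
    report_a: MetricsReport,
    report_b: MetricsReport,
    require_same_patients: bool = True,
) -> dict[str, str]:
    """Interval-overlap verdict per metric between two methods.

    The better point estimate wins "significantly better" only when the two
    bootstrap percentile intervals do not overlap; otherwise the methods are
    "not statistically distinguishable" on that metric. By default the two
    reports must cover the same patients; pass ``require_same_patients=False``
    to compare methods with unequal evaluable subsets (e.g. LLR after BLOQ
    dropouts against Bayesian estimation on all courses).
    """
    if require_same_patients and report_a.n_patients != report_b.n_patients:
        raise ValueError("reports must be computed on the same patient universe")
    out: dict[str, str] = {}
    for m in ("accuracy", "mpe", "nrmse"):
        a = getattr(report_a, m)
        b_ = getattr(report_b, m)
        lo_a, hi_a = report_a.intervals[m]
        lo_b, hi_b = report_b.intervals[m]
        overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
        if overlap:
            out[m] = "not statistically distinguishable"
        elif _BETTER[m](a, b_):
            out[m] = "A significantly better"
        else:
            out[m] = "B significantly better"
    return out
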