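"""Analytic intravenous-infusion pharmacokinetics.

One- and two-compartment models with covariate relations and log-normal
inter-individual variability, evaluated through closed-form superposition of
infusion solutions (no ODE integration), plus exposure summaries (AUC, peak,
trough).

Times are hours from the start of the first infusion; concentrations are
mg/L; amounts are mg; clearances L/h; volumes L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelSpec",
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "ConcentrationCurve",
    "CovariateRelation",
    "individual_parameters",
    "simulate_concentrations",
    "compute_auc",
    "cockcroft_gault",
    "load_model",
]

_PARAM_ORDER_1CMT = ("CL", "V1")
_PARAM_ORDER_2CMT = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class CovariateRelation:
    """One multiplicative covariate effect on a structural parameter.

    form "power-normalized": factor = (cov / reference) ** coefficient
    form "linear-normalized": factor = 1 + coefficient * (cov - reference) / reference
    """

    parameter: str
    covariate: str
    form: str
    coefficient: float
    reference: float

    def factor(self, value: float) -> float:
        if self.form == "power-normalized":
            return (value / self.reference) ** self.coefficient
        if self.form == "linear-normalized":
            return 1.0 + self.coefficient * (value - self.reference) / self.reference
        raise ValueError(f"unknown covariate relation form: {self.form!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A population PK model: structure, typical values, IIV, residual error.

    ``theta`` holds typical parameter values at the reference covariates;
    ``omega`` is the covariance of the log-scale random effects for the
    parameters named in ``iiv`` (variance units); the residual model is
    combined proportional (CV fraction) + additive (SD, mg/L).
    """

    n_compartments: int
    theta: dict[str, float]
    omega: np.ndarray
    iiv: tuple[str, ...]
    sigma_prop: float
    sigma_add: float
    covariate_relations: tuple[CovariateRelation, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        required = _PARAM_ORDER_2CMT if self.n_compartments == 2 else _PARAM_ORDER_1CMT
        for name in required:
            if name not in self.theta:
                raise ValueError(f"theta missing parameter {name!r}")
            if not self.theta[name] > 0:
                raise ValueError(f"theta[{name!r}] must be strictly positive")
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
            raise ValueError("omega must be a square matrix")
        if omega.shape[0] != len(self.iiv):
            raise ValueError("omega dimension must match the number of IIV parameters")
        if not np.allclose(omega, omega.T):
            raise ValueError("omega must be symmetric")
        if omega.size and np.min(np.linalg.eigvalsh(omega)) < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "iiv", tuple(self.iiv))
        object.__setattr__(
            self, "covariate_relations", tuple(self.covariate_relations)
        )
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual error parameters must be non-negative")

    @property
    def n_eta(self) -> int:
        return len(self.iiv)

    def residual_sd(self, pred):
        """SD of the residual error at a model prediction (mg/L)."""
        pred = np.asarray(pred, dtype=float)
        return np.sqrt((self.sigma_prop * pred) ** 2 + self.sigma_add**2)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelSpec":
        """Build from the ``model:`` block of a structured config file."""
        m = cfg.get("model", cfg)
        n_cmt = int(m["compartments"])
        theta = {k: float(v) for k, v in m["theta"].items()}
        iiv = tuple(m.get("iiv", list(theta)))
        tri = m["omega"]
        n = len(tri)
        omega = np.zeros((n, n))
        for i, row in enumerate(tri):
            for j, v in enumerate(row):
                omega[i, j] = omega[j, i] = float(v)
        sigma = m.get("sigma", {})
        rels = tuple(
            CovariateRelation(
                parameter=r["parameter"],
                covariate=r["covariate"],
                form=r["form"],
                coefficient=float(r["coefficient"]),
                reference=float(r["reference"]),
            )
            for r in m.get("covariates", [])
        )
        return cls(
            n_compartments=n_cmt,
            theta=theta,
            omega=omega,
            iiv=iiv,
            sigma_prop=float(sigma.get("prop", 0.0)),
            sigma_add=float(sigma.get("add", 0.0)),
            covariate_relations=rels,
            label=str(m.get("label", "")),
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PKParameters:
    """Individual structural parameters; Q and V2 are None for one compartment."""

    CL: float
    V1: float
    Q: float | None = None
    V2: float | None = None

    def __post_init__(self) -> None:
        for name in ("CL", "V1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("Q", "V2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive when present")
        if (self.Q is None) != (self.V2 is None):
            raise ValueError("Q and V2 must be supplied together")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V1, 1/h."""
        return self.CL / self.V1

    @property
    def n_compartments(self) -> int:
        return 1 if self.Q is None else 2

    def as_dict(self) -> dict[str, float]:
        d = {"CL": self.CL, "V1": self.V1}
        if self.Q is not None:
            d.update(Q=self.Q, V2=self.V2)
        return d


@dataclass(frozen=True)
class DoseEvent:
    """One IV infusion: amount (mg), start (h), duration (h), scheduled interval (h)."""

    amount: float
    time: float = 0.0
    tinf: float = 0.5
    tinterval: float = 24.0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if not self.tinf > 0:
            raise ValueError("infusion duration must be positive")

    @property
    def rate(self) -> float:
        return self.amount / self.tinf

    @property
    def end(self) -> float:
        return self.time + self.tinf


@dataclass(frozen=True)
class Regimen:
    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        doses = tuple(self.doses)
        if any(b.time < a.time for a, b in zip(doses, doses[1:])):
            raise ValueError("dose event times must be non-decreasing")
        object.__setattr__(self, "doses", doses)

    @classmethod
    def single(cls, amount: float, tinf: float = 0.5, tinterval: float = 24.0) -> "Regimen":
        return cls((DoseEvent(amount, 0.0, tinf, tinterval),))

    @classmethod
    def repeated(
        cls, amount: float, n: int, tinterval: float = 24.0, tinf: float = 0.5
    ) -> "Regimen":
        return cls(
            tuple(DoseEvent(amount, i * tinterval, tinf, tinterval) for i in range(n))
        )

    @property
    def total_dose(self) -> float:
        return sum(d.amount for d in self.doses)

    def daily_dose(self) -> float:
        """Scheduled dose per 24 h, from the last dose event."""
        last = self.doses[-1]
        return last.amount * 24.0 / last.tinterval

    def latest_dose_before(self, t: float) -> DoseEvent | None:
        prior = [d for d in self.doses if d.time <= t]
        return prior[-1] if prior else None


@dataclass(frozen=True)
class ConcentrationCurve:
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have the same shape")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < -1e-12):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance, mL/min.

    (140 - age) * weight / (72 * SCr), times 0.85 for females. Provided as an
    optional helper; the models consume creatinine clearance directly.
    """
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if str(sex).lower() in ("f", "female", "0"):
        crcl *= 0.85
    return crcl


def individual_parameters(
    spec: ModelSpec, covariates: dict[str, float], eta: Sequence[float]
) -> PKParameters:
    """Individual parameters: theta_i * covariate factors * exp(eta_i).

    ``eta`` is the log-scale random-effect vector ordered as ``spec.iiv``;
    parameters without a random effect get eta 0.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (spec.n_eta,):
        raise ValueError(
            f"eta has length {eta.size}, expected {spec.n_eta} (omega dimension)"
        )
    names = _PARAM_ORDER_2CMT if spec.n_compartments == 2 else _PARAM_ORDER_1CMT
    values: dict[str, float] = {}
    for name in names:
        v = spec.theta[name]
        for rel in spec.covariate_relations:
            if rel.parameter != name:
                continue
            if rel.covariate not in covariates:
                raise ValueError(
                    f"covariate {rel.covariate!r} required by parameter {name!r} "
                    "is missing from the supplied covariates"
                )
            v *= rel.factor(float(covariates[rel.covariate]))
        if name in spec.iiv:
            v *= math.exp(eta[spec.iiv.index(name)])
        if not v > 0:
            raise ValueError(f"parameter {name!r} is non-positive ({v})")
        values[name] = v
    if spec.n_compartments == 1:
        return PKParameters(CL=values["CL"], V1=values["V1"])
    return PKParameters(**values)


def _expm1_ratio(lam: float, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-lam t)) / lam, stable as lam -> 0."""
    x = lam * t
    out = np.where(np.abs(x) < 1e-12, t, -np.expm1(-x) / lam if lam != 0 else t)
    return out


def _single_infusion_1cmt(
    params: PKParameters, rate: float, tinf: float, tau: np.ndarray
) -> np.ndarray:
    """Concentration at times tau (from infusion start) for one infusion."""
    k = params.k
    c = np.zeros_like(tau, dtype=float)
    during = (tau >= 0) & (tau <= tinf)
    after = tau > tinf
    # R/(k V1) = R/CL
    scale = rate / params.CL
    c[during] = scale * -np.expm1(-k * tau[during])
    c[after] = scale * -np.expm1(-k * tinf) * np.exp(-k * (tau[after] - tinf))
    return c


def _macro_constants(params: PKParameters) -> tuple[float, float, float, float]:
    """Bi-exponential macro-constants (lam1, lam2, A, B) with C_bolus =
    (D/V1)(A e^{-lam1 t} + B e^{-lam2 t})."""
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    if disc == 0.0:
        raise ValueError("degenerate two-compartment eigenvalues")
    a = (lam1 - k21) / disc
    b = (k21 - lam2) / disc
    return lam1, lam2, a, b


def _single_infusion_2cmt(
    params: PKParameters, rate: float, tinf: float, tau: np.ndarray
) -> np.ndarray:
    lam1, lam2, a, b = _macro_constants(params)
    c = np.zeros_like(tau, dtype=float)
    during = (tau >= 0) & (tau <= tinf)
    after = tau > tinf
    scale = rate / params.V1
    td = tau[during]
    c[during] = scale * (a * _expm1_ratio(lam1, td) + b * _expm1_ratio(lam2, td))
    ta = tau[after] - tinf
    c[after] = scale * (
        a * _expm1_ratio(lam1, np.full_like(ta, tinf)) * np.exp(-lam1 * ta)
        + b * _expm1_ratio(lam2, np.full_like(ta, tinf)) * np.exp(-lam2 * ta)
    )
    return c


def simulate_concentrations(
    params: PKParameters, regimen: Regimen, times: Sequence[float]
) -> ConcentrationCurve:
    """Closed-form concentration-time curve by superposition over dose events."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("simulation times must be non-negative")
    single = (
        _single_infusion_1cmt if params.n_compartments == 1 else _single_infusion_2cmt
    )
    c = np.zeros_like(t, dtype=float)
    for dose in regimen.doses:
        if dose.amount == 0:
            continue
        c += single(params, dose.rate, dose.tinf, t - dose.time)
    return ConcentrationCurve(times=t, concentrations=np.maximum(c, 0.0))


def predict_concentrations(
    params: PKParameters, regimen: Regimen, times: Sequence[float]
) -> np.ndarray:
    """Concentrations at arbitrary (possibly unsorted) times."""
    t = np.asarray(times, dtype=float)
    order = np.argsort(t, kind="stable")
    # de-duplicate strictly increasing grid requirement by evaluating directly
    single = (
        _single_infusion_1cmt if params.n_compartments == 1 else _single_infusion_2cmt
    )
    c = np.zeros_like(t, dtype=float)
    for dose in regimen.doses:
        if dose.amount == 0:
            continue
        c += single(params, dose.rate, dose.tinf, t - dose.time)
    del order
    return np.maximum(c, 0.0)


def compute_auc(
    source,
    window: tuple[float, float] = (0.0, math.inf),
    regimen: Regimen | None = None,
    dt: float = 0.01,
) -> float:
    """AUC (mg.h/L) over a time window.

    ``source`` is either a :class:`ConcentrationCurve` (trapezoid over its
    grid) or :class:`PKParameters` with a ``regimen``: the 0-to-infinity case
    uses the mass-balance identity total dose / CL; finite windows use a fine
    trapezoid grid (default resolution 0.01 h).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed window start")
    if isinstance(source, ConcentrationCurve):
        t, c = source.times, source.concentrations
        if math.isinf(t1):
            t1 = t[-1]
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError("curve grid does not cover the requested window")
        mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        return float(np.trapezoid(c[mask], t[mask]))
    params: PKParameters = source
    if regimen is None:
        raise ValueError("a regimen is required when integrating from parameters")
    if math.isinf(t1):
        if t0 == 0.0:
            return regimen.total_dose / params.CL
        # residual AUC: total minus the finite head
        head = compute_auc(params, (0.0, t0), regimen, dt) if t0 > 0 else 0.0
        return regimen.total_dose / params.CL - head
    grid = np.linspace(t0, t1, max(int(round((t1 - t0) / dt)), 2) + 1)
    curve = simulate_concentrations(params, regimen, grid)
    return float(np.trapezoid(curve.concentrations, curve.times))


def peak_trough(
    params: PKParameters,
    regimen: Regimen,
    peak_offset: float = 1.0,
    trough_offset: float | None = None,
) -> tuple[float, float]:
    """Model-predicted peak and trough around the last dose.

    Offsets are hours from that dose's start; the trough defaults to the end
    of its scheduled interval.
    """
    last = regimen.doses[-1]
    if trough_offset is None:
        trough_offset = last.tinterval
    c = predict_concentrations(
        params, regimen, [last.time + peak_offset, last.time + trough_offset]
    )
    return float(c[0]), float(c[1])


def load_model(label_or_path) -> ModelSpec:
    """Load a ModelSpec from a packaged label (e.g. ``hennig_like``) or a path."""
    import importlib.resources as resources
    from pathlib import Path

    p = Path(str(label_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return ModelSpec.from_yaml(p)
    ref = resources.files("tobramipd") / "models" / f"{label_or_path}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(
            f"no packaged model named {label_or_path!r} and no such file"
        )
    return ModelSpec.from_dict(yaml.safe_load(ref.read_text()))
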