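"""Orchestration of the simulation comparison and the clinical replay.

``run_experiment`` is the full simulation study: virtual patients with
study-population covariates, several IIV draws each, a single weight-based
infusion, noisy censored samples under each sampling design, then AUC
estimation by two-sample log-linear regression and by MAP Bayesian
estimation (each estimation model x prior weight x design, matched and
mis-specified), and finally bootstrap metrics and interval-overlap
comparisons. Fully deterministic given (config, seed).

``replay_clinical`` is the forward-walking replay of an observed dataset:
LLR grouping and fitting plus the iterative a-priori/a-posteriori Bayesian
forecast per course, with the usual inclusion rules (two or more doses, two
or more concentrations, no sample during an infusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, llr, metrics
from .io import Course, read_dataset
from .pk import ModelSpec, compute_auc, load_model
from .simulate import (
    DEFAULT_LOQ,
    SamplingDesign,
    TWO_SAMPLE_DESIGN,
    draw_individuals,
    generate_patients,
    simulate_course,
    single_sample_design,
)

logger = logging.getLogger("tobramipd")

__all__ = ["ExperimentConfig", "run_experiment", "replay_clinical"]


@dataclass
class ExperimentConfig:
    """Settings for one simulation comparison run."""

    simulation_model: str = "hennig_like"
    estimation_models: tuple[str, ...] = ("hennig_like", "alghanem_like")
    prior_weights: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.1)
    designs: tuple[SamplingDesign, ...] = (TWO_SAMPLE_DESIGN,)
    n_patients: int = 50
    k_draws: int = 5
    seed: int = 1
    bootstrap_b: int = 1000
    loq: float = DEFAULT_LOQ
    dose_per_kg: float = 10.0
    tinf: float = 0.5
    auc_window: tuple[float, float] = (0.0, 24.0)
    map_n_restarts: int = 2

    def __post_init__(self) -> None:
        if not self.designs:
            raise ValueError("at least one sampling design is required")
        if any(not 0 < w <= 1 for w in self.prior_weights):
            raise ValueError("prior weights must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "designs" in raw:
            raw["designs"] = tuple(_parse_design(d) for d in raw["designs"])
        for key in ("estimation_models", "prior_weights", "auc_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _parse_design(d) -> SamplingDesign:
    if isinstance(d, SamplingDesign):
        return d
    if isinstance(d, dict):
        return SamplingDesign(d["name"], tuple(float(o) for o in d["offsets"]))
    offsets = tuple(float(o) for o in d)
    if len(offsets) == 1:
        return single_sample_design(offsets[0])
    return SamplingDesign("-".join(f"{o:g}" for o in offsets), offsets)


def _resolve(model) -> ModelSpec:
    return model if isinstance(model, ModelSpec) else load_model(model)


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run the full comparison; returns {predictions, reports, comparisons}.

    ``predictions`` is the long per-course table of estimated vs true AUC;
    ``reports`` holds bootstrap metrics per (method, model, weight, design)
    cell; ``comparisons`` holds interval-overlap verdicts of each Bayesian
    cell against LLR on the same design grid.
    """
    sim_spec = _resolve(config.simulation_model)
    est_specs = {str(getattr(m, "label", m)): _resolve(m) for m in config.estimation_models}

    ss = np.random.SeedSequence(config.seed)
    s_pat, s_eta, s_obs, s_boot = ss.spawn(4)
    logger.info("stage=patients n=%d", config.n_patients)
    patients = generate_patients(
        config.n_patients, seed=int(s_pat.generate_state(1)[0] % 2**31)
    )
    individuals = draw_individuals(
        patients, sim_spec, config.k_draws, seed=int(s_eta.generate_state(1)[0] % 2**31)
    )
    logger.info("stage=individuals n=%d", len(individuals))

    obs_seeds = s_obs.generate_state(len(individuals) * len(config.designs)) % 2**31
    rows: list[dict] = []
    for d_idx, design in enumerate(config.designs):
        logger.info("stage=simulate design=%s", design.name)
        for i_idx, (pat, eta) in enumerate(individuals):
            course = simulate_course(
                pat,
                eta,
                sim_spec,
                design=design,
                dose_per_kg=config.dose_per_kg,
                tinf=config.tinf,
                loq=config.loq,
                auc_window=config.auc_window,
                seed=int(obs_seeds[d_idx * len(individuals) + i_idx]),
                course_id=f"P{pat.patient_id}D{i_idx % config.k_draws}",
            )
            base = {
                "course_id": course.course_id,
                "patient_id": pat.patient_id,
                "design": design.name,
                "true_auc": course.true_auc,
            }
            if len(design.offsets) == 2:
                est = llr.TwoSampleLLR().fit(course)
                rows.append(
                    base
                    | {
                        "method": "llr",
                        "model": "",
                        "weight": np.nan,
                        "pred_auc": est.predict_auc24()
                        if est.status_ == "evaluable"
                        else np.nan,
                        "status": est.status_,
                        "reason": est.reason_ or "",
                    }
                )
            for label, espec in est_specs.items():
                for w in config.prior_weights:
                    f = bayes.map_fit(
                        espec,
                        course.observations,
                        course.regimen,
                        course.covariates,
                        w=w,
                        n_restarts=config.map_n_restarts,
                        seed=config.seed,
                    )
                    pred_auc = compute_auc(f.params, config.auc_window, course.regimen)
                    rows.append(
                        base
                        | {
                            "method": "map",
                            "model": label,
                            "weight": w,
                            "pred_auc": pred_auc,
                            "status": "evaluable",
                            "reason": "" if f.converged else "not-converged",
                        }
                    )
    predictions = pd.DataFrame(rows)

    logger.info("stage=metrics B=%d", config.bootstrap_b)
    boot_seed = int(s_boot.generate_state(1)[0] % 2**31)
    reports: dict[tuple, metrics.MetricsReport] = {}
    report_rows = []
    cells = predictions[predictions["pred_auc"].notna()]
    for (method, model, weight, design), sub in cells.groupby(
        ["method", "model", "weight", "design"], dropna=False, sort=True
    ):
        pairs = pd.DataFrame(
            {
                "patient_id": sub["patient_id"].to_numpy(),
                "pred": sub["pred_auc"].to_numpy(),
                "obs": sub["true_auc"].to_numpy(),
            }
        )
        labels = {
            "method": method,
            "model": model,
            "weight": weight,
            "design": design,
        }
        rep = metrics.bootstrap_metrics(
            pairs, "auc", b=config.bootstrap_b, seed=boot_seed, labels=labels
        )
        reports[(method, model, weight, design)] = rep
        report_rows.append(rep.as_row())
    reports_df = pd.DataFrame(report_rows).sort_values(
        ["method", "model", "design", "weight"], kind="stable", na_position="first"
    ).reset_index(drop=True)

    comp_rows = []
    llr_key = next((k for k in reports if k[0] == "llr"), None)
    if llr_key is not None:
        for key, rep in reports.items():
            if key[0] != "map":
                continue
            verdict = metrics.compare_methods(
                rep, reports[llr_key], require_same_patients=False
            )
            comp_rows.append(
                {
                    "model": key[1],
                    "weight": key[2],
                    "design": key[3],
                    **{f"{m}_verdict": v for m, v in verdict.items()},
                }
            )
    comparisons = pd.DataFrame(comp_rows)

    bundle = {"predictions": predictions, "reports": reports_df, "comparisons": comparisons}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name, df in bundle.items():
                p = out / f"{name}.csv"
                df.to_csv(p, index=False)
                written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return bundle


def _course_eligible(course: Course) -> str | None:
    """Inclusion rules; returns an exclusion reason or None."""
    if course.n_doses() < 2:
        return "fewer-than-two-doses"
    if course.n_observations() < 2:
        return "fewer-than-two-concentrations"
    for o in course.observations:
        if llr.classify_sample(o, course.regimen) == "invalid":
            return "sample-during-infusion"
    return None


def replay_clinical(
    dataset,
    model="hennig_like",
    weights: tuple[float, ...] = (1.0,),
    **fit_kwargs,
) -> dict:
    """Forward-walking replay of an observed (or simulated) dataset.

    Returns {predictions, reports, exclusions, llr_evaluability}:
    per-concentration prediction pairs for the Bayesian forecast (a priori /
    a posteriori, per prior weight) and for LLR where evaluable, metric
    tables per method/mode/kind, and the course-accounting tallies.
    """
    courses = read_dataset(dataset) if not isinstance(dataset, list) else dataset
    spec = _resolve(model)
    excl_rows = []
    pred_rows = []
    llr_status = []
    for course in courses:
        reason = _course_eligible(course)
        if reason:
            excl_rows.append(
                {"course_id": course.course_id, "included": False, "reason": reason}
            )
            continue
        excl_rows.append({"course_id": course.course_id, "included": True, "reason": ""})
        est = llr.TwoSampleLLR().fit(course)
        llr_status.append(
            {
                "course_id": course.course_id,
                "status": est.status_,
                "reason": est.reason_ or "",
                "n_groups": len(est.groups_),
            }
        )
        if est.status_ == "evaluable":
            # predict each sample after the first evaluable group with the
            # fitted steady-state one-compartment curve
            first_eval = next(
                g for g, e in zip(est.groups_, est.estimates_) if e.evaluable
            )
            t_fit = max(o.time for o in first_eval.observations)
            for o in course.observations:
                if o.time <= t_fit or o.kind not in ("peak", "trough"):
                    continue
                dose = course.regimen.latest_dose_before(o.time)
                pred = float(est.predict([o.time - dose.time])[0])
                pred_rows.append(
                    {
                        "course_id": course.course_id,
                        "patient_id": course.patient_id,
                        "method": "llr",
                        "weight": np.nan,
                        "mode": "a posteriori",
                        "kind": o.kind,
                        "time": o.time,
                        "pred": pred,
                        "obs": o.value,
                        "obs_bloq": o.bloq,
                    }
                )
        for w in weights:
            records = bayes.iterative_forecast(
                course.observations,
                course.regimen,
                course.covariates,
                spec,
                w=w,
                **fit_kwargs,
            )
            parts = bayes._chronological_groups(course.observations, course.regimen)
            for rec, part in zip(records, parts):
                for o, p in zip(part, rec.predicted):
                    pred_rows.append(
                        {
                            "course_id": course.course_id,
                            "patient_id": course.patient_id,
                            "method": "map",
                            "weight": w,
                            "mode": rec.mode,
                            "kind": o.kind or "",
                            "time": o.time,
                            "pred": float(p),
                            "obs": o.value,
                            "obs_bloq": o.bloq,
                        }
                    )
    predictions = pd.DataFrame(pred_rows)
    report_rows = []
    if len(predictions):
        usable = predictions[predictions["kind"].isin(["peak", "trough"])]
        for (method, weight, mode, kind), sub in usable.groupby(
            ["method", "weight", "mode", "kind"], dropna=False, sort=True
        ):
            sub2 = sub[~sub["obs_bloq"] | (kind == "trough")]
            if not len(sub2):
                continue
            rep = metrics.bootstrap_metrics(
                pd.DataFrame(
                    {
                        "patient_id": sub2["patient_id"].to_numpy(),
                        "pred": sub2["pred"].to_numpy(),
                        "obs": sub2["obs"].to_numpy(),
                        "obs_bloq": sub2["obs_bloq"].to_numpy(),
                    }
                ),
                kind,
                b=200,
                seed=0,
                labels={"method": method, "weight": weight, "mode": mode, "kind": kind},
            )
            report_rows.append(rep.as_row())
    return {
        "predictions": predictions,
        "reports": pd.DataFrame(report_rows),
        "exclusions": pd.DataFrame(excl_rows),
        "llr_evaluability": pd.DataFrame(llr_status),
    }
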