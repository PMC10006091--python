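"""End-to-end study orchestration: generate -> sample -> coalesce -> gamma ->
SPC/PCA -> sensitivity, behind a validated config with seeded reproducibility.

A study simulates a patient-specific QA programme on a synthetic plan
cohort: every plan is rendered, "delivered" with measurement noise,
measured by both array models under standard acquisition (SA) and
coalescence, and scored with the gamma index.  The resulting pass-rate
series feed the control charts and capability analysis (action limits are
derived from the SA cohorts, and each cohort's capability is assessed
against them, so the coalescence cohorts are judged inside the SA process
variability).  A separate error-injection cohort quantifies detection
sensitivity via delta-gamma and ROC/AUC.  Every run writes the resolved
config next to its results, and a machine-readable summary JSON from which
all figures and tables can be regenerated.

One integer seed governs all stochastic stages; each stage derives its own
generator from (seed, crc32(stage name)), so adding or reordering stages
does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spc
from .synthetic import (
    ErrorSpec,
    FieldSpec,
    Segment,
    add_measurement_noise,
    generate_vmat_dosemap,
    hd120_leaf_widths,
    random_field_spec,
)
from .detector import CoalescenceError, acquire_coalesced, build_array, sample
from .gamma import (
    GammaCriteria,
    evaluated_bounds_for,
    gamma_map,
    pass_rate,
    prepare_evaluated,
    profile_compare,
)
from .sensitivity import run_error_study

__all__ = ["StudyConfig", "StudyResult", "run_study", "ConfigError", "stage_rng"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid study configuration (raised before any computation)."""


_DEFAULT_CRITERIA = ({"dd": 3.0, "dta": 2.0, "norm": "global"},)
_DEFAULT_SENS_CRITERIA = (
    {"dd": 3.0, "dta": 2.0, "norm": "global"},
    {"dd": 3.0, "dta": 2.0, "norm": "local"},
)
_DEFAULT_ERRORS = (
    {"kind": "DLG_shift", "magnitude": 1.0},
    {"kind": "MU_scale", "magnitude": 0.02},
)


@dataclass
class StudyConfig:
    """Resolved parameters of one QA study run."""

    seed: int = 0
    n_qa_plans: int = 24
    baseline_n: int = 20
    n_error_plans: int = 8
    detectors: tuple = ("d729", "d1500")
    procedures: tuple = ("sa", "coalescence")
    criteria: tuple = _DEFAULT_CRITERIA
    sensitivity_criteria: tuple = _DEFAULT_SENS_CRITERIA
    error_specs: tuple = _DEFAULT_ERRORS
    beta: float = 4.0
    target: float = 100.0
    noise_sigma: float = 0.005
    coalescence_tolerance: float = 0.05
    gen_spacing_mm: float = 1.0
    ref_spacing_mm: float = 2.5
    plan_style: str = "modulated"  # or "open" (single open square field)
    idealized_measurement: bool = False  # evaluate the reference against itself
    figures: bool = False
    output_dir: str = "study_output"

    def validate(self) -> None:
        if self.n_qa_plans < 2:
            raise ConfigError("the QA cohort needs at least two plans")
        if not 2 <= self.baseline_n <= self.n_qa_plans:
            raise ConfigError(
                f"baseline_n={self.baseline_n} must lie in [2, n_qa_plans="
                f"{self.n_qa_plans}]"
            )
        if self.n_error_plans < 1:
            raise ConfigError("the error cohort needs at least one plan")
        for d in self.detectors:
            if d not in ("d729", "d1500"):
                raise ConfigError(f"unknown detector model {d!r}")
        for p in self.procedures:
            if p not in ("sa", "coalescence"):
                raise ConfigError(f"unknown procedure {p!r}")
        if self.plan_style not in ("modulated", "open"):
            raise ConfigError(f"unknown plan style {self.plan_style!r}")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be >= 0")
        for c in list(self.criteria) + list(self.sensitivity_criteria):
            self._criteria_obj(c)  # raises on bad values
        for e in self.error_specs:
            try:
                ErrorSpec(kind=e["kind"], magnitude=e["magnitude"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"bad error spec {e!r}: {exc}") from exc

    @staticmethod
    def _criteria_obj(c: dict) -> GammaCriteria:
        try:
            return GammaCriteria(
                dd_percent=float(c["dd"]),
                dta_mm=float(c["dta"]),
                normalization=c.get("norm", "global"),
                threshold_percent=float(c.get("threshold", 10.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad gamma criteria {c!r}: {exc}") from exc

    def criteria_objects(self) -> list[GammaCriteria]:
        return [self._criteria_obj(c) for c in self.criteria]

    def sensitivity_criteria_objects(self) -> list[GammaCriteria]:
        return [self._criteria_obj(c) for c in self.sensitivity_criteria]

    def error_objects(self) -> list[ErrorSpec]:
        return [ErrorSpec(kind=e["kind"], magnitude=e["magnitude"]) for e in self.error_specs]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("detectors", "procedures", "criteria", "sensitivity_criteria", "error_specs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


@dataclass
class StudyResult:
    config: StudyConfig
    summary: dict
    series: dict  # cohort key -> QaSeries
    output_dir: Path


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator: independent of other stages and of their order."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def _open_field_spec(noise_sigma: float) -> FieldSpec:
    widths = hd120_leaf_widths()
    openings = np.zeros((widths.size, 2))
    edges = np.concatenate([[0.0], np.cumsum(widths)]) - widths.sum() / 2
    centers = 0.5 * (edges[:-1] + edges[1:])
    inside = np.abs(centers) <= 50.0
    openings[inside] = (-50.0, 50.0)
    return FieldSpec(
        segments=[Segment(openings=openings, weight=1.0)],
        penumbra_mm=3.0,
        collimator_deg=0.0,
        noise_sigma=noise_sigma,
    )


def _cohort_key(det: str, proc: str, crit: GammaCriteria) -> str:
    return f"{det}|{proc}|{crit.label()}"


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full QA study described by ``config``.

    Deterministic for a fixed config (same seed -> byte-identical summary
    JSON).  Coalescence failures do not abort the run; they are recorded
    and the affected cohort entry is skipped.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "config_resolved.yaml").open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    criteria = config.criteria_objects()
    arrays = {d: build_array(d) for d in config.detectors}

    # ---- stage 1: QA cohort ------------------------------------------------
    rng = stage_rng(config.seed, "qa_cohort")
    series_vals: dict[str, list[float]] = {
        _cohort_key(d, p, c): []
        for d in config.detectors
        for p in config.procedures
        for c in criteria
    }
    n_coalescence_failures = 0
    stride = max(1, int(round(config.ref_spacing_mm / config.gen_spacing_mm)))
    first_plan_artifacts = None

    for plan in range(config.n_qa_plans):
        if config.plan_style == "open":
            spec = _open_field_spec(config.noise_sigma)
        else:
            spec = random_field_spec(rng)
        plan_seed = int(rng.integers(0, 2**31 - 1))
        clean = generate_vmat_dosemap(spec, 0, spacing_mm=config.gen_spacing_mm)
        delivered = add_measurement_noise(clean, config.noise_sigma, plan_seed)
        reference = clean.decimate(stride)

        for det in config.detectors:
            for proc in config.procedures:
                try:
                    if proc == "sa":
                        measured = sample(delivered, arrays[det], (0.0, 0.0))
                    else:
                        measured = acquire_coalesced(
                            delivered, arrays[det], tolerance=config.coalescence_tolerance
                        )
                except CoalescenceError as exc:
                    logger.warning("plan %d %s %s: %s", plan, det, proc, exc)
                    n_coalescence_failures += 1
                    continue
                fld = None
                for crit in criteria:
                    if config.idealized_measurement:
                        result = gamma_map(reference, reference, crit)
                    else:
                        if fld is None:
                            widest = max(criteria, key=lambda c: c.cap)
                            bounds = evaluated_bounds_for(reference, widest)
                            fld = prepare_evaluated(
                                measured, min(c.subgrid for c in criteria), bounds
                            )
                        result = gamma_map(reference, fld, crit)
                    series_vals[_cohort_key(det, proc, crit)].append(pass_rate(result))
                if plan == 0 and first_plan_artifacts is None:
                    first_plan_artifacts = (reference, measured)
        logger.info("qa cohort: plan %d/%d scored", plan + 1, config.n_qa_plans)

    series = {
        key: spc.QaSeries(np.asarray(vals), labels=dict(zip(("detector", "procedure", "criteria"), key.split("|"))))
        for key, vals in series_vals.items()
        if len(vals) >= 2
    }

    # ---- stage 2: SPC / PCA ------------------------------------------------
    spc_summary: dict[str, dict] = {}
    for key, qa in series.items():
        det, proc, crit_label = key.split("|")
        baseline_n = min(config.baseline_n, qa.n)
        chart = spc.control_limits(qa, baseline_n=baseline_n)
        limits = spc.action_limits(qa, beta=config.beta, target=config.target)
        # capability of this cohort against the SA-derived action limit
        sa_key = f"{det}|sa|{crit_label}"
        sa_limits = (
            spc.action_limits(series[sa_key], beta=config.beta, target=config.target)
            if sa_key in series
            else limits
        )
        kept = spc.remove_out_of_control(qa, chart.lcl)
        try:
            cap_res = spc.cpk(kept, lal=sa_limits.lal)
            cpk_val, cpl, cpu = cap_res.cpk, cap_res.cpl, cap_res.cpu
        except ValueError:
            cpk_val = cpl = cpu = None
        spc_summary[key] = {
            "n": qa.n,
            "cl": chart.cl,
            "mr_bar": chart.mr_bar,
            "lcl": chart.lcl,
            "n_flagged": int(chart.flagged.size),
            "flag_rate_percent": spc.flag_rate(int(chart.flagged.size), qa.n),
            "delta_a": limits.delta_a,
            "lal": limits.lal,
            "ual": limits.ual,
            "sigma": limits.sigma,
            "lal_sa_reference": sa_limits.lal,
            "cpk": cpk_val,
            "cpl": cpl,
            "cpu": cpu,
        }

    # ---- stage 3: cohort comparisons ---------------------------------------
    comparisons: dict[str, dict] = {}
    for det in config.detectors:
        for crit in criteria:
            key_sa = _cohort_key(det, "sa", crit)
            key_co = _cohort_key(det, "coalescence", crit)
            if key_sa in series and key_co in series and series[key_sa].n == series[key_co].n:
                cmp_res = spc.compare_cohorts(series[key_co], series[key_sa])
                comparisons[f"{det}|{crit.label()}"] = dataclasses.asdict(cmp_res)

    # ---- stage 4: sensitivity / ROC ----------------------------------------
    sens_seed = int(stage_rng(config.seed, "sensitivity").integers(0, 2**31 - 1))
    study = run_error_study(
        n_plans=config.n_error_plans,
        error_specs=config.error_objects(),
        detectors=config.detectors,
        procedures=config.procedures,
        criteria=config.sensitivity_criteria_objects(),
        seed=sens_seed,
        noise_sigma=config.noise_sigma,
        coalescence_tolerance=config.coalescence_tolerance,
        gen_spacing_mm=config.gen_spacing_mm,
        ref_spacing_mm=config.ref_spacing_mm,
    )
    roc_summary = {
        key: {
            "auc": r.auc,
            "p_value": r.p_value,
            "n_control": r.n_control,
            "n_test": r.n_test,
        }
        for key, r in study.roc.items()
    }

    # ---- stage 5: profile comparison ---------------------------------------
    profiles = {}
    if first_plan_artifacts is not None and not config.idealized_measurement:
        reference, measured = first_plan_artifacts
        for direction in ("lateral", "longitudinal", "diagonal"):
            prof = profile_compare(measured, reference, direction=direction)
            prof.to_csv(out_dir / f"profile_{direction}.csv", index=False)
            valid = prof["gamma"].dropna()
            profiles[direction] = {
                "n_points": int(len(prof)),
                "max_gamma": float(valid.max()) if len(valid) else None,
            }

    # ---- outputs -----------------------------------------------------------
    for key, qa in series.items():
        safe = key.replace("|", "_").replace("%", "pct").replace("/", "-").replace(" ", "_")
        pd.DataFrame({"pass_rate": qa.values}).to_csv(out_dir / f"series_{safe}.csv", index=False)
    study.records.to_csv(out_dir / "sensitivity_records.csv", index=False)

    summary = {
        "config": config.to_dict(),
        "qa_series": {k: [float(v) for v in s.values] for k, s in series.items()},
        "spc": spc_summary,
        "comparisons": comparisons,
        "sensitivity_roc": roc_summary,
        "n_coalescence_failures_qa": n_coalescence_failures,
        "n_coalescence_failures_sensitivity": study.n_coalescence_failures,
        "profiles": profiles,
    }
    with (out_dir / "summary.json").open("w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)

    if config.figures:
        _render_figures(series, spc_summary, study, out_dir)

    logger.info(
        "study complete: %d cohorts, %d sensitivity records, %d+%d coalescence failures",
        len(series),
        len(study.records),
        n_coalescence_failures,
        study.n_coalescence_failures,
    )
    return StudyResult(config=config, summary=summary, series=series, output_dir=out_dir)


def _render_figures(series, spc_summary, study, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for key, qa in series.items():
        info = spc_summary[key]
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        idx = np.arange(1, qa.n + 1)
        ax1.plot(idx, qa.values, "o-", ms=3)
        ax1.axhline(info["cl"], color="g", lw=1, label="CL")
        ax1.axhline(info["lcl"], color="r", lw=1, ls="--", label="LCL")
        ax1.set_ylabel("percent gamma")
        ax1.set_title(key)
        ax1.legend(loc="lower left", fontsize=8)
        ax2.plot(idx[1:], np.abs(np.diff(qa.values)), "o-", ms=3)
        ax2.axhline(info["mr_bar"], color="g", lw=1)
        ax2.set_ylabel("moving range")
        ax2.set_xlabel("plan number")
        safe = key.replace("|", "_").replace("%", "pct").replace("/", "-").replace(" ", "_")
        fig.savefig(out_dir / f"chart_{safe}.png", dpi=110)
        plt.close(fig)

    for key, r in study.roc.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(r.fpr, r.tpr, "-o", ms=3)
        ax.plot([0, 1], [0, 1], "k:", lw=1)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"{key}\nAUC={r.auc:.3f}  p={r.p_value:.3g}", fontsize=8)
        safe = key.replace("|", "_").replace("%", "pct").replace("/", "-").replace(" ", "_")
        fig.savefig(out_dir / f"roc_{safe}.png", dpi=110, bbox_inches="tight")
        plt.close(fig)
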