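"""Error-detection sensitivity: delta-gamma records and ROC/AUC separation.

A QA procedure detects an injected delivery error when the percent-gamma
pass rate of the comparison against the error-carrying calculation drops
below the no-error comparison:

    delta_gamma = gamma_NE - gamma_IE      (> 0: detected)

Across a cohort of plans, the no-error pass rates form the control group
and the error-induced pass rates the test group of a ROC analysis; a lower
pass rate scores as more "error-like".  The AUC equals the Mann-Whitney
rank statistic U / (n1 * n2) (ties half credit), i.e. the probability that
a random error case looks more error-like than a random no-error case; the
accompanying p-value comes from the two-sided rank-sum test.

``run_error_study`` generates a synthetic plan cohort, samples each plan
with both detector models under standard acquisition and coalescence,
scores no-error and error-injected references, and emits the per-plan
records plus per-scenario ROC results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import (
    ErrorSpec,
    add_measurement_noise,
    apply_error,
    generate_vmat_dosemap,
    random_field_spec,
)
from .detector import CoalescenceError, acquire_coalesced, build_array, sample
from .gamma import (
    GammaCriteria,
    evaluated_bounds_for,
    gamma_map,
    pass_rate,
    prepare_evaluated,
)

__all__ = [
    "SensitivityRecord",
    "RocResult",
    "StudyTable",
    "delta_gamma",
    "roc_auc",
    "run_error_study",
]

logger = logging.getLogger(__name__)


@dataclass
class SensitivityRecord:
    """Per-plan sensitivity of one scenario to one injected error."""

    plan_id: int
    detector: str
    procedure: str
    criteria: str
    error_kind: str
    gamma_ne: float
    gamma_ie: float

    @property
    def delta(self) -> float:
        return self.gamma_ne - self.gamma_ie

    @property
    def detected(self) -> bool:
        return self.delta > 0


@dataclass
class RocResult:
    """ROC curve, AUC and rank-test p-value of one error-detection scenario."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    p_value: float
    n_control: int
    n_test: int


@dataclass
class StudyTable:
    """Output bundle of an error-detection study."""

    records: pd.DataFrame
    roc: dict[str, RocResult]
    n_coalescence_failures: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)


def delta_gamma(gamma_ne: float, gamma_ie: float) -> tuple[float, bool]:
    """(gamma_NE - gamma_IE, detected flag); both inputs in [0, 100]."""
    if not (0 <= gamma_ne <= 100 and 0 <= gamma_ie <= 100):
        raise ValueError("percent gamma values must lie in [0, 100]")
    d = gamma_ne - gamma_ie
    return d, d > 0


def roc_auc(control, test) -> RocResult:
    """ROC of separating test (error) from control (no-error) pass rates.

    Lower pass rate means more error-like.  The curve sweeps a threshold
    over the pooled scores; AUC is the trapezoid area and coincides with
    the pair-counting rank statistic (ties counted half).
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("both ROC groups must be non-empty")
    if (c.size == 1 and t.size == 1) or (np.ptp(c) == 0 and np.ptp(t) == 0 and c[0] == t[0]):
        logger.warning("degenerate ROC: groups carry no score variation")

    # error-likeness score: negated pass rate
    scores = np.concatenate([-c, -t])
    labels = np.concatenate([np.zeros(c.size, bool), np.ones(t.size, bool)])
    order = np.argsort(-scores, kind="mergesort")  # descending score
    scores, labels = scores[order], labels[order]

    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    # collapse ties: keep the last point of each tied score block
    keep = np.r_[np.diff(scores) != 0, True]
    tpr = np.r_[0.0, tps[keep] / t.size]
    fpr = np.r_[0.0, fps[keep] / c.size]
    auc = float(np.trapezoid(tpr, fpr))

    if np.ptp(np.concatenate([c, t])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(t, c, alternative="two-sided").pvalue)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, p_value=p, n_control=c.size, n_test=t.size)


# ---------------------------------------------------------------------------
# the error study
# ---------------------------------------------------------------------------

DEFAULT_ERRORS = (
    ErrorSpec(kind="DLG_shift", magnitude=1.0),  # +1 mm on the leaf gap
    ErrorSpec(kind="MU_scale", magnitude=0.02),  # +2% output
)


def _measure(dose, array, procedure, tolerance):
    if procedure == "sa":
        return sample(dose, array, (0.0, 0.0))
    if procedure == "coalescence":
        return acquire_coalesced(dose, array, tolerance=tolerance)
    raise ValueError(f"unknown procedure: {procedure!r}")


def run_error_study(
    n_plans: int = 8,
    error_specs=DEFAULT_ERRORS,
    detectors=("d729", "d1500"),
    procedures=("sa", "coalescence"),
    criteria=(
        GammaCriteria(3.0, 2.0, normalization="global"),
        GammaCriteria(3.0, 2.0, normalization="local"),
    ),
    seed: int = 0,
    *,
    noise_sigma: float = 0.005,
    coalescence_tolerance: float = 0.05,
    gen_spacing_mm: float = 1.0,
    ref_spacing_mm: float = 2.5,
) -> StudyTable:
    """Simulate the error-detection experiment on a synthetic plan cohort.

    For each plan a modulated field is generated and delivered without
    error; each (detector, procedure) measurement of that delivery is
    scored against the no-error calculation (gamma_NE) and against each
    error-injected calculation (gamma_IE) under every criteria set.  A ROC
    result is produced per (error, detector, procedure, criteria) scenario,
    pooling pass rates across plans.  Coalescence failures are logged and
    excluded with a count.
    """
    rng = np.random.default_rng(seed)
    stride = max(1, int(round(ref_spacing_mm / gen_spacing_mm)))

    records: list[dict] = []
    failures: list[tuple[int, str]] = []

    for plan in range(n_plans):
        spec = random_field_spec(rng)
        plan_seed = int(rng.integers(0, 2**31 - 1))
        # noise-free calculation of the nominal plan; the delivered map is
        # the same fluence plus measurement noise
        clean_map = generate_vmat_dosemap(spec, 0, spacing_mm=gen_spacing_mm)
        delivered = add_measurement_noise(clean_map, noise_sigma, plan_seed)
        ref_ne = clean_map.decimate(stride)
        refs_ie = {
            (err.kind, err.magnitude): generate_vmat_dosemap(
                apply_error(spec, err), 0, spacing_mm=gen_spacing_mm
            ).decimate(stride)
            for err in error_specs
        }

        for det in detectors:
            array = build_array(det)
            for proc in procedures:
                try:
                    measured = _measure(delivered, array, proc, coalescence_tolerance)
                except CoalescenceError as exc:
                    logger.warning("plan %d %s %s: %s", plan, det, proc, exc)
                    failures.append((plan, f"{det}/{proc}"))
                    continue
                for crit in criteria:
                    # one fine grid serves the no-error and all error
                    # references (DLG widening pads the bounds slightly)
                    bounds = evaluated_bounds_for(ref_ne, crit, extra_mm=2.0)
                    fld = prepare_evaluated(measured, crit.subgrid, bounds)
                    g_ne = pass_rate(gamma_map(ref_ne, fld, crit))
                    for err in error_specs:
                        g_ie = pass_rate(
                            gamma_map(refs_ie[(err.kind, err.magnitude)], fld, crit)
                        )
                        records.append(
                            {
                                "plan_id": plan,
                                "detector": det,
                                "procedure": proc,
                                "criteria": crit.label(),
                                "error_kind": err.kind,
                                "error_magnitude": err.magnitude,
                                "gamma_ne": g_ne,
                                "gamma_ie": g_ie,
                                "delta_gamma": g_ne - g_ie,
                                "detected": g_ne - g_ie > 0,
                            }
                        )

    df = pd.DataFrame.from_records(records)
    roc: dict[str, RocResult] = {}
    if len(df):
        for (err, mag, det, proc, crit_label), grp in df.groupby(
            ["error_kind", "error_magnitude", "detector", "procedure", "criteria"]
        ):
            key = f"{err}({mag:g})|{det}|{proc}|{crit_label}"
            roc[key] = roc_auc(grp["gamma_ne"].to_numpy(), grp["gamma_ie"].to_numpy())
    logger.info(
        "error study: %d plans, %d records, %d coalescence failures",
        n_plans,
        len(df),
        len(failures),
    )
    return StudyTable(
        records=df,
        roc=roc,
        n_coalescence_failures=len(failures),
        failures=failures,
    )
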