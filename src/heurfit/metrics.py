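"""Per-participant introspective-accuracy measures and their chance levels.

Weight accuracy compares model-averaged fitted weights with model-averaged
self-reported weights: a participant-level Pearson correlation across the K
attributes (the primary, scale-free measure) and the mean absolute weight
difference. Method accuracy compares reported heuristic use with the fitted
heuristic-family probabilities (heuristic error), identifies the single
reported model by thresholding the three extents at 0.5, and scores it via
the ratio of its posterior probability to the best-fitting model's (a Bayes
factor in [0, 1], 1 iff the participant reported the best-fitting method) and
via the binary correct-method indicator, whose chance level under uniform
guessing is exactly 1/6.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .inference import ParticipantFit, model_averaged_reported_weights
from .models import ChoiceModelSpec, validate_model_spec
from .simulate import SelfReport

__all__ = [
    "AccuracyMetrics",
    "ChanceLevels",
    "weight_correlation",
    "absolute_weight_error",
    "heuristic_error",
    "reported_model",
    "reported_model_bayes_factor",
    "correct_method",
    "compute_metrics",
    "chance_levels",
]

log = logging.getLogger(__name__)

#: analytic chance of naming the best-fitting model among six by uniform guessing
CORRECT_METHOD_CHANCE = 1.0 / 6.0


@dataclasses.dataclass
class AccuracyMetrics:
    """The five accuracy scores for one (participant fit, report) pair.

    ``weight_correlation`` is None when either weight vector is constant
    (Pearson r undefined); such participants are excluded from cohort means.
    """

    participant_id: str
    weight_correlation: float | None
    absolute_weight_error: float
    heuristic_error: float
    reported_model_id: int
    reported_model_bayes_factor: float
    correct_method: bool


@dataclasses.dataclass
class ChanceLevels:
    """Permutation-bootstrap chance level of each metric.

    Means over ``n_boot`` random re-pairings of self-reports to fits; the
    analytic 1/6 for correct_method is reported alongside the empirical value.
    """

    weight_correlation: float
    absolute_weight_error: float
    heuristic_error: float
    reported_model_bayes_factor: float
    correct_method: float
    correct_method_analytic: float
    n_boot: int
    seed: int


def weight_correlation(fitted: np.ndarray, reported: np.ndarray) -> float | None:
    """Pearson correlation across attributes; None when undefined."""
    fitted = np.asarray(fitted, dtype=float)
    reported = np.asarray(reported, dtype=float)
    if fitted.shape != reported.shape:
        raise ValueError("fitted and reported weights must have equal length")
    if fitted.shape[0] < 3:
        raise ValueError("need at least 3 attributes for a correlation")
    if np.ptp(fitted) == 0 or np.ptp(reported) == 0:
        return None
    return float(stats.pearsonr(fitted, reported).statistic)


def absolute_weight_error(fitted: np.ndarray, reported: np.ndarray) -> float:
    """Mean elementwise absolute difference across attributes (range [0, 2])."""
    fitted = np.asarray(fitted, dtype=float)
    reported = np.asarray(reported, dtype=float)
    if fitted.shape != reported.shape:
        raise ValueError("fitted and reported weights must have equal length")
    return float(np.abs(fitted - reported).mean())


def heuristic_error(family_probs: np.ndarray, extents: np.ndarray) -> float:
    """Mean |reported extent − fitted family probability| over the 3 heuristics."""
    family_probs = np.asarray(family_probs, dtype=float)
    extents = np.asarray(extents, dtype=float)
    for name, v in (("family_probs", family_probs), ("extents", extents)):
        if v.shape != (3,) or np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must be three values in [0, 1]")
    return float(np.abs(family_probs - extents).mean())


def reported_model(report: SelfReport) -> ChoiceModelSpec:
    """The single model a participant's heuristic extents describe.

    Each extent is dichotomized at 0.5 (> 0.5 means "used"; exactly 0.5 maps
    conservatively to "not used"). If both single_attribute and binary_weights
    exceed 0.5 — an inadmissible combination — single_attribute wins, since it
    is the special case that subsumes binary weights; the conflict is logged.
    """
    sa, bw, bv = (bool(e > 0.5) for e in report.extents)
    if sa and bw:
        log.info(
            "participant %s reported both single_attribute and binary_weights; "
            "resolving to single_attribute", report.participant_id,
        )
        bw = False
    return validate_model_spec(sa, bw, bv)


def reported_model_bayes_factor(
    model_probs: np.ndarray, reported: ChoiceModelSpec
) -> float:
    """P(reported model) / P(best-fitting model); 1 iff they coincide."""
    p = np.asarray(model_probs, dtype=float)
    if p.shape != (6,):
        raise ValueError("model_probs must have six entries")
    return float(p[reported.model_id - 1] / p.max())


def correct_method(model_probs: np.ndarray, reported: ChoiceModelSpec) -> bool:
    """Whether the reported model is the best-fitting one (ties → lowest id)."""
    p = np.asarray(model_probs, dtype=float)
    if p.shape != (6,):
        raise ValueError("model_probs must have six entries")
    ties = np.flatnonzero(np.isclose(p, p.max(), rtol=0, atol=1e-12))
    if len(ties) > 1:
        log.info("argmax model tie among ids %s; using the lowest", (ties + 1).tolist())
    return int(ties[0]) + 1 == reported.model_id


def compute_metrics(fit: ParticipantFit, report: SelfReport) -> AccuracyMetrics:
    """All five accuracy scores for one participant."""
    avg_reported = model_averaged_reported_weights(report, fit.model_probs)
    rep_spec = reported_model(report)
    return AccuracyMetrics(
        participant_id=fit.participant_id,
        weight_correlation=weight_correlation(fit.averaged_w, avg_reported),
        absolute_weight_error=absolute_weight_error(fit.averaged_w, avg_reported),
        heuristic_error=heuristic_error(fit.family_probs, report.extents),
        reported_model_id=rep_spec.model_id,
        reported_model_bayes_factor=reported_model_bayes_factor(
            fit.model_probs, rep_spec
        ),
        correct_method=correct_method(fit.model_probs, rep_spec),
    )


def _mean_metrics(fits: list[ParticipantFit], reports: list[SelfReport]) -> np.ndarray:
    """(corr, abs_err, heur_err, bf, correct) means over a pairing; corr skips
    undefined values."""
    rows = [compute_metrics(f, r) for f, r in zip(fits, reports)]
    corrs = [m.weight_correlation for m in rows if m.weight_correlation is not None]
    n_excluded = len(rows) - len(corrs)
    if n_excluded:
        log.debug("excluded %d undefined weight correlations", n_excluded)
    return np.array(
        [
            np.mean(corrs) if corrs else np.nan,
            np.mean([m.absolute_weight_error for m in rows]),
            np.mean([m.heuristic_error for m in rows]),
            np.mean([m.reported_model_bayes_factor for m in rows]),
            np.mean([float(m.correct_method) for m in rows]),
        ]
    )


def chance_levels(
    cohort_fits: list[ParticipantFit],
    reports: list[SelfReport],
    n_boot: int = 1000,
    seed: int = 0,
) -> ChanceLevels:
    """Chance level of each metric by re-pairing reports with other fits.

    Each bootstrap iteration permutes the report-to-fit pairing uniformly at
    random and recomputes the cohort-mean metrics; the chance level is the
    mean over iterations. correct_method's analytic chance under uniform
    method guessing (1/6) is reported alongside.
    """
    if len(cohort_fits) != len(reports):
        raise ValueError("need one report per fit")
    if len(cohort_fits) < 2:
        raise ValueError("chance levels need at least 2 participants")
    rng = np.random.default_rng(seed)
    acc = np.zeros(5)
    n_defined = 0
    for _ in range(n_boot):
        perm = rng.permutation(len(reports))
        vals = _mean_metrics(cohort_fits, [reports[i] for i in perm])
        if np.isnan(vals[0]):
            vals[0] = 0.0
        else:
            n_defined += 1
        acc += vals
    acc /= n_boot
    corr_chance = acc[0] * n_boot / n_defined if n_defined else float("nan")
    return ChanceLevels(
        weight_correlation=float(corr_chance),
        absolute_weight_error=float(acc[1]),
        heuristic_error=float(acc[2]),
        reported_model_bayes_factor=float(acc[3]),
        correct_method=float(acc[4]),
        correct_method_analytic=CORRECT_METHOD_CHANCE,
        n_boot=n_boot,
        seed=seed,
    )
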