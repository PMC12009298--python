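"""Synthetic tasks, deciders, choices and self-reports with ground truth.

Emulates the structure of a two-alternative multi-attribute choice experiment:
each trial shows two options described by K attributes scaled to [0, 1], with
the two options forced to differ substantially on every attribute so that each
trial is informative. Simulated deciders use one of the six strategies in
:mod:`heurfit.models`, with inverse temperatures drawn from the Gamma(4, 1)
fitting prior, and can emit noiseless or noise-perturbed self-reports of their
weights and heuristic use.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .models import (
    ALL_SPECS,
    ChoiceDataset,
    ChoiceModelSpec,
    PriorConfig,
    choice_probability,
    enumerate_weight_configs,
    validate_weights,
)

__all__ = [
    "TaskConfig",
    "TrialSet",
    "SimulatedDecider",
    "SelfReport",
    "DeciderTruth",
    "CohortTruth",
    "generate_trials",
    "simulate_choices",
    "simulate_self_report",
    "generate_cohort",
]


@dataclasses.dataclass(frozen=True)
class TaskConfig:
    """Task layout: K attributes, trial count, per-attribute separation.

    ``min_separation`` is the smallest allowed |x_A − x_B| on every attribute;
    the default 0.25 (on the unit scale) keeps every trial informative and
    rules out binary-value ties. ``value_grid`` optionally restricts attribute
    values to discrete levels in [0, 1].
    """

    k: int = 9
    n_trials: int = 100
    min_separation: float = 0.25
    value_grid: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.min_separation < 1:
            raise ValueError("min_separation must lie in (0, 1)")
        if self.value_grid is not None:
            grid = np.sort(np.asarray(self.value_grid, dtype=float))
            if grid.min() < 0 or grid.max() > 1:
                raise ValueError("value_grid levels must lie in [0, 1]")


@dataclasses.dataclass
class TrialSet:
    """Trials with choices not yet observed: two (n_trials, K) value arrays."""

    x_a: np.ndarray
    x_b: np.ndarray

    def __len__(self) -> int:
        return self.x_a.shape[0]


@dataclasses.dataclass
class SimulatedDecider:
    """A ground-truth decision-maker: strategy, weights, inverse temperature."""

    spec: ChoiceModelSpec
    w: np.ndarray
    beta: float
    report_noise: float = 0.0

    def __post_init__(self) -> None:
        self.w = validate_weights(self.spec, self.w)
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.report_noise < 0:
            raise ValueError("report_noise must be >= 0")


@dataclasses.dataclass
class SelfReport:
    """A participant's (or observer's) report of their choice process.

    ``graded``: signed weights in [−1, 1] per attribute. ``binary``: signed
    checklist weights in {−1, 0, 1}. ``single``: signed one-hot vector naming
    the one most-used attribute. ``extents``: how much each heuristic was used,
    in [0, 1], ordered (single_attribute, binary_weights, binary_values).
    """

    participant_id: str
    graded: np.ndarray
    binary: np.ndarray
    single: np.ndarray
    extents: np.ndarray

    def __post_init__(self) -> None:
        self.graded = np.asarray(self.graded, dtype=float)
        self.binary = np.asarray(self.binary, dtype=float)
        self.single = np.asarray(self.single, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        k = self.graded.shape[0]
        if self.binary.shape != (k,) or self.single.shape != (k,):
            raise ValueError("graded, binary and single must share one length K")
        if np.any(np.abs(self.graded) > 1):
            raise ValueError("graded weights must lie in [-1, 1]")
        if not np.isin(self.binary, (-1.0, 0.0, 1.0)).all():
            raise ValueError("binary weights must lie in {-1, 0, 1}")
        nonzero = np.flatnonzero(self.single)
        if len(nonzero) != 1 or abs(self.single[nonzero[0]]) != 1.0:
            raise ValueError("single must have exactly one entry of ±1")
        if self.extents.shape != (3,) or np.any((self.extents < 0) | (self.extents > 1)):
            raise ValueError("extents must be three values in [0, 1]")


@dataclasses.dataclass
class DeciderTruth:
    """Generating process of one simulated dataset (for recovery scoring)."""

    participant_id: str
    model_id: int
    w: np.ndarray
    beta: float
    report_noise: float = 0.0

    @property
    def spec(self) -> ChoiceModelSpec:
        return ChoiceModelSpec.from_id(self.model_id)


@dataclasses.dataclass
class CohortTruth:
    """Ground truth for a simulated cohort, one record per dataset."""

    records: list[DeciderTruth]

    def by_id(self, participant_id: str) -> DeciderTruth:
        for rec in self.records:
            if rec.participant_id == participant_id:
                return rec
        raise KeyError(participant_id)


def _sample_values(rng: np.random.Generator, shape, grid: np.ndarray | None) -> np.ndarray:
    if grid is None:
        return rng.uniform(0.0, 1.0, shape)
    return rng.choice(grid, size=shape)


def generate_trials(config: TaskConfig, seed: int) -> TrialSet:
    """Draw trials whose options differ by ≥ min_separation on every attribute.

    Values are uniform on [0, 1] (or uniform over ``value_grid``), resampled
    per attribute until the separation constraint holds. Deterministic given
    ``seed``.
    """
    grid = None
    if config.value_grid is not None:
        grid = np.sort(np.asarray(config.value_grid, dtype=float))
        if grid.max() - grid.min() < config.min_separation:
            raise ValueError("value_grid span cannot satisfy min_separation")
    rng = np.random.default_rng(seed)
    shape = (config.n_trials, config.k)
    x_a = _sample_values(rng, shape, grid)
    x_b = _sample_values(rng, shape, grid)
    bad = np.abs(x_a - x_b) < config.min_separation
    while bad.any():
        n_bad = int(bad.sum())
        x_a[bad] = _sample_values(rng, n_bad, grid)
        x_b[bad] = _sample_values(rng, n_bad, grid)
        bad = np.abs(x_a - x_b) < config.min_separation
    return TrialSet(x_a=x_a, x_b=x_b)


def simulate_choices(
    decider: SimulatedDecider,
    trials: TrialSet,
    seed: int,
    participant_id: str = "sim",
) -> ChoiceDataset:
    """Draw one choice per trial from the decider's choice probabilities."""
    rng = np.random.default_rng(seed)
    p_a = np.array(
        [
            choice_probability(decider.spec, decider.w, decider.beta, a, b)
            for a, b in zip(trials.x_a, trials.x_b)
        ]
    )
    choices = (rng.random(len(trials)) >= p_a).astype(int)  # 0 = A, 1 = B
    return ChoiceDataset(
        participant_id=participant_id, x_a=trials.x_a, x_b=trials.x_b, choices=choices
    )


def _truth_report_slots(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary and single-attribute renderings of a weight vector.

    Binary: sign of any weight with magnitude > 0.5 (identity for weights
    already in {−1, 0, 1}). Single: signed one-hot at the largest-magnitude
    attribute (lowest index on ties; sign +1 for a zero vector).
    """
    binary = np.where(np.abs(w) > 0.5, np.sign(w), 0.0)
    idx = int(np.argmax(np.abs(w)))
    single = np.zeros_like(w)
    single[idx] = 1.0 if w[idx] >= 0 else -1.0
    return binary, single


def simulate_self_report(
    decider: SimulatedDecider, seed: int, participant_id: str = "sim"
) -> SelfReport:
    """Emit a self-report; exact at ``report_noise=0``, perturbed otherwise.

    Noise model: additive N(0, noise) on weight magnitudes and heuristic
    extents, clipped to range, plus sign flips on the graded weights with
    probability min(0.5, noise/2); the binary and single slots are derived
    from the noisy graded vector, mimicking a participant whose introspection
    itself is noisy.
    """
    rng = np.random.default_rng(seed)
    noise = decider.report_noise
    w = decider.w.copy()
    extents = decider.spec.flags.copy()
    if noise > 0:
        mag = np.clip(np.abs(w) + rng.normal(0.0, noise, w.shape), 0.0, 1.0)
        sign = np.where(w != 0, np.sign(w), rng.choice([-1.0, 1.0], w.shape))
        flip = rng.random(w.shape) < min(0.5, noise / 2)
        graded = mag * np.where(flip, -sign, sign)
        extents = np.clip(extents + rng.normal(0.0, noise, 3), 0.0, 1.0)
    else:
        graded = w
    binary, single = _truth_report_slots(graded)
    return SelfReport(
        participant_id=participant_id,
        graded=graded,
        binary=binary,
        single=single,
        extents=extents,
    )


def _draw_weights(
    spec: ChoiceModelSpec, k: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.is_discrete:
        configs = enumerate_weight_configs(spec, k)
        return configs[rng.integers(len(configs))]
    return rng.uniform(-1.0, 1.0, k)


def generate_cohort(
    n_per_model: int,
    task: TaskConfig,
    seed: int,
    prior: PriorConfig | None = None,
    report_noise: float = 0.0,
    fixed_beta: float | None = None,
) -> tuple[list[ChoiceDataset], list[SelfReport], CohortTruth]:
    """Simulate a balanced cohort: ``n_per_model`` deciders per model 1..6.

    Continuous weights are uniform on [−1, 1] per attribute, discrete weights
    uniform over the model's admissible configurations, and beta is drawn from
    the Gamma fitting prior unless ``fixed_beta`` is given. One global seed
    fans out to per-decider substreams, so any dataset is independently
    reproducible.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    prior = prior or PriorConfig()
    root = np.random.SeedSequence(seed)
    datasets: list[ChoiceDataset] = []
    reports: list[SelfReport] = []
    records: list[DeciderTruth] = []
    idx = 0
    for spec in ALL_SPECS:
        for _ in range(n_per_model):
            idx += 1
            pid = f"sim_{idx:03d}"
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,))
            s_param, s_trial, s_choice, s_report = child.spawn(4)
            rng = np.random.default_rng(s_param)
            w = _draw_weights(spec, task.k, rng)
            beta = (
                float(fixed_beta)
                if fixed_beta is not None
                else float(rng.gamma(prior.beta_shape, 1.0 / prior.beta_rate))
            )
            decider = SimulatedDecider(spec=spec, w=w, beta=beta, report_noise=report_noise)
            trials = generate_trials(task, seed=s_trial)
            datasets.append(simulate_choices(decider, trials, seed=s_choice, participant_id=pid))
            reports.append(simulate_self_report(decider, seed=s_report, participant_id=pid))
            records.append(
                DeciderTruth(
                    participant_id=pid,
                    model_id=spec.model_id,
                    w=w,
                    beta=beta,
                    report_noise=report_noise,
                )
            )
    return datasets, reports, CohortTruth(records=records)
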