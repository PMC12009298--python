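"""The six-model family of two-alternative multi-attribute choice strategies.

Every model shares a weighted-additive core: each option's value is a linear
combination of its K attribute values (scaled to [0, 1]) with signed attribute
weights, and the probability of choosing option A is a softmax over the two
option values — equivalently, a logistic function of the inverse temperature
times the value difference.

Three composable heuristics simplify that core:

* ``single_attribute`` (take-the-best / lexicographic): exactly one weight is
  ±1, all others are 0.
* ``binary_weights`` (equal weights): every weight is in {−1, 0, 1} — an
  attribute is "in" (positively or negatively) or "out".
* ``binary_values`` (weighted pros): per attribute only *which* option is
  greater is represented — the greater option's value becomes 1, the other 0.

``single_attribute`` and ``binary_weights`` cannot be combined (the former is
a special case of the latter), leaving exactly six valid models:

===  ================  ==============  =============
id   single_attribute  binary_weights  binary_values
===  ================  ==============  =============
1    —                 —               —   ("classically rational")
2    —                 —               ✓
3    —                 ✓               —
4    —                 ✓               ✓
5    ✓                 —               —
6    ✓                 —               ✓
===  ================  ==============  =============
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "ChoiceModelSpec",
    "ChoiceDataset",
    "PriorConfig",
    "InvalidModelError",
    "ConstraintViolationError",
    "NotEnumerableError",
    "ALL_SPECS",
    "HEURISTICS",
    "FAMILY_MEMBERS",
    "validate_model_spec",
    "validate_weights",
    "transform_attribute_values",
    "choice_probability",
    "log_likelihood",
    "enumerate_weight_configs",
    "log_sigmoid",
]


class InvalidModelError(ValueError):
    """Raised for a heuristic combination outside the six-model family."""


class ConstraintViolationError(ValueError):
    """Raised when a weight vector violates its model's constraints."""


class NotEnumerableError(ValueError):
    """Raised when discrete enumeration is requested for a continuous model."""


#: heuristic names in canonical order; family probabilities follow this order.
HEURISTICS = ("single_attribute", "binary_weights", "binary_values")

# (single_attribute, binary_weights, binary_values) in model-id order 1..6
_FLAG_TABLE = (
    (False, False, False),
    (False, False, True),
    (False, True, False),
    (False, True, True),
    (True, False, False),
    (True, False, True),
)

#: model ids belonging to each heuristic family.
FAMILY_MEMBERS = {
    "single_attribute": (5, 6),
    "binary_weights": (3, 4),
    "binary_values": (2, 4, 6),
}


@dataclasses.dataclass(frozen=True)
class ChoiceModelSpec:
    """One of the six valid heuristic combinations."""

    single_attribute: bool
    binary_weights: bool
    binary_values: bool
    model_id: int

    @classmethod
    def from_flags(
        cls, single_attribute: bool, binary_weights: bool, binary_values: bool
    ) -> "ChoiceModelSpec":
        if single_attribute and binary_weights:
            raise InvalidModelError(
                "single_attribute and binary_weights cannot be combined: "
                "the former is a special case of the latter"
            )
        flags = (bool(single_attribute), bool(binary_weights), bool(binary_values))
        return cls(*flags, model_id=_FLAG_TABLE.index(flags) + 1)

    @classmethod
    def from_id(cls, model_id: int) -> "ChoiceModelSpec":
        if not 1 <= int(model_id) <= 6:
            raise InvalidModelError(f"model_id must be 1..6, got {model_id}")
        return cls(*_FLAG_TABLE[int(model_id) - 1], model_id=int(model_id))

    @property
    def is_discrete(self) -> bool:
        """True when the admissible weight vectors form a finite set."""
        return self.single_attribute or self.binary_weights

    @property
    def flags(self) -> np.ndarray:
        """Heuristic-use indicators in :data:`HEURISTICS` order, as floats."""
        return np.array(
            [self.single_attribute, self.binary_weights, self.binary_values],
            dtype=float,
        )


#: the six valid specs in model-id order.
ALL_SPECS = tuple(ChoiceModelSpec.from_id(i) for i in range(1, 7))


def validate_model_spec(
    single_attribute: bool, binary_weights: bool, binary_values: bool
) -> ChoiceModelSpec:
    """Validate a heuristic combination and return its spec (model_id 1..6)."""
    return ChoiceModelSpec.from_flags(single_attribute, binary_weights, binary_values)


def validate_weights(spec: ChoiceModelSpec, w: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Check that ``w`` satisfies ``spec``'s constraints; return it as an array.

    Models 1–2: each entry in [−1, 1]. Models 3–4: entries in {−1, 0, 1}.
    Models 5–6: exactly one entry in {−1, 1}, the rest 0.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ConstraintViolationError("weights must be a 1-D vector")
    if spec.single_attribute:
        nonzero = np.abs(w) > atol
        if nonzero.sum() != 1 or not np.isclose(np.abs(w[nonzero][0]), 1.0, atol=atol):
            raise ConstraintViolationError(
                "single-attribute models need exactly one weight of ±1, rest 0"
            )
    elif spec.binary_weights:
        if not np.all(np.isclose(w, np.round(w), atol=atol) & (np.abs(w) <= 1 + atol)):
            raise ConstraintViolationError(
                "binary-weights models need every weight in {-1, 0, 1}"
            )
    else:
        if np.any(np.abs(w) > 1 + atol):
            raise ConstraintViolationError("continuous weights must lie in [-1, 1]")
    return w


def transform_attribute_values(
    x_a: np.ndarray, x_b: np.ndarray, binary_values: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the binary-attribute-values (weighted pros) representation.

    With the flag unset this is the identity. With it set, per attribute the
    option with the greater value maps to 1 and the other to 0; exact ties map
    both to 0.5, so a tied attribute contributes nothing to the value
    difference.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if not binary_values:
        return x_a, x_b
    t_a = np.where(x_a > x_b, 1.0, np.where(x_a < x_b, 0.0, 0.5))
    return t_a, 1.0 - t_a


def log_sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 / (1 + exp(-x)))."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def choice_probability(
    spec: ChoiceModelSpec,
    w: np.ndarray,
    beta: float,
    x_a: np.ndarray,
    x_b: np.ndarray,
) -> float:
    """Probability of choosing option A on one trial.

    ``logistic(beta * (w · x̃_A − w · x̃_B))`` where x̃ are the (possibly
    binary-transformed) attribute values. Softmax over two options reduces to
    this logistic-of-difference form.
    """
    w = validate_weights(spec, w)
    if beta < 0:
        raise ConstraintViolationError("inverse temperature must be >= 0")
    t_a, t_b = transform_attribute_values(x_a, x_b, spec.binary_values)
    return float(expit(beta * (w @ (np.asarray(t_a) - np.asarray(t_b)))))


@dataclasses.dataclass
class ChoiceDataset:
    """One participant's observed two-alternative choice trials.

    ``x_a``/``x_b`` are (n_trials, K) arrays of attribute values in [0, 1];
    ``choices`` holds 0 for option A and 1 for option B.
    """

    participant_id: str
    x_a: np.ndarray
    x_b: np.ndarray
    choices: np.ndarray

    def __post_init__(self) -> None:
        self.x_a = np.atleast_2d(np.asarray(self.x_a, dtype=float))
        self.x_b = np.atleast_2d(np.asarray(self.x_b, dtype=float))
        self.choices = np.asarray(self.choices, dtype=int)
        if self.x_a.shape != self.x_b.shape:
            raise ValueError("x_a and x_b must have identical shapes")
        if self.choices.shape != (self.x_a.shape[0],):
            raise ValueError("one observed choice is required per trial")
        for name, arr in (("x_a", self.x_a), ("x_b", self.x_b)):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} attribute values must lie in [0, 1]")
        if self.choices.size and not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be 0 (option A) or 1 (option B)")

    @property
    def n_trials(self) -> int:
        return self.x_a.shape[0]

    @property
    def k(self) -> int:
        return self.x_a.shape[1]

    def signed_diffs(self, binary_values: bool) -> np.ndarray:
        """(n_trials, K) array D with rows s_t · (x̃_A − x̃_B).

        s_t is +1 when A was chosen and −1 when B was, so the log-likelihood
        of any weight vector is ``sum_t log_sigmoid(beta * (D @ w)_t)``.
        """
        t_a, t_b = transform_attribute_values(self.x_a, self.x_b, binary_values)
        sign = np.where(self.choices == 0, 1.0, -1.0)
        return (t_a - t_b) * sign[:, None]


def log_likelihood(
    spec: ChoiceModelSpec, w: np.ndarray, beta: float, data: ChoiceDataset
) -> float:
    """Log-probability of the observed choices given model parameters.

    Trials are conditionally independent; an empty dataset has likelihood 1.
    """
    w = validate_weights(spec, w)
    if data.n_trials == 0:
        return 0.0
    d = data.signed_diffs(spec.binary_values)
    return float(log_sigmoid(beta * (d @ w)).sum())


_MAX_ENUM_K = 13  # 3**13 ≈ 1.6e6 rows; beyond this enumeration is impractical


def enumerate_weight_configs(spec: ChoiceModelSpec, k: int) -> np.ndarray:
    """All admissible weight vectors of a discrete model as an (M, K) array.

    Models 3–4: the full {−1, 0, 1}^K grid (3^K rows, the all-zero vector
    included — it yields chance responding). Models 5–6: the 2K signed
    one-hot vectors, ordered (+1 at attribute 0, −1 at attribute 0, +1 at
    attribute 1, ...). Order is deterministic and duplicate-free.
    """
    if not spec.is_discrete:
        raise NotEnumerableError(
            f"model {spec.model_id} has continuous weights; nothing to enumerate"
        )
    if spec.single_attribute:
        configs = np.zeros((2 * k, k))
        for i in range(k):
            configs[2 * i, i] = 1.0
            configs[2 * i + 1, i] = -1.0
        return configs
    if k > _MAX_ENUM_K:
        raise NotEnumerableError(f"3**{k} configurations exceed the enumeration limit")
    idx = np.arange(3**k)
    powers = 3 ** np.arange(k - 1, -1, -1)
    return (idx[:, None] // powers[None, :]) % 3 - 1.0


@dataclasses.dataclass(frozen=True)
class PriorConfig:
    """Priors used for fitting: uniform weights, Gamma inverse temperature.

    ``beta_shape``/``beta_rate`` follow the shape–rate convention, so the
    default Gamma(4, 1) has mean 4. Weight priors are uniform over each
    model's admissible set (a continuous box or a discrete uniform).
    """

    beta_shape: float = 4.0
    beta_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_shape <= 0 or self.beta_rate <= 0:
            raise ValueError("Gamma shape and rate must be positive")

    def log_beta_pdf(self, beta: np.ndarray) -> np.ndarray:
        """Log density of the Gamma prior on the inverse temperature."""
        beta = np.asarray(beta, dtype=float)
        a, r = self.beta_shape, self.beta_rate
        with np.errstate(divide="ignore"):
            out = a * np.log(r) - gammaln(a) + (a - 1) * np.log(beta) - r * beta
        return np.where(beta > 0, out, -np.inf)
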