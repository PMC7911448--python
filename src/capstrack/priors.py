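"""Priors on intestine diameter and capsule sample frequency.

Path reconstruction cannot observe the true bowel radius nor, after
vendor software re-samples the video to fixed frames per second, the true
acquisition frequency.  Both are therefore drawn fresh at every frame
transition from priors.  Two families are supported: a truncated Gaussian
(``T``) and a uniform (``U``) law, combined into the four combos T-T,
T-U, U-T and U-U (first letter: diameter prior, second: frequency prior).

The diameter prior follows published morphometry of the large intestine:
mean 4.6 cm, standard deviation 0.7 cm, support [2.5, 9] cm.  The
re-exported videos carry a nominal 2 Hz frame rate, so the default
frequency prior is centred there with a 0.5 Hz spread on [0.5, 4] Hz;
a wide preset covering the native 4-35 Hz acquisition range is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PriorSpec",
    "PriorCombo",
    "sample_truncated_gaussian",
    "draw_frame_parameters",
    "DIAMETER_TRUNCNORM",
    "DIAMETER_UNIFORM",
    "FREQUENCY_TRUNCNORM",
    "FREQUENCY_UNIFORM",
    "FREQUENCY_NATIVE_UNIFORM",
    "prior_combo",
]


@dataclass(frozen=True)
class PriorSpec:
    """One marginal prior: truncated Gaussian or uniform on [a, b]."""

    kind: str  # "truncated_gaussian" | "uniform"
    a: float
    b: float
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("truncated_gaussian", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not self.a < self.b:
            raise ValueError("need a < b")
        if self.kind == "truncated_gaussian":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("truncated Gaussian needs mu and sigma > 0")

    @property
    def letter(self) -> str:
        return "T" if self.kind == "truncated_gaussian" else "U"

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        return sample_truncated_gaussian(self.mu, self.sigma, self.a, self.b, rng, size=size)

    def mean(self) -> float:
        """Analytic mean of the prior (closed-form truncated-normal moment)."""
        if self.kind == "uniform":
            return 0.5 * (self.a + self.b)
        lo = (self.a - self.mu) / self.sigma
        hi = (self.b - self.mu) / self.sigma
        return float(stats.truncnorm.mean(lo, hi, loc=self.mu, scale=self.sigma))

    def var(self) -> float:
        if self.kind == "uniform":
            return (self.b - self.a) ** 2 / 12.0
        lo = (self.a - self.mu) / self.sigma
        hi = (self.b - self.mu) / self.sigma
        return float(stats.truncnorm.var(lo, hi, loc=self.mu, scale=self.sigma))


def sample_truncated_gaussian(mu, sigma, a, b, rng: np.random.Generator, size=None):
    """Inverse-CDF draw from N(mu, sigma^2) conditioned on [a, b].

    Rejection-free: a uniform variate is pushed through the truncated
    normal quantile function, so the draw count is deterministic for a
    given generator state.
    """
    if not a < b:
        raise ValueError("need a < b")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo = (a - mu) / sigma
    hi = (b - mu) / sigma
    u = rng.uniform(size=size)
    x = stats.truncnorm.ppf(u, lo, hi, loc=mu, scale=sigma)
    return float(x) if size is None else x


# Canonical marginals.  Diameter values in cm, frequencies in Hz.
DIAMETER_TRUNCNORM = PriorSpec("truncated_gaussian", a=2.5, b=9.0, mu=4.6, sigma=0.7)
DIAMETER_UNIFORM = PriorSpec("uniform", a=2.5, b=9.0)
FREQUENCY_TRUNCNORM = PriorSpec("truncated_gaussian", a=0.5, b=4.0, mu=2.0, sigma=0.5)
FREQUENCY_UNIFORM = PriorSpec("uniform", a=0.5, b=4.0)
#: native capsule acquisition range, for sensitivity runs
FREQUENCY_NATIVE_UNIFORM = PriorSpec("uniform", a=4.0, b=35.0)


@dataclass(frozen=True)
class PriorCombo:
    """A (diameter, frequency) prior pair with its T/U label."""

    radius_prior: PriorSpec  # prior on the *diameter* 2R, halved on draw
    frequency_prior: PriorSpec
    label: str = ""

    def __post_init__(self) -> None:
        expect = f"{self.radius_prior.letter}-{self.frequency_prior.letter}"
        if self.label == "":
            object.__setattr__(self, "label", expect)
        elif self.label != expect:
            raise ValueError(f"label {self.label!r} inconsistent with priors ({expect})")


_PRESETS = {
    "tt": (DIAMETER_TRUNCNORM, FREQUENCY_TRUNCNORM),
    "tu": (DIAMETER_TRUNCNORM, FREQUENCY_UNIFORM),
    "ut": (DIAMETER_UNIFORM, FREQUENCY_TRUNCNORM),
    "uu": (DIAMETER_UNIFORM, FREQUENCY_UNIFORM),
}


def prior_combo(name: str) -> PriorCombo:
    """Look up a preset combo by name: 'tt', 'tu', 'ut' or 'uu'."""
    key = name.lower().replace("-", "")
    if key not in _PRESETS:
        raise KeyError(f"unknown prior combo {name!r}; choose from {sorted(_PRESETS)}")
    d, f = _PRESETS[key]
    return PriorCombo(radius_prior=d, frequency_prior=f)


def draw_frame_parameters(combo: PriorCombo, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one frame's (radius R in cm, frequency f in Hz).

    The diameter prior is sampled and halved; draws are independent
    across frames.
    """
    diameter = float(combo.radius_prior.sample(rng))
    f = float(combo.frequency_prior.sample(rng))
    return diameter / 2.0, f
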