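"""Forward signal models for multi-b-value diffusion-weighted MRI.

The package works with two descriptions of the diffusion decay of a voxel:

* a mono-exponential model ``S(b) = S0 * exp(-b * ADC)`` summarising the
  whole voxel with a single apparent diffusion coefficient, and
* a three-compartment (restriction-spectrum) model
  ``S(b) = S0 * (f1 * exp(-b*D1) + f2 * exp(-b*D2) + f3 * exp(-b*D3))``
  in which ``f1``, ``f2`` and ``f3`` are the volume fractions of the
  restricted (intracellular), hindered (extracellular) and free-water
  compartments.  The compartmental diffusivities ``D1 < D2 < D3`` are held
  fixed at literature values so the model stays linear in the amplitudes.

Units: b-values in s/mm^2, diffusivities in mm^2/s, so ``b*D`` is
dimensionless.  Fractions live on the unit simplex.

Measurement noise on magnitude MR images is Rician: the magnitude of a
complex signal whose real and imaginary channels carry independent Gaussian
noise.  :func:`add_rician_noise` implements exactly that construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError

#: 12-point acquisition schedule used throughout (s/mm^2).
DEFAULT_BVALUES: tuple[float, ...] = (
    0, 25, 50, 100, 150, 200, 400, 600, 800, 1000, 1500, 2000
)

#: Fixed compartmental diffusivities (mm^2/s): restricted, hindered, free.
DEFAULT_DIFFUSIVITIES: tuple[float, float, float] = (1.0e-3, 2.0e-3, 3.0e-3)

#: Absolute tolerance within which fraction triples are renormalised.
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class BValueSchedule:
    """Ordered diffusion weightings, starting at b=0.

    The first value must be 0 (the unattenuated reference), values must be
    strictly increasing and non-negative, and at least 4 points are required
    so that fitting has more observations than free amplitudes.
    """

    values: tuple[float, ...] = DEFAULT_BVALUES

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 4:
            raise InvalidInputError("schedule needs at least 4 b-values")
        if vals[0] != 0:
            raise InvalidInputError("first b-value must be 0")
        if any(v < 0 for v in vals):
            raise InvalidInputError("b-values must be non-negative")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidInputError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_json(self) -> str:
        return json.dumps({"b_values": list(self.values)})

    @classmethod
    def from_json(cls, text: str) -> "BValueSchedule":
        return cls(tuple(json.loads(text)["b_values"]))


@dataclass(frozen=True)
class MonoExpParams:
    """Mono-exponential decay parameters (ADC in mm^2/s, S0 > 0)."""

    ADC: float
    S0: float = 1.0

    def __post_init__(self):
        if not self.ADC > 0:
            raise InvalidInputError("ADC must be positive")
        if not self.S0 > 0:
            raise InvalidInputError("S0 must be positive")


@dataclass(frozen=True)
class CompartmentParams:
    """Three-compartment parameters on the unit simplex.

    Fractions within ``SIMPLEX_TOL`` of summing to one are renormalised;
    larger deviations raise :class:`InvalidInputError`.
    """

    f1: float
    f2: float
    f3: float
    D1: float = DEFAULT_DIFFUSIVITIES[0]
    D2: float = DEFAULT_DIFFUSIVITIES[1]
    D3: float = DEFAULT_DIFFUSIVITIES[2]
    S0: float = 1.0

    def __post_init__(self):
        f = np.array([self.f1, self.f2, self.f3], dtype=float)
        if np.any(f < -SIMPLEX_TOL):
            raise InvalidInputError("fractions must be non-negative")
        f = np.clip(f, 0.0, None)
        total = f.sum()
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise InvalidInputError(
                f"fractions must sum to 1 (got {total!r})"
            )
        f = f / total
        if not (self.D1 < self.D2 < self.D3):
            raise InvalidInputError("diffusivities must satisfy D1 < D2 < D3")
        if not self.S0 > 0:
            raise InvalidInputError("S0 must be positive")
        object.__setattr__(self, "f1", float(f[0]))
        object.__setattr__(self, "f2", float(f[1]))
        object.__setattr__(self, "f3", float(f[2]))

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.D1, self.D2, self.D3])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian channel noise level and RNG seed for Rician corruption."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise InvalidInputError("b-values must be non-negative")
    return b


def mono_exp_signal(params: MonoExpParams, b) -> np.ndarray | float:
    """Mono-exponential decay ``S0 * exp(-b * ADC)``.

    Accepts a scalar b-value or an array; returns the matching shape.
    """
    b = _check_b(b)
    out = params.S0 * np.exp(-b * params.ADC)
    return float(out) if out.ndim == 0 else out


def tri_exp_signal(params: CompartmentParams, b) -> np.ndarray | float:
    """Three-compartment decay ``S0 * sum_i f_i * exp(-b * D_i)``."""
    b = _check_b(b)
    decay = np.exp(-np.multiply.outer(b, params.diffusivities))
    out = params.S0 * decay @ params.fractions
    return float(out) if out.ndim == 0 else out


def add_rician_noise(signal, noise: NoiseSpec) -> np.ndarray:
    """Corrupt a noise-free magnitude signal with Rician noise.

    Each output sample is ``sqrt((s + g1)^2 + g2^2)`` with ``g1, g2``
    independent zero-mean Gaussians of standard deviation ``noise.sigma``.
    ``sigma == 0`` returns the input unchanged (as an array copy).
    Reproducible for a fixed ``noise.seed``.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise InvalidInputError("magnitude signals must be non-negative")
    if noise.sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(noise.seed)
    g1 = rng.normal(0.0, noise.sigma, size=signal.shape)
    g2 = rng.normal(0.0, noise.sigma, size=signal.shape)
    return np.hypot(signal + g1, g2)
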