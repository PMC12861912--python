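"""Voxelwise estimation of diffusion parameters from multi-b-value signals.

Two per-voxel model fits are provided, each as a scikit-learn style
estimator operating on a ``(n_voxels, n_bvalues)`` signal matrix plus a thin
single-voxel function:

* :class:`MonoExponentialADC` — ordinary least squares of ``log(S)`` on b;
  the apparent diffusion coefficient is minus the slope.  Exact on
  noiseless mono-exponential input.
* :class:`RestrictionSpectrumNNLS` — non-negative linear least squares of
  the amplitudes against the fixed exponential basis
  ``exp(-b * D_i)``; ``S0`` is recovered as the amplitude sum and fractions
  as amplitudes over that sum, so the simplex constraint holds exactly by
  construction.

Voxels that cannot be fitted (all-zero signal, fewer than two positive
amplitudes for the log fit, non-positive fitted ADC) are dropped from the
output masks rather than propagated as garbage values.

No Rician bias correction is applied before fitting; at low SNR the noise
floor biases high-b amplitudes upward, which the noise-robustness tests
exercise and the documentation flags as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .diffusion import (
    DEFAULT_DIFFUSIVITIES,
    BValueSchedule,
    CompartmentParams,
    MonoExpParams,
)
from .exceptions import EmptyROIError, InvalidInputError, UnfittableVoxelError


@dataclass(frozen=True)
class VoxelSignal:
    """A single voxel's amplitudes over a b-value schedule."""

    schedule: BValueSchedule
    amplitudes: tuple[float, ...]

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes)
        if len(amps) != len(self.schedule):
            raise InvalidInputError("amplitude count must match schedule")
        if any(a < 0 for a in amps):
            raise InvalidInputError("amplitudes must be non-negative")
        if not any(a > 0 for a in amps):
            raise InvalidInputError("at least one amplitude must be positive")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.amplitudes, dtype=float)


@dataclass
class ParameterMap:
    """A fitted parameter image with the mask of valid voxels.

    ``values`` is defined only where ``mask`` is true (NaN elsewhere).
    """

    name: str
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.name not in {"ADC", "f1", "f2", "f3", "S0"}:
            raise InvalidInputError(f"unknown map name {self.name!r}")
        if self.values.shape != self.mask.shape:
            raise InvalidInputError("values and mask shapes differ")


@dataclass(frozen=True)
class ROISummary:
    """Per-parameter arithmetic means over an ROI."""

    roi_id: str
    means: dict[str, float]
    n_voxels: int


def _adc_fit_core(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """OLS of log-signal on b over positive amplitudes -> (ADC, S0)."""
    pos = s > 0
    if pos.sum() < 2:
        raise UnfittableVoxelError("fewer than 2 positive amplitudes")
    slope, intercept = np.polyfit(b[pos], np.log(s[pos]), 1)
    adc = -float(slope)
    if adc <= 0:
        raise UnfittableVoxelError("non-positive fitted ADC")
    return adc, float(np.exp(intercept))


def _rsi_fit_core(basis: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, float]:
    """NNLS amplitudes against the exponential basis -> (fractions, S0)."""
    if not np.any(s > 0):
        raise UnfittableVoxelError("all-zero signal")
    coefs, _ = nnls(basis, s)
    s0 = coefs.sum()
    if s0 <= 0:
        raise UnfittableVoxelError("NNLS returned zero total amplitude")
    return coefs / s0, float(s0)


class MonoExponentialADC(BaseEstimator):
    """Per-voxel log-linear ADC estimator.

    Parameters
    ----------
    schedule : BValueSchedule, optional
        Acquisition schedule; defaults to the 12-point schedule.

    Attributes (after ``fit``)
    --------------------------
    adc_ : ndarray of shape (n_voxels,) — NaN where unfittable.
    s0_ : ndarray of shape (n_voxels,)
    mask_ : boolean ndarray of fittable voxels.
    """

    def __init__(self, schedule: BValueSchedule | None = None):
        self.schedule = schedule

    def _resolved_schedule(self) -> BValueSchedule:
        return self.schedule if self.schedule is not None else BValueSchedule()

    def fit(self, X, y=None):
        sched = self._resolved_schedule()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(sched):
            raise InvalidInputError(
                f"X must be (n_voxels, {len(sched)}) for this schedule"
            )
        b = sched.as_array
        n = X.shape[0]
        self.adc_ = np.full(n, np.nan)
        self.s0_ = np.full(n, np.nan)
        self.mask_ = np.zeros(n, dtype=bool)
        for i in range(n):
            try:
                adc, s0 = _adc_fit_core(b, X[i])
            except UnfittableVoxelError:
                continue
            self.adc_[i], self.s0_[i], self.mask_[i] = adc, s0, True
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return np.column_stack([self.adc_, self.s0_])

    def transform(self, X) -> np.ndarray:
        """Stateless map from signals to ``(ADC, S0)`` columns."""
        return type(self)(self.schedule).fit_transform(X)


class RestrictionSpectrumNNLS(BaseEstimator):
    """Per-voxel three-compartment fraction estimator via NNLS.

    The compartmental diffusivities are fixed, not estimated, keeping the
    problem linear in the amplitudes.

    Attributes (after ``fit``)
    --------------------------
    fractions_ : ndarray of shape (n_voxels, 3) — rows on the unit simplex.
    s0_ : ndarray of shape (n_voxels,)
    mask_ : boolean ndarray of fittable voxels.
    """

    def __init__(
        self,
        schedule: BValueSchedule | None = None,
        diffusivities: Sequence[float] = DEFAULT_DIFFUSIVITIES,
    ):
        self.schedule = schedule
        self.diffusivities = diffusivities

    def _resolved_schedule(self) -> BValueSchedule:
        return self.schedule if self.schedule is not None else BValueSchedule()

    def _basis(self) -> np.ndarray:
        d = np.asarray(self.diffusivities, dtype=float)
        if d.shape != (3,) or not (d[0] < d[1] < d[2]):
            raise InvalidInputError("diffusivities must satisfy D1 < D2 < D3")
        b = self._resolved_schedule().as_array
        return np.exp(-np.outer(b, d))

    def fit(self, X, y=None):
        basis = self._basis()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != basis.shape[0]:
            raise InvalidInputError(
                f"X must be (n_voxels, {basis.shape[0]}) for this schedule"
            )
        n = X.shape[0]
        self.fractions_ = np.full((n, 3), np.nan)
        self.s0_ = np.full(n, np.nan)
        self.mask_ = np.zeros(n, dtype=bool)
        for i in range(n):
            try:
                f, s0 = _rsi_fit_core(basis, X[i])
            except UnfittableVoxelError:
                continue
            self.fractions_[i], self.s0_[i], self.mask_[i] = f, s0, True
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return np.column_stack([self.fractions_, self.s0_])

    def transform(self, X) -> np.ndarray:
        return type(self)(self.schedule, self.diffusivities).fit_transform(X)


def fit_adc(signal: VoxelSignal) -> MonoExpParams:
    """Fit the mono-exponential model to one voxel.

    Raises :class:`UnfittableVoxelError` when fewer than two amplitudes are
    positive or the fitted ADC is non-positive.
    """
    adc, s0 = _adc_fit_core(signal.schedule.as_array, signal.as_array)
    return MonoExpParams(ADC=adc, S0=s0)


def fit_rsi(
    signal: VoxelSignal,
    diffusivities: Sequence[float] = DEFAULT_DIFFUSIVITIES,
) -> CompartmentParams:
    """Fit the three-compartment model to one voxel (fixed diffusivities)."""
    d = np.asarray(diffusivities, dtype=float)
    if d.shape != (3,) or not (d[0] < d[1] < d[2]):
        raise InvalidInputError("diffusivities must satisfy D1 < D2 < D3")
    basis = np.exp(-np.outer(signal.schedule.as_array, d))
    f, s0 = _rsi_fit_core(basis, signal.as_array)
    return CompartmentParams(
        f1=f[0], f2=f[1], f3=f[2], D1=d[0], D2=d[1], D3=d[2], S0=s0
    )


def fit_parameter_maps(
    stack: np.ndarray,
    schedule: BValueSchedule,
    mask: np.ndarray | None = None,
    diffusivities: Sequence[float] = DEFAULT_DIFFUSIVITIES,
) -> dict[str, ParameterMap]:
    """Fit ADC and compartment-fraction maps over a masked image stack.

    Parameters
    ----------
    stack : ndarray, shape (n_bvalues, *spatial)
        One volume per scheduled b-value.
    schedule : BValueSchedule
    mask : boolean ndarray of shape ``spatial``, optional
        Voxels to fit; defaults to all voxels.

    Returns a dict with keys ``ADC, f1, f2, f3, S0``; voxels unfittable
    under either model are removed from that model's output masks.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] != len(schedule):
        raise InvalidInputError(
            "stack must have one leading volume per scheduled b-value"
        )
    spatial = stack.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise InvalidInputError("mask shape must match spatial dimensions")

    signals = stack.reshape(len(schedule), -1).T  # (n_voxels, n_b)
    flat_mask = mask.ravel()
    idx = np.flatnonzero(flat_mask)

    def empty(name):
        return ParameterMap(
            name, np.full(spatial, np.nan), np.zeros(spatial, dtype=bool)
        )

    maps = {name: empty(name) for name in ("ADC", "f1", "f2", "f3", "S0")}
    if idx.size == 0:
        return maps

    selected = signals[idx]
    # non-negative clip guards against interpolation artefacts in inputs
    selected = np.clip(selected, 0.0, None)

    adc_est = MonoExponentialADC(schedule).fit(selected)
    rsi_est = RestrictionSpectrumNNLS(schedule, diffusivities).fit(selected)

    def scatter(map_, flat_values, ok):
        flat = map_.values.ravel()
        mflat = map_.mask.ravel()
        flat[idx[ok]] = flat_values[ok]
        mflat[idx[ok]] = True
        map_.values = flat.reshape(spatial)
        map_.mask = mflat.reshape(spatial)

    scatter(maps["ADC"], adc_est.adc_, adc_est.mask_)
    for j, name in enumerate(("f1", "f2", "f3")):
        scatter(maps[name], rsi_est.fractions_[:, j], rsi_est.mask_)
    scatter(maps["S0"], rsi_est.s0_, rsi_est.mask_)
    return maps


def summarize_roi(
    maps: dict[str, ParameterMap],
    roi_mask: np.ndarray,
    roi_id: str = "roi",
) -> ROISummary:
    """Arithmetic mean of each parameter over the ROI-and-fitted mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    means: dict[str, float] = {}
    n_min = None
    for name, pmap in maps.items():
        joint = roi_mask & pmap.mask
        if joint.sum() == 0:
            raise EmptyROIError(
                f"ROI {roi_id!r} intersects no fitted voxels for {name!r}"
            )
        means[name] = float(pmap.values[joint].mean())
        n_min = joint.sum() if n_min is None else min(n_min, joint.sum())
    return ROISummary(roi_id=roi_id, means=means, n_voxels=int(n_min or 0))
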