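"""Synthetic data: lesion phantoms with known ground truth and two-group
patient cohorts.

Two generators make every downstream stage testable without any real data:

``generate_phantom``
    Builds an image stack by evaluating the three-compartment forward model
    voxelwise over a b-value schedule (ellipse lesion on a free-water
    background) and corrupting it with Rician noise.

``generate_cohort``
    Draws a two-group (SCC vs AC) patient table whose per-group marginal
    distributions emulate the group summaries of a clinical NSCLC cohort:
    normal variables (age, restricted fraction f1, ADC) are parameterised
    by mean and SD, right-skewed variables (lesion diameter, SUVmax, f2,
    f3) by median and interquartile range via a log-normal, and binary
    variables (male sex, smoking) by group proportions.

Distribution details
--------------------
* Bounded normal variables use a truncated normal whose location and scale
  are solved numerically so that the *truncated* distribution reproduces
  the target mean exactly (and the target SD as closely as the family
  allows).  Naive truncation at the target location would bias means
  noticeably when the target sits close to a bound.
* Log-normals take ``mu = ln(median)`` and
  ``sigma = (ln q3 - ln q1) / (2 * z_{0.75})``; when the printed lower
  quartile is zero (a rounding artefact) the upper half-spread is used
  instead, and sigma is capped for the fraction variables to keep draws
  meaningful.
* The fraction triple is coupled to the simplex with f1 given priority:
  f1 is drawn from its truncated normal, then provisional log-normal f2
  and f3 draws are rescaled (preserving their ratio) to sum to ``1 - f1``.
  The three printed marginals cannot hold simultaneously under an exact
  simplex; f1, the headline discriminator, keeps its marginal.

Every generator is reproducible given its integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from math import inf, log

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diffusion import (
    BValueSchedule,
    CompartmentParams,
    NoiseSpec,
    tri_exp_signal,
    add_rician_noise,
)
from .exceptions import EmptyROIError, InvalidInputError
from .fitting import ParameterMap, fit_parameter_maps, summarize_roi

_Z75 = float(stats.norm.ppf(0.75))

COHORT_COLUMNS = (
    "id", "group", "age", "sex_male", "smoking",
    "diameter_cm", "suvmax", "adc", "f1", "f2", "f3",
)


# --------------------------------------------------------------------------
# distribution specs


@lru_cache(maxsize=64)
def _calibrated_truncnorm_params(
    mean: float, sd: float, low: float, high: float
) -> tuple[float, float]:
    """Solve (loc, scale) so the truncated normal matches the target moments.

    The target mean is matched exactly by a root solve on ``loc`` (the
    truncated mean is strictly increasing in ``loc``); ``scale`` is chosen
    to bring the truncated SD as close as possible to the target.
    """

    def frozen(loc, scale):
        a, b = (low - loc) / scale, (high - loc) / scale
        return stats.truncnorm(a, b, loc=loc, scale=scale)

    def loc_for(scale):
        f = lambda loc: frozen(loc, scale).mean() - mean
        lo, hi = mean - scale, mean + scale
        for _ in range(200):
            if f(lo) < 0:
                break
            lo -= 2 * scale
        for _ in range(200):
            if f(hi) > 0:
                break
            hi += 2 * scale
        return optimize.brentq(f, lo, hi, xtol=1e-12)

    # fast path: negligible truncation at the naive parameterisation
    naive = frozen(mean, sd)
    if abs(naive.mean() - mean) < 1e-9 * max(1.0, abs(mean)) and abs(
        naive.std() - sd
    ) < 1e-9 * sd:
        return mean, sd

    def sd_err(scale):
        return frozen(loc_for(scale), scale).std() - sd

    lo_s, hi_s = sd * 0.2, sd * 40
    if sd_err(lo_s) * sd_err(hi_s) < 0:
        scale = optimize.brentq(sd_err, lo_s, hi_s, xtol=1e-10)
    else:  # target SD unattainable within the family: best effort
        res = optimize.minimize_scalar(
            lambda s: abs(sd_err(s)), bounds=(lo_s, hi_s), method="bounded"
        )
        scale = float(res.x)
    return loc_for(scale), scale


@dataclass(frozen=True)
class TruncNormalSpec:
    """Normal variable with optional bounds; target mean/SD are those of
    the *truncated* distribution."""

    mean: float
    sd: float
    low: float = -inf
    high: float = inf

    def __post_init__(self):
        if not self.sd > 0:
            raise InvalidInputError("sd must be positive")
        if not self.low < self.mean < self.high:
            raise InvalidInputError("mean must lie inside the bounds")

    def frozen(self):
        loc, scale = _calibrated_truncnorm_params(
            self.mean, self.sd, self.low, self.high
        )
        a, b = (self.low - loc) / scale, (self.high - loc) / scale
        return stats.truncnorm(a, b, loc=loc, scale=scale)


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal parameterised by median and interquartile range."""

    median: float
    q1: float
    q3: float
    sigma_cap: float | None = None

    def __post_init__(self):
        if not self.median > 0:
            raise InvalidInputError("median must be positive")
        if not self.q3 > self.median:
            raise InvalidInputError("q3 must exceed the median")
        if self.q1 < 0 or self.q1 > self.median:
            raise InvalidInputError("q1 must lie in [0, median]")

    @property
    def sigma(self) -> float:
        if self.q1 > 0:
            s = (log(self.q3) - log(self.q1)) / (2 * _Z75)
        else:  # lower quartile printed as zero: use the upper half-spread
            s = (log(self.q3) - log(self.median)) / _Z75
        if self.sigma_cap is not None:
            s = min(s, self.sigma_cap)
        return s

    def frozen(self):
        return stats.lognorm(s=self.sigma, scale=self.median)


@dataclass(frozen=True)
class BernoulliSpec:
    p: float

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise InvalidInputError("probability must be in [0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """Marginal generators for one patient group.

    ``adc`` is in units of 1e-3 mm^2/s (the scale clinical reports use);
    fraction variables are dimensionless in [0, 1].
    """

    age: TruncNormalSpec
    f1: TruncNormalSpec
    adc: TruncNormalSpec
    f2: LogNormalSpec
    f3: LogNormalSpec
    diameter: LogNormalSpec
    suvmax: LogNormalSpec
    male: BernoulliSpec
    smoking: BernoulliSpec


@dataclass(frozen=True)
class GroupDistributionSpec:
    scc: GroupSpec
    ac: GroupSpec

    def group(self, label: str) -> GroupSpec:
        if label == "SCC":
            return self.scc
        if label == "AC":
            return self.ac
        raise InvalidInputError(f"unknown group {label!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroupDistributionSpec":
        def group(g):
            return GroupSpec(
                age=TruncNormalSpec(**g["age"]),
                f1=TruncNormalSpec(**g["f1"]),
                adc=TruncNormalSpec(**g["adc"]),
                f2=LogNormalSpec(**g["f2"]),
                f3=LogNormalSpec(**g["f3"]),
                diameter=LogNormalSpec(**g["diameter"]),
                suvmax=LogNormalSpec(**g["suvmax"]),
                male=BernoulliSpec(**g["male"]),
                smoking=BernoulliSpec(**g["smoking"]),
            )

        return cls(scc=group(d["scc"]), ac=group(d["ac"]))

    @classmethod
    def from_json(cls, path) -> "GroupDistributionSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Cap on the IQR-matched sigma of the fraction log-normals; quartiles
#: printed as 0.00 are rounding artefacts and would otherwise degenerate.
_FRACTION_SIGMA_CAP = 2.5


def default_cohort_spec() -> GroupDistributionSpec:
    """Default two-group parameterisation emulating an NSCLC cohort
    (30 SCC vs 67 AC): lower f1/ADC and higher f2/f3/SUVmax/diameter and
    smoking and male rates in the SCC group."""
    scc = GroupSpec(
        age=TruncNormalSpec(62.47, 8.85),
        f1=TruncNormalSpec(0.6711, 0.1727, 0.0, 1.0),
        adc=TruncNormalSpec(1.11, 0.35, 0.0, inf),
        f2=LogNormalSpec(0.0871, 0.0164, 0.1293, _FRACTION_SIGMA_CAP),
        f3=LogNormalSpec(0.2139, 0.1188, 0.3368, _FRACTION_SIGMA_CAP),
        diameter=LogNormalSpec(3.45, 2.38, 4.50),
        suvmax=LogNormalSpec(9.93, 5.30, 12.80),
        male=BernoulliSpec(25 / 30),
        smoking=BernoulliSpec(21 / 30),
    )
    ac = GroupSpec(
        age=TruncNormalSpec(61.51, 8.01),
        f1=TruncNormalSpec(0.8627, 0.1301, 0.0, 1.0),
        adc=TruncNormalSpec(1.37, 0.25, 0.0, inf),
        f2=LogNormalSpec(0.0024, 0.0, 0.0433, _FRACTION_SIGMA_CAP),
        f3=LogNormalSpec(0.0832, 0.0001, 0.1941, _FRACTION_SIGMA_CAP),
        diameter=LogNormalSpec(2.00, 1.50, 3.00),
        suvmax=LogNormalSpec(3.77, 1.88, 6.64),
        male=BernoulliSpec(40 / 67),
        smoking=BernoulliSpec(21 / 67),
    )
    return GroupDistributionSpec(scc=scc, ac=ac)


# --------------------------------------------------------------------------
# cohort generation


def _draw_fractions(gspec: GroupSpec, n: int, rng) -> np.ndarray:
    """Simplex-coupled (f1, f2, f3) draws; f1 keeps its marginal."""
    f1 = gspec.f1.frozen().rvs(n, random_state=rng)
    f2_raw = gspec.f2.frozen().rvs(n, random_state=rng)
    f3_raw = gspec.f3.frozen().rvs(n, random_state=rng)
    rest = 1.0 - f1
    scale = rest / (f2_raw + f3_raw)
    return np.column_stack([f1, f2_raw * scale, f3_raw * scale])


def _draw_clinical(gspec: GroupSpec, n: int, rng) -> dict[str, np.ndarray]:
    return {
        "age": gspec.age.frozen().rvs(n, random_state=rng),
        "sex_male": (rng.random(n) < gspec.male.p).astype(int),
        "smoking": (rng.random(n) < gspec.smoking.p).astype(int),
        "diameter_cm": gspec.diameter.frozen().rvs(n, random_state=rng),
        "suvmax": gspec.suvmax.frozen().rvs(n, random_state=rng),
    }


def generate_cohort(
    spec: GroupDistributionSpec | None = None,
    n_scc: int = 30,
    n_ac: int = 67,
    seed: int = 0,
    mode: str = "summary",
    **image_kwargs,
) -> pd.DataFrame:
    """Draw a two-group patient table.

    ``mode="summary"`` draws the imaging variables (ADC, f1-f3) directly
    from the group distributions — fast, for statistical tests.
    ``mode="image"`` instead simulates a phantom per patient, fits it, and
    uses the ROI means — physically consistent end-to-end.
    """
    if spec is None:
        spec = default_cohort_spec()
    if n_scc < 2 or n_ac < 2:
        raise InvalidInputError("need at least 2 patients per group")
    if mode == "image":
        return cohort_from_group_phantoms(
            spec, n_scc, n_ac, seed=seed, **image_kwargs
        )
    if mode != "summary":
        raise InvalidInputError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    frames = []
    for label, n in (("SCC", n_scc), ("AC", n_ac)):
        gspec = spec.group(label)
        cols = _draw_clinical(gspec, n, rng)
        f = _draw_fractions(gspec, n, rng)
        adc = gspec.adc.frozen().rvs(n, random_state=rng)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{label}-{i + 1:03d}" for i in range(n)],
                    "group": label,
                    **cols,
                    "adc": adc,
                    "f1": f[:, 0],
                    "f2": f[:, 1],
                    "f3": f[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(COHORT_COLUMNS)]


# --------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """An elliptical lesion with known compartment ground truth.

    ``ramp_f1`` optionally ramps f1 linearly along the x axis across the
    lesion's bounding box; the remaining mass is split between f2 and f3
    in the base-truth ratio.
    """

    shape: tuple[int, int] = (24, 24)
    center: tuple[float, float] = (11.5, 11.5)
    axes: tuple[float, float] = (8.0, 6.0)
    truth: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(0.7, 0.1, 0.2, S0=1000.0)
    )
    ramp_f1: tuple[float, float] | None = None
    sigma: float = 0.0
    schedule: BValueSchedule = field(default_factory=BValueSchedule)

    def __post_init__(self):
        cy, cx = self.center
        ay, ax = self.axes
        ny, nx = self.shape
        if ay <= 0 or ax <= 0:
            raise InvalidInputError("ellipse axes must be positive")
        if not (cy - ay >= 0 and cy + ay <= ny - 1 and cx - ax >= 0
                and cx + ax <= nx - 1):
            raise InvalidInputError("lesion must lie fully inside the image")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")
        if self.ramp_f1 is not None:
            lo, hi = self.ramp_f1
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise InvalidInputError("ramp endpoints must be in [0, 1]")


def _lesion_mask(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = spec.center
    ay, ax = spec.axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _truth_fields(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel fraction field (ny, nx, 3) and the lesion mask."""
    mask = _lesion_mask(spec)
    ny, nx = spec.shape
    f = np.zeros((ny, nx, 3))
    f[..., 2] = 1.0  # free-water background
    base = spec.truth.fractions
    if spec.ramp_f1 is None:
        f[mask] = base
    else:
        lo, hi = spec.ramp_f1
        xs = np.nonzero(mask.any(axis=0))[0]
        x0, x1 = xs.min(), xs.max()
        t = np.zeros(nx) if x1 == x0 else np.clip(
            (np.arange(nx) - x0) / (x1 - x0), 0, 1
        )
        f1_line = lo + (hi - lo) * t
        rest = base[1] + base[2]
        w2 = base[1] / rest if rest > 0 else 0.5
        field3 = np.stack(
            [f1_line, (1 - f1_line) * w2, (1 - f1_line) * (1 - w2)], axis=-1
        )
        f[mask] = np.broadcast_to(field3, (ny, nx, 3))[mask]
    return f, mask


def generate_phantom(
    spec: PhantomSpec, seed: int = 0
) -> tuple[np.ndarray, dict[str, ParameterMap], np.ndarray]:
    """Simulate a phantom stack.

    Returns ``(stack, truth_maps, roi_mask)`` where ``stack`` has shape
    ``(n_bvalues, ny, nx)``, ``truth_maps`` holds the generating f1/f2/f3
    fields (defined everywhere; background is free water), and ``roi_mask``
    marks the lesion.  Reproducible given ``seed``.
    """
    f, mask = _truth_fields(spec)
    b = spec.schedule.as_array
    decay = np.exp(-np.multiply.outer(b, spec.truth.diffusivities))  # (nb, 3)
    stack = spec.truth.S0 * np.einsum("bk,yxk->byx", decay, f)
    stack = add_rician_noise(stack, NoiseSpec(sigma=spec.sigma, seed=seed))
    full = np.ones(spec.shape, dtype=bool)
    truth_maps = {
        name: ParameterMap(name, f[..., i].copy(), full.copy())
        for i, name in enumerate(("f1", "f2", "f3"))
    }
    return stack, truth_maps, mask


def cohort_from_phantoms(
    specs: list[tuple[str, PhantomSpec]],
    seed: int = 0,
    clinical_spec: GroupDistributionSpec | None = None,
) -> pd.DataFrame:
    """End-to-end "image mode": simulate, fit and summarise one phantom per
    patient; clinical covariates are drawn from the group distributions.

    ``specs`` is a list of ``(group_label, PhantomSpec)``.  Patients whose
    lesion cannot be fitted are dropped with a warning.
    """
    if clinical_spec is None:
        clinical_spec = default_cohort_spec()
    labels = [g for g, _ in specs]
    for g in labels:
        clinical_spec.group(g)  # validates the label
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(specs))

    rows = []
    counters = {"SCC": 0, "AC": 0}
    for (label, pspec), pseed in zip(specs, seeds):
        counters[label] += 1
        pid = f"{label}-{counters[label]:03d}"
        stack, _, roi = generate_phantom(pspec, seed=int(pseed))
        maps = fit_parameter_maps(stack, pspec.schedule, mask=roi)
        try:
            summary = summarize_roi(maps, roi, roi_id=pid)
        except EmptyROIError:
            warnings.warn(f"patient {pid}: lesion unfittable, dropped")
            continue
        clin = _draw_clinical(clinical_spec.group(label), 1, rng)
        rows.append(
            {
                "id": pid,
                "group": label,
                **{k: v[0] for k, v in clin.items()},
                # ADC reported in 1e-3 mm^2/s, matching the summary mode
                "adc": summary.means["ADC"] * 1e3,
                "f1": summary.means["f1"],
                "f2": summary.means["f2"],
                "f3": summary.means["f3"],
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def cohort_from_group_phantoms(
    spec: GroupDistributionSpec,
    n_scc: int,
    n_ac: int,
    seed: int = 0,
    s0: float = 1000.0,
    snr: float = 50.0,
    shape: tuple[int, int] = (24, 24),
) -> pd.DataFrame:
    """Image-mode cohort: per-patient ground truth drawn from the group
    fraction distributions, rendered as a phantom at the given SNR
    (``sigma = s0 / snr``; ``snr=inf`` for noiseless) and recovered by
    fitting."""
    rng = np.random.default_rng(seed)
    sigma = 0.0 if np.isinf(snr) else s0 / snr
    ny, nx = shape
    center = ((ny - 1) / 2, (nx - 1) / 2)
    axes = (0.35 * ny, 0.3 * nx)
    specs = []
    for label, n in (("SCC", n_scc), ("AC", n_ac)):
        f = _draw_fractions(spec.group(label), n, rng)
        for i in range(n):
            truth = CompartmentParams(f[i, 0], f[i, 1], f[i, 2], S0=s0)
            specs.append(
                (label, PhantomSpec(shape=shape, center=center, axes=axes,
                                    truth=truth, sigma=sigma))
            )
    phantom_seed = int(rng.integers(0, 2**31 - 1))
    return cohort_from_phantoms(specs, seed=phantom_seed, clinical_spec=spec)
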