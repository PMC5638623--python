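"""Turing-instability analysis: dispersion relation and phase diagrams.

Linearizing the averaged weight dynamics on the torus, the Fourier mode at
spatial frequency k grows as exp(eta lambda(k) t) with

    lambda(k) = rho W_tot (4 pi^2 / L^2) G~^2(k) K~sp(k) - a,   k != 0,

where G~(k) = (L^2 r_av / 2 pi) exp(-(2 pi k)^2 sigma^2 / 2) is the Hankel
transform of the Gaussian tuning curve and K~sp the Hankel transform of the
spatial adaptation kernel.  A periodic pattern can emerge when lambda has a
positive global maximum lambda_max at k_max > 0, on the structure-formation
time scale tau_str = 1 / (eta lambda_max).

For spatially-irregular inputs (M superimposed random fields per neuron)
the expected spectrum is attenuated by the k-independent scale factor

    Phi(M) = (pi / 3M) (4/pi + 1/(3M))  ~  4/(3M)  for M > 3,

derived from the Rayleigh-distributed resultant of M random phasors with
Irwin-Hall-distributed total amplitude; Phi = 1 at k = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .inputs import GaussianFieldSpec
from .kernels import AdaptationKernel

__all__ = [
    "SpectrumConfig",
    "CriticalPoint",
    "IrregularScale",
    "gaussian_hankel",
    "eigenvalue_spectrum",
    "critical_point",
    "structure_time",
    "sweep",
    "phi_factor",
    "phi_monte_carlo",
    "irregular_spectrum",
]


def _default_k_grid() -> np.ndarray:
    return np.arange(0.05, 20.0001, 0.05)


@dataclass(frozen=True)
class SpectrumConfig:
    """Inputs of the dispersion relation.

    rho : input receptive-field density N / L^2, m^-2.
    field_spec : Gaussian tuning-curve shape (sigma, r_av, L).
    kernel : temporal adaptation kernel (or AHP-equivalent kernel).
    v : running speed, m/s.
    w_tot : STDP window integral, seconds.
    a : effective weight-decay rate, s^-1.
    k_grid : spatial-frequency grid (cycles/m) used for peak search.
    """

    rho: float = 900.0
    field_spec: GaussianFieldSpec = field(default_factory=GaussianFieldSpec)
    kernel: AdaptationKernel = field(default_factory=AdaptationKernel)
    v: float = 0.25
    w_tot: float = 1.0
    a: float = 1.1
    k_grid: np.ndarray = field(default_factory=_default_k_grid)

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("require rho > 0")
        k = np.asarray(self.k_grid, dtype=float)
        if np.any(k <= 0) or np.any(np.diff(k) <= 0):
            raise ValueError("k_grid must be positive and strictly increasing")
        object.__setattr__(self, "k_grid", k)

    def replace(self, **changes) -> "SpectrumConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CriticalPoint:
    """Peak of the dispersion relation and the regime it implies.

    regime: "grid" (k_max > 0, lambda_max > 0), "place" (supremum at
    k -> 0 with lambda_max > 0), or "none" (lambda_max <= 0).
    """

    k_max: float
    lambda_max: float
    regime: str


@dataclass(frozen=True)
class IrregularScale:
    """Scale factor Phi attenuating the spectrum for M-field inputs."""

    M: int
    phi: float
    phi_coarse: float


def gaussian_hankel(spec: GaussianFieldSpec, k):
    """Hankel transform of the Gaussian tuning curve at k (cycles/m)."""
    k = np.asarray(k, dtype=float)
    out = (
        spec.L ** 2
        * spec.r_av
        / (2.0 * np.pi)
        * np.exp(-0.5 * (2.0 * np.pi * k) ** 2 * spec.sigma ** 2)
    )
    return out if np.ndim(out) else float(out)


def _positive_term(cfg: SpectrumConfig, k):
    g = gaussian_hankel(cfg.field_spec, k)
    ksp = cfg.kernel.spatial_hankel(cfg.v, k)
    return (
        cfg.rho
        * cfg.w_tot
        * (4.0 * np.pi ** 2 / cfg.field_spec.L ** 2)
        * g ** 2
        * ksp
    )


def eigenvalue_spectrum(cfg: SpectrumConfig, k):
    """Growth rate lambda(k), s^-1, for k > 0 (k = 0 governs normalization)."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("eigenvalue spectrum defined for k > 0")
    out = _positive_term(cfg, k) - cfg.a
    return out if np.ndim(out) else float(out)


def critical_point(cfg: SpectrumConfig) -> CriticalPoint:
    """Locate (k_max, lambda_max) on the config's k grid.

    The grid argmax is refined by local parabolic interpolation.  An argmax
    at the smallest grid frequency is reported as the place-field regime
    (k_max = 0); an argmax at the upper grid edge raises, since the grid
    then fails to span the peak.
    """
    k = cfg.k_grid
    lam = eigenvalue_spectrum(cfg, k)
    j = int(np.argmax(lam))
    if j == len(k) - 1:
        raise ValueError("spectrum peak at the upper edge of k_grid; extend it")
    if lam[j] <= 0.0:
        return CriticalPoint(k_max=float("nan"), lambda_max=float(lam[j]), regime="none")
    if j == 0:
        return CriticalPoint(k_max=0.0, lambda_max=float(lam[j]), regime="place")
    y0, y1, y2 = lam[j - 1 : j + 2]
    denom = y0 - 2.0 * y1 + y2
    k_ref = float(k[j])
    if denom < 0:
        k_ref += -0.5 * (y2 - y0) / denom * float(k[j + 1] - k[j])
    lam_ref = float(eigenvalue_spectrum(cfg, k_ref))
    return CriticalPoint(k_max=k_ref, lambda_max=max(lam_ref, float(y1)), regime="grid")


def structure_time(lambda_max: float, eta: float) -> float:
    """Structure-formation time tau_str = 1 / (eta lambda_max), seconds."""
    if lambda_max <= 0:
        raise ValueError("tau_str defined only for lambda_max > 0")
    return 1.0 / (eta * lambda_max)


def sweep(
    cfg: SpectrumConfig,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Phase diagram of (k_max, lambda_max, regime) over two kernel axes.

    Axis names are fields of the config's kernel dataclass (e.g. "tau_l",
    "mu" for the adaptation kernel; "tau_out", "mu_out" for the AHP
    kernel).  Returns arrays of shape (len(axis2), len(axis1)) — axis1
    varies along columns — plus the axis values.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    shape = (len(vals2), len(vals1))
    k_map = np.full(shape, np.nan)
    lam_map = np.full(shape, np.nan)
    regime = np.empty(shape, dtype=object)
    for i2, v2 in enumerate(vals2):
        for i1, v1 in enumerate(vals1):
            try:
                kern = cfg.kernel.replace(**{name1: v1, name2: v2})
            except ValueError:
                regime[i2, i1] = "invalid"
                continue
            cp = critical_point(cfg.replace(kernel=kern))
            k_map[i2, i1] = cp.k_max
            lam_map[i2, i1] = cp.lambda_max
            regime[i2, i1] = cp.regime
    return {
        name1: vals1,
        name2: vals2,
        "k_max": k_map,
        "lambda_max": lam_map,
        "regime": regime,
    }


def phi_factor(M: int) -> IrregularScale:
    """Analytic scale factor Phi(M) for M >= 2 superimposed fields."""
    if M < 2:
        raise ValueError("Phi(M) derived for M >= 2; Phi = 1 at k = 0")
    phi = (np.pi / (3.0 * M)) * (4.0 / np.pi + 1.0 / (3.0 * M))
    return IrregularScale(M=M, phi=float(phi), phi_coarse=4.0 / (3.0 * M))


def phi_monte_carlo(
    M: int,
    n_draws: int = 3600,
    rng: np.random.Generator | int | None = None,
    k: tuple[float, float] = (1.0, 0.0),
    L: float = 1.0,
) -> float:
    """Monte-Carlo estimator <alpha^2 / beta^2> of the scale factor.

    Draws amplitudes A ~ U(0,1) and field centers uniform in the arena,
    then measures the squared resultant of the M phasors A e^{-2 pi j r.k}
    relative to the squared total amplitude (the power-spectrum estimator
    applied to synthetic input realizations).
    """
    rng = np.random.default_rng(rng)
    amps = rng.uniform(0.0, 1.0, size=(n_draws, M))
    centers = rng.uniform(0.0, L, size=(n_draws, M, 2))
    phase = -2.0 * np.pi * (centers @ np.asarray(k, dtype=float))
    alpha = np.abs((amps * np.exp(1j * phase)).sum(axis=1))
    beta = amps.sum(axis=1)
    return float(np.mean(alpha ** 2 / beta ** 2))


def irregular_spectrum(cfg: SpectrumConfig, M: int, k):
    """Expected growth rate for M-field irregular inputs (Phi-scaled)."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("irregular spectrum defined for k > 0")
    out = phi_factor(M).phi * _positive_term(cfg, k) - cfg.a
    return out if np.ndim(out) else float(out)
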