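"""Averaged (deterministic) weight dynamics and input-correlation models.

Ensemble- and time-averaging the stochastic STDP updates yields the drift

    eta^-1 dw_i/dt = sum_j C_ij w_j - a w_i + b,   w_i >= 0,

where C_ij is the adaptation-filtered spatial correlation of the input
tuning curves along the trajectory, and

    a = r_av [alpha - int W(s) K(-s) ds],    b = r_av (W_tot r_0 + beta).

For smooth constant-speed trajectories the correlation reduces to a circle
average: C_ij = (W_tot/L^2) int dtau K(tau) <Psi_i * Psi_j>_{|z|=tau v},
which for Gaussian tuning curves has the radial closed form

    C(u) = (W_tot L^2 r_av^2 / 4 pi sigma^2)
           int dtau K(tau) e^{-(u^2+(tau v)^2)/4 sigma^2} I0(u tau v / 2 sigma^2),

a Mexican-hat interaction (positive at short field distances, negative at
intermediate ones) that drives Turing-type pattern formation.

Numerical choices
-----------------
The tau quadrature runs over (0, 10 * theta_max] with 400 Gauss-Legendre
nodes, where theta_max is the slowest kernel time constant.  The horizon is
deliberately longer than the 5 * theta_max support used for spike-train
convolutions: the kernel integral is a near-cancellation of the two lobes,
and truncating at 5 * theta_max biases the mean correlation (hence tau_av
and w_av_inf) by ~10%.  The modified Bessel term is evaluated in its
exponentially scaled form for numerical stability; its printed negative
argument is immaterial since I0 is even.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.ndimage import map_coordinates
from scipy.special import i0e

from .inputs import GaussianFieldSpec, InputEnsemble, rate_map
from .kernels import AdaptationKernel
from .spiking import NeuronParams, PlasticityParams
from .trajectory import minimal_image

__all__ = [
    "AveragedParams",
    "CorrelationModel",
    "correlation_radial",
    "correlation_matrix",
    "derive_ab",
    "stdp_kernel_overlap",
    "normalization_quantities",
    "integrate",
]

#: quadrature horizon in units of the slowest kernel time constant
TAU_HORIZON_FACTOR = 10.0
#: Gauss-Legendre nodes for the tau quadrature
TAU_QUAD_NODES = 400
#: angles per radius for the circle average of map cross-correlograms
CIRCLE_ANGLES = 256


@dataclass(frozen=True)
class AveragedParams:
    """Euler integration parameters for the averaged dynamics."""

    a: float
    b: float
    eta: float = 2e-5
    dt: float = 50.0

    def __post_init__(self):
        if self.dt <= 0 or self.eta <= 0:
            raise ValueError("require dt > 0 and eta > 0")


@dataclass
class CorrelationModel:
    """Input-correlation matrix with its provenance."""

    matrix: np.ndarray  # (N, N), s^-1
    rho: float  # input density N / L^2
    w_tot: float
    v: float
    kernel: AdaptationKernel
    method: str

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def c_av(self) -> float:
        """Mean correlation N^-2 sum_ij C_ij."""
        return float(self.matrix.mean())


def _tau_quadrature(kernel) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and K-weighted weights for int_0^T K(tau) f(tau) dtau."""
    t_upper = TAU_HORIZON_FACTOR * max(th for _, th in kernel.components)
    x, w = leggauss(TAU_QUAD_NODES)
    tau = 0.5 * t_upper * (x + 1.0)
    return tau, w * 0.5 * t_upper * kernel.value(tau)


def correlation_radial(
    spec: GaussianFieldSpec,
    kernel: AdaptationKernel,
    v: float,
    w_tot: float,
    u,
) -> float | np.ndarray:
    """Radial correlation C(u) for regular Gaussian inputs (closed form)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("field distance u must be >= 0")
    scalar = u.ndim == 0
    uu = np.atleast_1d(u)
    tau, kw = _tau_quadrature(kernel)
    tv = tau * v
    s2 = spec.sigma ** 2
    # e^{-(u^2+tv^2)/4s^2} I0(u tv / 2 s^2) == e^{-(u-tv)^2/4s^2} i0e(u tv / 2 s^2)
    ring = np.exp(-((uu[:, None] - tv[None, :]) ** 2) / (4.0 * s2)) * i0e(
        uu[:, None] * tv[None, :] / (2.0 * s2)
    )
    vals = (
        w_tot
        * spec.L ** 2
        * spec.r_av ** 2
        / (4.0 * np.pi * s2)
        * (ring @ kw)
    )
    return float(vals[0]) if scalar else vals


def _matrix_from_modes(ensemble, kernel, v, w_tot) -> np.ndarray:
    """C_ij by exact expansion over torus Fourier modes.

    On the periodic arena the tuning curves have the Fourier series
    Psi_j(x) = sum_k c_jk exp(2 pi j k.x) with analytic Gaussian-mixture
    coefficients, and the circle-averaged, K-weighted correlation becomes

        C_ij = W_tot sum_k conj(c_ik) c_jk K~sp(|k|),

    using the closed-form Hankel transform of the spatial kernel (no tau
    quadrature, exact periodization).  Modes are truncated where the
    Gaussian power envelope drops below ~1e-11 of its peak.
    """
    spec = ensemble.spec
    L, sig = spec.L, spec.sigma
    k_cut = 5.0 / (2.0 * np.pi * sig)
    n_max = max(int(np.ceil(k_cut * L)), 1)
    nn = np.arange(-n_max, n_max + 1)
    n1, n2 = np.meshgrid(nn, nn, indexing="ij")
    kx = n1.ravel() / L
    ky = n2.ravel() / L
    kk = np.hypot(kx, ky)
    keep = kk <= k_cut + 1e-12
    kx, ky, kk = kx[keep], ky[keep], kk[keep]
    # |Ghat(k)|^2 Ksp~(k) / L^4, with Ghat the plane transform of G
    ghat = L ** 2 * spec.r_av * np.exp(-0.5 * (2.0 * np.pi * kk) ** 2 * sig ** 2)
    d = w_tot * ghat ** 2 * kernel.spatial_hankel(v, kk) / L ** 4
    centers = ensemble.centers.reshape(-1, 2)
    q = ensemble.field_weights().ravel()
    phase = np.exp(
        -2j * np.pi * (np.outer(centers[:, 0], kx) + np.outer(centers[:, 1], ky))
    )
    phase *= q[:, None]
    B = phase.reshape(ensemble.N, ensemble.M, len(kk)).sum(axis=1)
    C = (B * d[None, :]) @ B.conj().T
    return np.ascontiguousarray(C.real)


def _matrix_from_maps(ensemble, kernel, v, w_tot, n_bins=100) -> np.ndarray:
    """C_ij from gridded tuning maps: FFT cross-correlograms averaged over
    circles of radius tau*v (periodic bilinear interpolation at 256 angles),
    weighted by K(tau).  General: makes no Gaussian assumption."""
    import warnings

    spec = ensemble.spec
    if spec.sigma < 2.0 * spec.L / n_bins:
        warnings.warn("map resolution coarse relative to sigma; increase n_bins")
    L = spec.L
    h = L / n_bins
    maps = np.stack(
        [rate_map(ensemble, i, n_bins).values for i in range(ensemble.N)]
    )
    F = np.fft.rfft2(maps)
    tau, kw = _tau_quadrature(kernel)
    ang = (np.arange(CIRCLE_ANGLES) + 0.5) * (2.0 * np.pi / CIRCLE_ANGLES)
    # sample coordinates (in bins) of every circle point, per tau: (T, A, 2)
    radii = tau * v / h
    rows = radii[:, None] * np.sin(ang)[None, :]
    cols = radii[:, None] * np.cos(ang)[None, :]
    coords = np.stack([rows.ravel(), cols.ravel()])
    N = ensemble.N
    C = np.empty((N, N))
    for i in range(N):
        cross = np.fft.irfft2(np.conj(F[i]) * F, s=(n_bins, n_bins)) * h * h
        for j in range(N):
            ring = map_coordinates(
                cross[j], coords, order=1, mode="grid-wrap"
            ).reshape(len(tau), CIRCLE_ANGLES)
            C[i, j] = ring.mean(axis=1) @ kw
    return (w_tot / L ** 2) * 0.5 * (C + C.T)


def correlation_matrix(
    ensemble: InputEnsemble,
    kernel: AdaptationKernel,
    v: float,
    w_tot: float,
    method: str = "modes",
    n_bins: int = 100,
) -> CorrelationModel:
    """Build the N x N input-correlation model for an ensemble.

    method="modes" expands the Gaussian-mixture tuning curves exactly over
    torus Fourier modes with the closed-form Hankel factor (fast and exact
    for the ensembles this package generates).  method="maps" is the
    general construction from gridded tuning curves via FFT
    cross-correlograms and circle averaging; it is the independent
    cross-check and works for arbitrary tuning shapes.
    """
    if method == "modes":
        mat = _matrix_from_modes(ensemble, kernel, v, w_tot)
    elif method == "maps":
        mat = _matrix_from_maps(ensemble, kernel, v, w_tot, n_bins=n_bins)
    else:
        raise ValueError("method must be 'modes' or 'maps'")
    return CorrelationModel(
        matrix=mat,
        rho=ensemble.rho,
        w_tot=w_tot,
        v=v,
        kernel=kernel,
        method=method,
    )


def stdp_kernel_overlap(plasticity: PlasticityParams, kernel) -> float:
    """Closed-form window-kernel overlap int W(s) K(-s) ds.

    With the symmetric exponential window, each kernel component A e^{-t/th}
    contributes (W_tot / 2 tau_w) * A / (1/tau_w + 1/th).
    """
    w0 = plasticity.w_tot / (2.0 * plasticity.tau_w)
    return float(
        sum(
            w0 * a / (1.0 / plasticity.tau_w + 1.0 / th)
            for a, th in kernel.components
        )
    )


def derive_ab(
    plasticity: PlasticityParams,
    kernel,
    neuron: NeuronParams,
    r_av: float,
) -> dict[str, float]:
    """Effective decay/drive rates of the averaged dynamics (units s^-1)."""
    a = r_av * (plasticity.alpha - stdp_kernel_overlap(plasticity, kernel))
    b = r_av * (plasticity.w_tot * neuron.r_0 + plasticity.beta)
    return {"a": a, "b": b}


def normalization_quantities(
    model: CorrelationModel | np.ndarray,
    a: float,
    b: float,
    eta: float,
) -> dict[str, float]:
    """Steady-state mean weight w_av_inf and normalization time tau_av.

    The mean weight obeys eta^-1 d w_av/dt = (N C_av - a) w_av + b, hence
    w_av_inf = b / (a - N C_av) and tau_av = 1 / (eta (a - N C_av)), valid
    while a - N C_av > 0.
    """
    mat = model.matrix if isinstance(model, CorrelationModel) else np.asarray(model)
    n = mat.shape[0]
    denom = a - n * float(mat.mean())
    if denom <= 0:
        raise ValueError(
            "unstable normalization: a - N*C_av must be positive "
            f"(got {denom:.4g})"
        )
    return {"w_av_inf": b / denom, "tau_av": 1.0 / (eta * denom)}


@dataclass
class AveragedHistory:
    """Checkpoints of the averaged weight integration."""

    times: np.ndarray  # (n_checkpoints,)
    weights: np.ndarray  # (n_checkpoints, ...) matching w_init shape
    final: np.ndarray


def integrate(
    model: CorrelationModel | np.ndarray,
    params: AveragedParams,
    w_init: np.ndarray,
    t_end: float,
    checkpoints: np.ndarray | None = None,
    clamp: bool = True,
    divergence_limit: float | None = None,
) -> AveragedHistory:
    """Forward-Euler integration of the averaged drift (projected on w >= 0).

    ``w_init`` may be (N,) or (B, N) to evolve B initializations at once.
    The clamp projects onto the non-negativity constraint after each Euler
    step; disabling it recovers the linear system (used to demonstrate that
    weight saturation is the nonlinearity responsible for the triangular
    symmetry).  Integration aborts with a diagnostic if any weight exceeds
    ``divergence_limit`` (default 1e3 * max(|w_init|, b/a)).
    """
    C = model.matrix if isinstance(model, CorrelationModel) else np.asarray(model)
    w = np.atleast_2d(np.asarray(w_init, dtype=float)).copy()
    single = np.asarray(w_init).ndim == 1
    if w.shape[1] != C.shape[0]:
        raise ValueError("w_init length does not match correlation matrix")
    a, b, eta, dt = params.a, params.b, params.eta, params.dt
    # spectral-radius estimate by power iteration (C is symmetric)
    vec = np.random.default_rng(0).standard_normal(C.shape[0])
    for _ in range(12):
        vec = C @ vec
        vec /= np.linalg.norm(vec)
    lam_scale = float(np.abs(vec @ (C @ vec))) + a
    if eta * dt * lam_scale > 1.5:  # forward Euler diverges at 2
        raise ValueError(
            "Euler step unstable: eta * dt * |lambda| = "
            f"{eta * dt * lam_scale:.3g} > 1.5; reduce dt"
        )
    if divergence_limit is None:
        divergence_limit = 1e3 * max(np.abs(w).max(), abs(b / a), 1e-3)

    n_steps = int(round(t_end / dt))
    if checkpoints is None:
        checkpoints = np.array([t_end])
    ck = np.asarray(checkpoints, dtype=float)
    ck_steps = np.minimum(np.round(ck / dt).astype(int), n_steps)
    snaps = np.empty((len(ck),) + w.shape)
    next_ck = 0
    for i in range(n_steps + 1):
        while next_ck < len(ck) and ck_steps[next_ck] == i:
            snaps[next_ck] = w
            next_ck += 1
        if i == n_steps:
            break
        w += (eta * dt) * (w @ C - a * w + b)
        if clamp:
            np.maximum(w, 0.0, out=w)
        if np.abs(w).max() > divergence_limit:
            raise RuntimeError(
                f"averaged integration diverged at t={ (i + 1) * dt:.0f} s "
                f"(|w| > {divergence_limit:.3g})"
            )
    weights = snaps[:, 0, :] if single else snaps
    return AveragedHistory(times=ck, weights=weights, final=weights[-1].copy())
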