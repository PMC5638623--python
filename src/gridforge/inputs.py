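"""Spatially tuned input ensembles on a periodic square arena.

Two scenarios feed the output neuron:

* *regular* inputs — each of the N neurons has a single circular Gaussian
  receptive field; the field centers tile the arena on an even sqrt(N) x
  sqrt(N) lattice (place-cell-like tuning, density rho = N/L^2);
* *irregular* inputs — each neuron superimposes M Gaussian fields with
  uniformly random centers and amplitudes A_ij ~ U(0,1), normalized by
  beta_i = sum_j A_ij so every tuning curve has the same spatial mean r_av
  (parasubiculum-like multi-field tuning).

The Gaussian field G(r) = L^2 r_av / (2 pi sigma^2) exp(-r^2 / 2 sigma^2) is
normalized so that its wrapped spatial mean over the arena equals r_av.
Periodic evaluation uses the minimal image, extended to a 3x3 image sum when
the field is wide relative to the arena (4 sigma >= L/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import minimal_image

__all__ = [
    "GaussianFieldSpec",
    "InputEnsemble",
    "Map2D",
    "RateMapGrid",
    "make_regular_ensemble",
    "make_irregular_ensemble",
    "rate_at",
    "rate_map",
    "rates_at_positions",
]


@dataclass(frozen=True)
class GaussianFieldSpec:
    """Shape of a single input receptive field.

    sigma : field width, metres.
    r_av : spatial-average firing rate of the tuning curve, spikes/s.
    L : arena side length, metres.
    """

    sigma: float = 0.0625
    r_av: float = 0.4
    L: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0 or self.r_av <= 0 or self.L <= 0:
            raise ValueError("require sigma > 0, r_av > 0, L > 0")

    @property
    def peak(self) -> float:
        """Field amplitude at its center, L^2 r_av / (2 pi sigma^2)."""
        return self.L ** 2 * self.r_av / (2.0 * np.pi * self.sigma ** 2)


@dataclass(frozen=True)
class Map2D:
    """Square map of values over the arena, bin-center sampled.

    Row index = y, column index = x, origin at the lower-left; bin centers
    at (i + 1/2) L / n_bins.
    """

    values: np.ndarray
    L: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Map2D values must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("Map2D values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_size(self) -> float:
        return self.L / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


#: Discretized firing-rate map (alias kept for the rate-map producing API).
RateMapGrid = Map2D


@dataclass(frozen=True)
class InputEnsemble:
    """Collection of N input tuning curves.

    centers : (N, M, 2) field centers on the torus (M=1 for regular).
    amplitudes : (N, M) field weights in (0, 1) (all ones for regular).
    betas : (N,) per-neuron normalizers sum_j A_ij.
    """

    kind: str
    centers: np.ndarray
    amplitudes: np.ndarray
    spec: GaussianFieldSpec
    seed: int | None = None

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if c.ndim != 3 or c.shape[2] != 2 or a.shape != c.shape[:2]:
            raise ValueError("centers must be (N, M, 2) with matching amplitudes")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "amplitudes", a)

    @property
    def N(self) -> int:
        return self.centers.shape[0]

    @property
    def M(self) -> int:
        return self.centers.shape[1]

    @property
    def betas(self) -> np.ndarray:
        return self.amplitudes.sum(axis=1)

    @property
    def rho(self) -> float:
        """Input density N / L^2 (m^-2)."""
        return self.N / self.spec.L ** 2

    def field_weights(self) -> np.ndarray:
        """(N, M) weights A_ij / beta_i with which fields enter the rate."""
        return self.amplitudes / self.betas[:, None]

    def save(self, path) -> None:
        np.savez(
            path,
            kind=self.kind,
            centers=self.centers,
            amplitudes=self.amplitudes,
            sigma=self.spec.sigma,
            r_av=self.spec.r_av,
            L=self.spec.L,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def load(cls, path) -> "InputEnsemble":
        d = np.load(path)
        seed = int(d["seed"])
        return cls(
            kind=str(d["kind"]),
            centers=d["centers"],
            amplitudes=d["amplitudes"],
            spec=GaussianFieldSpec(
                sigma=float(d["sigma"]), r_av=float(d["r_av"]), L=float(d["L"])
            ),
            seed=None if seed < 0 else seed,
        )


def make_regular_ensemble(N: int, spec: GaussianFieldSpec) -> InputEnsemble:
    """Even sqrt(N) x sqrt(N) lattice of single-field neurons (deterministic)."""
    side = int(round(np.sqrt(N)))
    if side * side != N:
        raise ValueError("regular ensemble requires a perfect-square N")
    d = spec.L / side
    ax = np.arange(side) * d
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])[:, None, :]
    return InputEnsemble(
        kind="regular",
        centers=centers,
        amplitudes=np.ones((N, 1)),
        spec=spec,
    )


def make_irregular_ensemble(
    N: int,
    M: int,
    spec: GaussianFieldSpec,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> InputEnsemble:
    """N neurons with M uniformly placed fields and amplitudes ~ U(0, 1)."""
    if M < 1:
        raise ValueError("require M >= 1")
    if seed is not None:
        rng = seed
    stored_seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    centers = rng.uniform(0.0, spec.L, size=(N, M, 2))
    amps = rng.uniform(0.0, 1.0, size=(N, M))
    while np.any(amps <= 0.0):  # open interval (0,1); guards beta_i = 0 at M=1
        bad = amps <= 0.0
        amps[bad] = rng.uniform(0.0, 1.0, size=int(bad.sum()))
    return InputEnsemble(
        kind="irregular",
        centers=centers,
        amplitudes=amps,
        spec=spec,
        seed=None if stored_seed is None else int(stored_seed),
    )


def _periodic_gauss(delta: np.ndarray, spec: GaussianFieldSpec) -> np.ndarray:
    """Wrapped Gaussian of displacement vectors (..., 2), unit amplitude at 0.

    Minimal-image evaluation; when the field is wide (4 sigma >= L/2) the
    3x3 neighbouring images are summed as well (truncation beyond is < 1e-6
    of the peak for sigma << L).
    """
    L, s2 = spec.L, spec.sigma ** 2
    d = minimal_image(delta, L)
    if 4.0 * spec.sigma < 0.5 * L:
        r2 = np.sum(d * d, axis=-1)
        return np.exp(-0.5 * r2 / s2)
    out = 0.0
    for ix in (-L, 0.0, L):
        for iy in (-L, 0.0, L):
            r2 = (d[..., 0] + ix) ** 2 + (d[..., 1] + iy) ** 2
            out = out + np.exp(-0.5 * r2 / s2)
    return out


def rate_at(ensemble: InputEnsemble, neuron: int, x) -> float | np.ndarray:
    """Firing rate of one neuron at position(s) x (shape (2,) or (P, 2))."""
    if not 0 <= neuron < ensemble.N:
        raise IndexError("neuron index out of range")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = x[None, :] if single else x
    delta = pts[:, None, :] - ensemble.centers[neuron][None, :, :]
    g = _periodic_gauss(delta, ensemble.spec)  # (P, M)
    w = ensemble.field_weights()[neuron]
    rates = ensemble.spec.peak * (g @ w)
    return float(rates[0]) if single else rates


def rates_at_positions(
    ensemble: InputEnsemble, positions, chunk: int = 512
) -> np.ndarray:
    """Rates of all N neurons at P positions; returns (P, N)."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    flat_centers = ensemble.centers.reshape(-1, 2)
    flat_w = ensemble.field_weights().ravel()
    out = np.empty((len(pts), ensemble.N))
    for lo in range(0, len(pts), chunk):
        sel = pts[lo : lo + chunk]
        delta = sel[:, None, :] - flat_centers[None, :, :]
        g = _periodic_gauss(delta, ensemble.spec) * flat_w[None, :]
        out[lo : lo + len(sel)] = g.reshape(len(sel), ensemble.N, ensemble.M).sum(2)
    return ensemble.spec.peak * out


def rate_map(ensemble: InputEnsemble, neuron: int, n_bins: int) -> Map2D:
    """Tuning curve of one neuron sampled at every bin center."""
    if n_bins < 8:
        raise ValueError("require n_bins >= 8")
    c = (np.arange(n_bins) + 0.5) * ensemble.spec.L / n_bins
    gx, gy = np.meshgrid(c, c)  # row = y, column = x
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = rate_at(ensemble, neuron, pts).reshape(n_bins, n_bins)
    return Map2D(vals, ensemble.spec.L)
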