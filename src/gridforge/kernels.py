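"""Temporal adaptation kernels and their spatial / spectral transforms.

The output neuron's spike-rate adaptation is modelled as a causal temporal
filter K applied to the input spike trains.  K is a difference of two
exponentials: a fast excitatory lobe (time constant ``tau_s``) followed by a
slow inhibitory lobe (``tau_l``), with ``mu`` scaling the inhibitory part so
that the filter integral is ``1 - mu``.  Acting along a trajectory of speed
``v``, the temporal filter is equivalent to a radial spatial kernel
``K_sp(r) = K(r/v) / (r v)`` whose zeroth-order Hankel transform enters the
dispersion relation of the averaged weight dynamics.

All frequency arguments are in cycles per unit (s^-1 or m^-1); standard
Fourier/Bessel transforms are therefore evaluated at angular frequency 2*pi*k.

An after-spike-potential (AHP) variant is provided through an equivalent
feed-forward kernel with the same evaluation contract, so every consumer of a
kernel (spiking simulator, correlation builder, spectral analysis) is
agnostic to which adaptation mechanism generated it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdaptationKernel",
    "AHPKernel",
    "KernelSingularityError",
    "resonance_frequency",
]


class KernelSingularityError(ValueError):
    """Pointwise evaluation requested at the (integrable) r=0 singularity."""


class _ExponentialMixtureKernel:
    """Shared behaviour for causal kernels K(t) = sum_c A_c exp(-t/theta_c)."""

    @property
    def components(self) -> tuple[tuple[float, float], ...]:
        """Pairs (amplitude A_c, time constant theta_c) of the mixture."""
        raise NotImplementedError

    @property
    def integral(self) -> float:
        """Integral of K over [0, inf): sum of A_c * theta_c."""
        return float(sum(a * th for a, th in self.components))

    @property
    def tau_max(self) -> float:
        """Support used for discrete convolutions: 5x the slowest decay."""
        return 5.0 * max(th for _, th in self.components)

    def __call__(self, t):
        return self.value(t)

    def value(self, t):
        """Evaluate K(t); exactly 0 for t < 0 (causality)."""
        t = np.asarray(t, dtype=float)
        pos = t >= 0
        tp = np.where(pos, t, 0.0)
        out = np.zeros(t.shape, dtype=float)
        for a, th in self.components:
            out += a * np.exp(-tp / th)
        out = np.where(pos, out, 0.0)
        return out if out.ndim else float(out)

    def integral_upto(self, t_upper: float) -> float:
        """Integral of K over [0, t_upper]."""
        return float(
            sum(a * th * (1.0 - np.exp(-t_upper / th)) for a, th in self.components)
        )

    def frequency_response(self, f):
        """Fourier transform of K at temporal frequency f (cycles/s).

        For each exponential component, F{A e^{-t/theta}}(2 pi f) =
        A theta / (1 + 2 pi j f theta).  The DC gain equals the kernel
        integral.
        """
        f = np.asarray(f, dtype=float)
        jw = 2j * np.pi * f
        out = sum(a * th / (1.0 + jw * th) for a, th in self.components)
        return out if np.ndim(out) else complex(out)

    def spatial(self, v: float, r):
        """Equivalent spatial kernel K_sp(r) = K(r/v) / (r v) for r > 0."""
        if v <= 0:
            raise ValueError("speed v must be positive")
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise KernelSingularityError(
                "K_sp has an integrable singularity at r=0; evaluate r>0 only"
            )
        out = self.value(r / v) / (r * v)
        return out if out.ndim else float(out)

    def spatial_hankel(self, v: float, k):
        """Closed-form Hankel transform of K_sp at spatial frequency k (m^-1).

        integral_0^inf K(tau) J0(2 pi k v tau) dtau evaluated through the
        Laplace transform of J0: each exponential component contributes
        A / sqrt(theta^-2 + (2 pi k v)^2).  Units: seconds.
        """
        if v <= 0:
            raise ValueError("speed v must be positive")
        k = np.asarray(k, dtype=float)
        if np.any(k < 0):
            raise ValueError("spatial frequency k must be >= 0")
        c2 = (2.0 * np.pi * k * v) ** 2
        out = sum(a / np.sqrt(th ** -2 + c2) for a, th in self.components)
        return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class AdaptationKernel(_ExponentialMixtureKernel):
    """Biphasic spike-rate adaptation kernel.

    K(t) = (1/tau_s) e^{-t/tau_s} - (mu/tau_l) e^{-t/tau_l}  for t >= 0.

    Parameters
    ----------
    tau_s : short (excitatory) time constant, seconds; 0 < tau_s < tau_l.
    tau_l : long (inhibitory) time constant, seconds.
    mu : dimensionless scale of the inhibitory lobe; the kernel integral
        is 1 - mu, negative for mu > 1 (net-inhibitory adaptation).
    """

    tau_s: float = 0.1
    tau_l: float = 0.16
    mu: float = 1.06

    def __post_init__(self):
        if not (0.0 < self.tau_s < self.tau_l):
            raise ValueError("require 0 < tau_s < tau_l")
        if self.mu <= 0:
            raise ValueError("require mu > 0")

    @property
    def components(self):
        return ((1.0 / self.tau_s, self.tau_s), (-self.mu / self.tau_l, self.tau_l))

    def replace(self, **changes) -> "AdaptationKernel":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class AHPKernel(_ExponentialMixtureKernel):
    """Equivalent feed-forward kernel of an after-spike-potential model.

    An excitatory input PSP kernel (1/tau_in) e^{-t/tau_in} combined with an
    output-spike-triggered hyperpolarization of integral -mu_out and decay
    tau_out is, on average, equivalent to the feed-forward kernel

        K_eq(t) = H [ (1/tau_in - 1/tau_out) e^{-t/tau_in}
                      - (mu_out/tau_out) e^{-t (1+mu_out)/tau_out} ]

    with H = (1/tau_in) / (1/tau_in - (1+mu_out)/tau_out).  The integral of
    K_eq is 1/(1+mu_out), always positive.
    """

    tau_in: float = 0.005
    tau_out: float = 1.0
    mu_out: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.tau_in < self.tau_out):
            raise ValueError("require 0 < tau_in < tau_out")
        if self.mu_out <= 0:
            raise ValueError("require mu_out > 0")
        if abs(1.0 / self.tau_in - (1.0 + self.mu_out) / self.tau_out) < 1e-12:
            raise ValueError(
                "degenerate AHP parameters: 1/tau_in == (1+mu_out)/tau_out"
            )

    @property
    def prefactor(self) -> float:
        return (1.0 / self.tau_in) / (
            1.0 / self.tau_in - (1.0 + self.mu_out) / self.tau_out
        )

    @property
    def components(self):
        h = self.prefactor
        return (
            (h * (1.0 / self.tau_in - 1.0 / self.tau_out), self.tau_in),
            (-h * self.mu_out / self.tau_out, self.tau_out / (1.0 + self.mu_out)),
        )

    def replace(self, **changes) -> "AHPKernel":
        return dataclasses.replace(self, **changes)


def resonance_frequency(
    kernel: _ExponentialMixtureKernel,
    f_max: float = 10.0,
    df: float = 1e-3,
) -> float:
    """Temporal frequency (cycles/s) maximizing |frequency response|.

    Scans a regular grid (0, f_max] with step df and refines the argmax by
    local parabolic interpolation.
    """
    f = np.arange(df, f_max + 0.5 * df, df)
    mag = np.abs(kernel.frequency_response(f))
    j = int(np.argmax(mag))
    if 0 < j < len(f) - 1:
        y0, y1, y2 = mag[j - 1 : j + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            return float(f[j] - 0.5 * (y2 - y0) / denom * df)
    return float(f[j])
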