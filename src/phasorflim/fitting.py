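"""Mono- and biexponential least-squares fitting of TCSPC histograms.

The model is fitted to binned counts: the expected count in bin k is the
integral of ``sum_i a_i * exp(-t/tau_i)`` over the bin, so the fit is
consistent with the synthetic generator's binning (no center-of-bin
approximation bias).  The objective is Poisson-weighted least squares
with weights ``1/max(c_k, 1)``, bounded to tau in [50 ps, 12 ns].

Summary lifetimes for a two-component fit:

    amplitude-weighted mean   a1*tau1 + a2*tau2
    intensity-weighted mean   sum a_i*tau_i^2 / sum a_i*tau_i

with amplitude fractions a1 + a2 = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data_model import AcquisitionMetadata

__all__ = [
    "MonoExpFit",
    "BiExpFit",
    "FitError",
    "fit_monoexponential",
    "fit_biexponential",
    "amplitude_weighted_mean",
    "intensity_weighted_fractions",
]

TAU_MIN_S = 50e-12
TAU_MAX_S = 12e-9

#: tau1/tau2 above this at the optimum is reported as ill-separated
SEPARATION_RATIO = 0.8


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge."""


@dataclass
class MonoExpFit:
    tau_ps: float
    amplitude: float
    reduced_residual: float
    at_bound: bool = False


@dataclass
class BiExpFit:
    """Two-exponential fit, components ordered tau1 <= tau2."""

    tau1_ps: float
    tau2_ps: float
    a1: float
    a2: float
    tau_amp_mean_ps: float
    tau_int_mean_ps: float
    reduced_residual: float
    ill_separated: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tau1_ps <= self.tau2_ps):
            raise ValueError("components must satisfy 0 < tau1 <= tau2")
        if min(self.a1, self.a2) < 0 or abs(self.a1 + self.a2 - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must be non-negative and sum to 1")

    @classmethod
    def from_components(
        cls,
        tau1_ps: float,
        tau2_ps: float,
        a1: float,
        a2: float,
        reduced_residual: float = 0.0,
        ill_separated: bool = False,
    ) -> "BiExpFit":
        if tau1_ps > tau2_ps:
            tau1_ps, tau2_ps, a1, a2 = tau2_ps, tau1_ps, a2, a1
        amp_mean = a1 * tau1_ps + a2 * tau2_ps
        denom = a1 * tau1_ps + a2 * tau2_ps
        int_mean = (a1 * tau1_ps**2 + a2 * tau2_ps**2) / denom if denom > 0 else np.nan
        return cls(
            tau1_ps=tau1_ps,
            tau2_ps=tau2_ps,
            a1=a1,
            a2=a2,
            tau_amp_mean_ps=amp_mean,
            tau_int_mean_ps=int_mean,
            reduced_residual=reduced_residual,
            ill_separated=ill_separated,
        )


def amplitude_weighted_mean(fit: BiExpFit) -> float:
    """``a1*tau1 + a2*tau2`` in ps."""
    return fit.a1 * fit.tau1_ps + fit.a2 * fit.tau2_ps


def intensity_weighted_fractions(fit: BiExpFit) -> tuple[float, float]:
    """Photon (intensity) fractions ``f_i = a_i*tau_i / sum_j a_j*tau_j``."""
    w1 = fit.a1 * fit.tau1_ps
    w2 = fit.a2 * fit.tau2_ps
    total = w1 + w2
    return w1 / total, w2 / total


def _bin_factors(tau_s: np.ndarray | float, edges_s: np.ndarray) -> np.ndarray:
    # integral of exp(-t/tau) over each bin = tau*(e^{-t_k/tau}-e^{-t_{k+1}/tau})
    e = np.exp(-edges_s[None, :] / np.atleast_1d(tau_s)[:, None])
    return np.atleast_1d(tau_s)[:, None] * (e[:, :-1] - e[:, 1:])


# The optimizer works in scaled units -- lifetimes in ns, component
# amplitudes as O(1) multiples of the total count -- so that all free
# parameters share a scale and trust-region steps behave.
_NS = 1e-9


def _weights(counts: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(np.maximum(counts, 1.0))


def fit_monoexponential(hist: Sequence[float], meta: AcquisitionMetadata) -> MonoExpFit:
    """Weighted least-squares fit of ``A*exp(-t/tau)`` to a decay histogram.

    Requires >= 100 total photons and >= 8 bins.  Deterministic: the
    initial lifetime comes from the histogram's mean arrival time.
    """
    counts = np.asarray(hist, dtype=float)
    if counts.ndim != 1 or counts.size < 8:
        raise ValueError("histogram must be 1-D with >= 8 bins")
    if counts.sum() < 100:
        raise ValueError("mono fit requires >= 100 total photons")
    edges = meta.bin_edges_s
    t = meta.bin_centers_s
    w = _weights(counts)
    total = counts.sum()

    tau0 = float(np.clip((counts @ t) / total, TAU_MIN_S * 2, TAU_MAX_S / 2))

    def resid(p):
        alpha, tau_ns = p
        model = total * alpha * _bin_factors(tau_ns * _NS, edges)[0] / _NS
        return (model - counts) * w

    x0 = np.array([1.0 / (tau0 / _NS), tau0 / _NS])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, TAU_MIN_S / _NS], [np.inf, TAU_MAX_S / _NS]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not sol.success:
        raise FitError(f"mono fit failed: {sol.message}")
    alpha, tau_ns = sol.x
    a, tau = total * alpha / _NS, tau_ns * _NS
    dof = max(counts.size - 2, 1)
    at_bound = bool(
        np.isclose(tau, TAU_MIN_S, rtol=1e-6) or np.isclose(tau, TAU_MAX_S, rtol=1e-6)
    )
    return MonoExpFit(
        tau_ps=tau * 1e12,
        amplitude=a,
        reduced_residual=float(2 * sol.cost / dof),
        at_bound=at_bound,
    )


def fit_biexponential(
    hist: Sequence[float],
    meta: AcquisitionMetadata,
    init: Optional[tuple[float, float, float]] = None,
) -> BiExpFit:
    """Weighted least-squares fit of ``a1*exp(-t/tau1) + a2*exp(-t/tau2)``.

    Requires >= 1000 total photons and >= 16 bins.  ``init`` may supply
    starting values ``(tau1_s, tau2_s, a1_fraction)``; by default a mono
    fit seeds the components at ``(tau_hat/3, 1.5*tau_hat)`` with equal
    amplitudes.  A fit whose optimum has ``tau1/tau2 > 0.8`` is flagged
    ill-separated (warning, not an error).
    """
    counts = np.asarray(hist, dtype=float)
    if counts.ndim != 1 or counts.size < 16:
        raise ValueError("histogram must be 1-D with >= 16 bins")
    total = counts.sum()
    if total < 1000:
        raise ValueError("biexp fit requires >= 1000 total photons")
    edges = meta.bin_edges_s
    w = _weights(counts)

    if init is None:
        tau_hat = fit_monoexponential(counts, meta).tau_ps * 1e-12
        tau1_0 = np.clip(tau_hat / 3.0, TAU_MIN_S, TAU_MAX_S)
        tau2_0 = np.clip(1.5 * tau_hat, TAU_MIN_S, TAU_MAX_S)
        f1_0 = 0.5
    else:
        tau1_0, tau2_0, f1_0 = init
    # scaled amplitudes: component amplitude = total * alpha_i / 1 ns
    amp0 = 1.0 / ((f1_0 * tau1_0 + (1 - f1_0) * tau2_0) / _NS + 1e-30)

    def resid(p):
        alpha1, alpha2, tau1_ns, tau2_ns = p
        q = _bin_factors(np.array([tau1_ns, tau2_ns]) * _NS, edges)
        model = total * (alpha1 * q[0] + alpha2 * q[1]) / _NS
        return (model - counts) * w

    x0 = np.array([f1_0 * amp0, (1 - f1_0) * amp0, tau1_0 / _NS, tau2_0 / _NS])
    lo, hi = TAU_MIN_S / _NS, TAU_MAX_S / _NS
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, lo, lo], [np.inf, np.inf, hi, hi]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10000,
    )
    if not sol.success:
        raise FitError(f"biexp fit failed: {sol.message}")
    a1_raw, a2_raw = sol.x[0], sol.x[1]
    tau1, tau2 = sol.x[2] * _NS, sol.x[3] * _NS
    amp_total = a1_raw + a2_raw
    if amp_total <= 0:
        raise FitError("biexp fit degenerate: zero total amplitude")
    a1, a2 = a1_raw / amp_total, a2_raw / amp_total
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    ill = bool(tau1 / tau2 > SEPARATION_RATIO or min(a1, a2) < 1e-6)
    if ill:
        warnings.warn(
            f"biexp components ill-separated (tau1/tau2 = {tau1 / tau2:.3f}, "
            f"a = ({a1:.3g}, {a2:.3g}))",
            stacklevel=2,
        )
    dof = max(counts.size - 4, 1)
    return BiExpFit.from_components(
        tau1_ps=tau1 * 1e12,
        tau2_ps=tau2 * 1e12,
        a1=a1,
        a2=a2,
        reduced_residual=float(2 * sol.cost / dof),
        ill_separated=ill,
    )
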