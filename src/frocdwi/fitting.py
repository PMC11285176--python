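"""Voxel-wise nonlinear least-squares estimation of diffusion parameters.

Both models are fitted to the normalized signal ``S_b / S_0`` (the measured
b = 0 volume provides the normalizer; S0 is not a free parameter).  The
mono-exponential ADC is fitted by nonlinear least squares over all b-values,
for symmetry with the FROC fit.  The FROC fit estimates (D, β, µ) under box
constraints with a trust-region-reflective Levenberg–Marquardt-type solver:

* bounds: D ∈ [1e-4, 4] µm²/ms, β ∈ [0.05, 1], µ ∈ [0.1, 20] µm;
* warm start: D₀ = the voxel's mono-exponential ADC, β₀ = 0.9, µ₀ = 5 µm;
* one restart from (D₀, 0.6, 2.5) if the first solution lands on a bound,
  keeping the lower-residual fit;
* convergence: relative tolerance 1e-8, at most 500 iterations.

Identifiability caveat: with fixed gradient timings the FROC signal is
``exp(-K b^β)``, so the data determine only β and the composite decay
coefficient K (see :func:`frocdwi.signal_models.froc_decay_coefficient`) —
D and µ individually lie on an exact zero-residual ridge and the values the
fit reports for them depend on the (documented, deterministic) warm start.
β and K are the quantities to compare across fits; at β = 1 additionally
µ drops out entirely and D equals the ADC.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .phantom import DwiSeries
from .signal_models import (AcquisitionProtocol, FrocParams, MonoExpParams,
                            froc_signal, mono_exp_signal)

__all__ = [
    "FitResult",
    "ParameterMaps",
    "FROC_BOUNDS",
    "fit_monoexp",
    "fit_froc",
    "fit_volume",
    "voi_statistics",
]

#: Box constraints of the FROC fit: (lower, upper) per (D, beta, mu).
FROC_BOUNDS = ((1e-4, 0.05, 0.1), (4.0, 1.0, 20.0))

_XTOL = 1e-8
_MAX_NFEV = 500


class FitError(ValueError):
    """Raised when a voxel cannot be fitted (e.g. non-positive S0)."""


@dataclass
class FitResult:
    """Outcome of a single-voxel fit."""

    params: Union[FrocParams, MonoExpParams]
    residual_norm: float
    converged: bool
    n_iter: int


@dataclass
class ParameterMaps:
    """Voxel-wise D/β/µ/ADC maps with a convergence QC mask.

    Unfitted (unmasked) voxels are NaN; ``converged`` is False there and for
    masked voxels whose fit did not converge.
    """

    D: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    adc: np.ndarray
    converged: np.ndarray


def _normalize(signal, protocol):
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != len(protocol):
        raise ValueError(
            f"signal length {signal.shape[-1]} != number of b-values {len(protocol)}")
    i0 = protocol.b_values.index(0.0)
    s0 = signal[i0]
    if not s0 > 0:
        raise FitError("signal at b=0 must be positive")
    return signal / s0


def fit_monoexp(signal, protocol: AcquisitionProtocol) -> FitResult:
    """Least-squares ADC estimate from a multi-b-value signal.

    Exact on noiseless mono-exponential input; a constant signal gives
    ADC = 0 (the lower bound).
    """
    y = _normalize(signal, protocol)
    b = np.asarray(protocol.b_values)

    def resid(theta):
        return np.exp(-b / 1000.0 * theta[0]) - y

    # Log-linear warm start (guarded against non-positive signals).
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(b[pos]) > 0:
        slope = -np.polyfit(b[pos] / 1000.0, np.log(y[pos]), 1)[0]
        x0 = float(np.clip(slope, 0.0, 10.0))
    else:
        x0 = 1.0
    sol = least_squares(resid, [x0], bounds=([0.0], [np.inf]),
                        xtol=_XTOL, max_nfev=_MAX_NFEV)
    return FitResult(
        params=MonoExpParams(adc=float(sol.x[0])),
        residual_norm=float(2 * sol.cost),
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
    )


def _froc_residual_factory(y, b, protocol):
    delta, big_delta = protocol.delta, protocol.big_delta
    q2 = (b / 1000.0) / protocol.diffusion_time  # q², µm⁻²

    def resid(theta):
        D, beta, mu = theta
        t_eff = big_delta - (2 * beta - 1) / (2 * beta + 1) * delta
        expo = D * mu ** (2 * (beta - 1)) * q2 ** beta * t_eff
        return np.exp(-expo) - y

    return resid


def fit_froc(signal, protocol: AcquisitionProtocol,
             init: Optional[FrocParams] = None,
             bounds=FROC_BOUNDS) -> FitResult:
    """Fit (D, β, µ) of the FROC model to one voxel's multi-b-value signal.

    Parameters
    ----------
    signal : array-like
        Magnitude signal per b-value (not yet normalized).
    protocol : AcquisitionProtocol
        Must provide ≥ 4 distinct b-values including 0.
    init : FrocParams, optional
        Explicit starting point; by default the warm start described in the
        module docstring is used.
    bounds : tuple of tuples
        (lower, upper) box constraints per (D, beta, mu).
    """
    if len(protocol) < 4:
        raise ValueError("FROC fit needs at least 4 distinct b-values")
    y = _normalize(signal, protocol)
    b = np.asarray(protocol.b_values)
    lower, upper = np.asarray(bounds[0]), np.asarray(bounds[1])
    resid = _froc_residual_factory(y, b, protocol)

    if init is not None:
        starts = [np.clip([init.D, init.beta, init.mu], lower, upper)]
    else:
        adc0 = fit_monoexp(signal, protocol).params.adc
        d0 = float(np.clip(adc0, lower[0], upper[0]))
        starts = [np.clip([d0, 0.9, 5.0], lower, upper)]

    best = None
    for attempt, x0 in enumerate(starts):
        sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                            xtol=_XTOL, max_nfev=_MAX_NFEV)
        if best is None or sol.cost < best.cost:
            best = sol
        # Restart from a heterogeneous interior point if the solution sits
        # on a box bound (β = 1 excluded: the mono-exponential limit is a
        # legitimate boundary solution).
        on_bound = bool(np.any(np.isclose(sol.x, lower))
                        or np.any(np.isclose(sol.x[:2], upper[:2])))
        if attempt == 0 and init is None and on_bound:
            starts.append(np.clip([starts[0][0], 0.6, 2.5], lower, upper))

    return FitResult(
        params=FrocParams(D=float(best.x[0]), beta=float(best.x[1]), mu=float(best.x[2])),
        residual_norm=float(2 * best.cost),
        converged=bool(best.success),
        n_iter=int(best.nfev),
    )


def fit_volume(series: DwiSeries, mask: np.ndarray) -> ParameterMaps:
    """Fit both models voxel-by-voxel inside ``mask``.

    Voxels whose fit raises (zero b=0 signal) or fails to converge are
    flagged in the QC mask; unmasked voxels are NaN.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} does not match grid {series.shape[:3]}")
    if not mask.any():
        raise ValueError("mask is empty")

    shape = series.shape[:3]
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(D=nan.copy(), beta=nan.copy(), mu=nan.copy(),
                         adc=nan.copy(), converged=np.zeros(shape, dtype=bool))
    for ijk in zip(*np.nonzero(mask)):
        sig = series.data[ijk]
        try:
            mono = fit_monoexp(sig, series.protocol)
            froc = fit_froc(sig, series.protocol)
        except FitError:
            continue
        maps.adc[ijk] = mono.params.adc
        maps.D[ijk] = froc.params.D
        maps.beta[ijk] = froc.params.beta
        maps.mu[ijk] = froc.params.mu
        maps.converged[ijk] = mono.converged and froc.converged
    return maps


def voi_statistics(param_map: np.ndarray, voi_mask: np.ndarray,
                   converged: Optional[np.ndarray] = None):
    """Mean and sample SD of a parameter map over a volume of interest.

    Only converged voxels contribute when a QC mask is given.  Returns
    ``(mean, sd)``; the SD uses the n−1 denominator (0.0 for a single voxel).
    """
    voi_mask = np.asarray(voi_mask).astype(bool)
    if not voi_mask.any():
        raise ValueError("VOI is empty")
    sel = voi_mask if converged is None else (voi_mask & np.asarray(converged))
    vals = np.asarray(param_map)[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("VOI contains no converged voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd
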