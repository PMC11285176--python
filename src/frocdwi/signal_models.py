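"""Forward diffusion signal models for multi-b-value DWI.

Two models of the normalized diffusion signal :math:`S_b/S_0`:

* the mono-exponential (Gaussian) model
  :math:`S_b/S_0 = \\exp(-b \\cdot ADC)`, and
* the fractional-order calculus (FROC) model

  .. math::

     S_b/S_0 = \\exp\\Bigl[-D\\,\\mu^{2(\\beta-1)}\\,q^{2\\beta}
               \\Bigl(\\Delta - \\tfrac{2\\beta-1}{2\\beta+1}\\,\\delta\\Bigr)\\Bigr]

  where :math:`q = \\gamma G_d \\delta` is the diffusion gradient factor,
  :math:`\\delta` the gradient pulse width, :math:`\\Delta` the gradient
  interval, D the anomalous diffusion coefficient (µm²/ms), β the intravoxel
  diffusion heterogeneity (unitless, 0 < β ≤ 1) and µ a spatial constant (µm).
  At β = 1 the FROC model reduces exactly to the mono-exponential model.

Scanners report nominal b-values, not gradient amplitudes, so q is recovered
from b through the Stejskal–Tanner relation ``b = q² (Δ − δ/3)``.  Under this
parameterization the gyromagnetic ratio γ never enters numerically; it is kept
as a documented constant only.

Units: b is accepted in s/mm² at every interface and converted internally via
1000 s/mm² = 1 ms/µm²; D and ADC are in µm²/ms (numerically equal to
10⁻³ mm²/s); µ in µm; δ, Δ in ms; q in µm⁻¹.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionProtocol",
    "FrocParams",
    "MonoExpParams",
    "b_to_gradient_factor",
    "froc_signal",
    "mono_exp_signal",
    "breast_14b_protocol",
]

#: Proton gyromagnetic ratio, rad/(ms·mT).  Documented for completeness: the
#: q-parameterization used throughout makes it drop out of every formula.
GAMMA_PROTON = 267.522187  # rad ms^-1 mT^-1

#: Unit conversion: 1000 s/mm² = 1 ms/µm².
_B_SMM2_PER_MS_UM2 = 1000.0


def _b_to_ms_per_um2(b_s_mm2):
    return np.asarray(b_s_mm2, dtype=float) / _B_SMM2_PER_MS_UM2


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Fixed experimental context of a multi-b-value DWI acquisition.

    Parameters
    ----------
    b_values : sequence of float
        Nominal diffusion weightings in s/mm², strictly increasing,
        containing 0.
    n_averages : sequence of int
        Number of averaged acquisitions per b-value (one entry per b).
    delta : float
        Diffusion gradient pulse width δ in ms.
    big_delta : float
        Diffusion gradient interval Δ in ms; must exceed ``delta``.
    gamma : float
        Proton gyromagnetic ratio; never used numerically, see module docs.
    """

    b_values: tuple
    n_averages: tuple
    delta: float
    big_delta: float
    gamma: float = GAMMA_PROTON

    def __init__(self, b_values: Sequence[float], n_averages: Sequence[int],
                 delta: float, big_delta: float, gamma: float = GAMMA_PROTON):
        b = tuple(float(v) for v in b_values)
        n = tuple(int(v) for v in n_averages)
        if len(b) == 0 or b[0] != 0.0 and 0.0 not in b:
            raise ValueError("b_values must contain 0")
        if any(v < 0 for v in b):
            raise ValueError("b_values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b_values must be strictly increasing")
        if len(n) != len(b):
            raise ValueError("n_averages must have one entry per b-value")
        if any(v < 1 for v in n):
            raise ValueError("every n_averages entry must be >= 1")
        if not (0.0 < delta < big_delta):
            raise ValueError("require 0 < delta < big_delta")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "n_averages", n)
        object.__setattr__(self, "delta", float(delta))
        object.__setattr__(self, "big_delta", float(big_delta))
        object.__setattr__(self, "gamma", float(gamma))

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def diffusion_time(self) -> float:
        """Effective diffusion time Δ − δ/3 (ms) of the Stejskal–Tanner pair."""
        return self.big_delta - self.delta / 3.0

    def to_dict(self) -> dict:
        return {
            "b_values": list(self.b_values),
            "n_averages": list(self.n_averages),
            "delta": self.delta,
            "big_delta": self.big_delta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(d["b_values"], d["n_averages"], d["delta"], d["big_delta"])

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class FrocParams:
    """FROC model parameters: D (µm²/ms), β (unitless, 0 < β ≤ 1), µ (µm)."""

    D: float
    beta: float
    mu: float

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


@dataclass(frozen=True)
class MonoExpParams:
    """Mono-exponential model parameter: ADC in µm²/ms (= 10⁻³ mm²/s)."""

    adc: float

    def __post_init__(self):
        if self.adc < 0:
            raise ValueError(f"adc must be non-negative, got {self.adc}")


def b_to_gradient_factor(b, protocol: AcquisitionProtocol):
    """Gradient factor q = γ·G_d·δ (µm⁻¹) for a nominal b-value (s/mm²).

    Inverts the Stejskal–Tanner relation ``b = q² (Δ − δ/3)``; this is the
    conventional practical mapping when the per-b gradient amplitude is not
    recorded, and it makes the β = 1 FROC limit coincide exactly with the
    mono-exponential model.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    q = np.sqrt(_b_to_ms_per_um2(b) / protocol.diffusion_time)
    return q if q.ndim else float(q)


def froc_signal(params: FrocParams, b, protocol: AcquisitionProtocol):
    """Normalized FROC signal S_b/S_0 at b-value(s) ``b`` (s/mm²).

    Equals 1 at b = 0, is strictly decreasing in b, and reduces to
    ``exp(-b·D)`` at β = 1.
    """
    q = b_to_gradient_factor(b, protocol)
    beta = params.beta
    t_eff = protocol.big_delta - (2 * beta - 1) / (2 * beta + 1) * protocol.delta
    exponent = params.D * params.mu ** (2 * (beta - 1)) * np.asarray(q) ** (2 * beta) * t_eff
    out = np.exp(-exponent)
    return out if out.ndim else float(out)


def mono_exp_signal(params: MonoExpParams, b):
    """Normalized mono-exponential signal exp(−b·ADC) at b (s/mm²)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = np.exp(-_b_to_ms_per_um2(b) * params.adc)
    return out if out.ndim else float(out)


def froc_decay_coefficient(params: FrocParams, protocol: AcquisitionProtocol) -> float:
    """The identifiable composite decay coefficient K of the FROC model.

    At fixed gradient timings the FROC signal is exactly
    ``exp(-K · b^β)`` (b in ms/µm²) with

    .. math::

       K = D\\,\\mu^{2(\\beta-1)}\\,
           \\frac{\\Delta - \\tfrac{2\\beta-1}{2\\beta+1}\\delta}
                {(\\Delta - \\delta/3)^{\\beta}} .

    D and µ enter the signal only through K: parameter sets with equal
    (K, β) are indistinguishable from a single-(δ, Δ) acquisition, so K and
    β — not D and µ separately — are the quantities a fit can recover.
    """
    beta = params.beta
    t_eff = protocol.big_delta - (2 * beta - 1) / (2 * beta + 1) * protocol.delta
    return (params.D * params.mu ** (2 * (beta - 1)) * t_eff
            / protocol.diffusion_time ** beta)


def breast_14b_protocol() -> AcquisitionProtocol:
    """The bundled 14-b-value breast protocol (0–3000 s/mm², δ=25.66 ms, Δ=30.13 ms)."""
    ref = importlib.resources.files("frocdwi") / "data" / "breast_14b_protocol.yaml"
    with ref.open() as fh:
        return AcquisitionProtocol.from_dict(yaml.safe_load(fh))
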