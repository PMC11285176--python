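"""Synthetic data generation: digital breast phantoms and lesion cohorts.

Two generators stand in for patient data:

* a **digital phantom** — a 3-D grid holding ellipsoidal lesions in a uniform
  tissue background, each voxel carrying ground-truth FROC parameters
  (D, β, µ) and a proton-density scale S0.  The forward FROC model plus
  Rician noise (magnitude of a complex Gaussian, the noise law of magnitude
  MR images) produces a 4-D multi-b-value series; per-b signal averaging is
  simulated as the mean of independent magnitude draws, matching how
  scanners build "means".  An ``air_fraction`` slab of the grid is
  signal-free, giving the background region that SNR measurements need
  (magnitude air noise is Rayleigh with mean σ·√(π/2)).

* a **lesion cohort** — per-lesion parameter values (D, β, µ, ADC) for a
  benign and a malignant group under two echo-planar DWI sequences
  (conventional single-shot, ``SSEPI``, and simultaneous-multi-slice
  accelerated, ``SMS``).  Values are truncated-normal draws (re-drawn
  outside each parameter's physical domain, β capped at 1) around
  group/sequence means and SDs; the two sequences share a latent Gaussian
  per lesion so paired sequence readings are correlated, as repeated
  measurements of one lesion are in practice.  The default moments are a
  published breast cohort (73 benign / 105 malignant lesions).

File formats: NIfTI-1 volumes, an FSL-style whitespace b-value text file
plus a YAML timing sidecar, and plain CSV cohort tables.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .signal_models import AcquisitionProtocol, FrocParams, froc_signal

__all__ = [
    "EllipsoidLesion",
    "PhantomSpec",
    "PhantomMaps",
    "DwiSeries",
    "CohortSpec",
    "TABLE_COHORT_MOMENTS",
    "generate_parameter_maps",
    "simulate_dwi_series",
    "simulate_phantom",
    "simulate_cohort",
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

#: Label-mask codes: air, normal tissue, lesions 2, 3, ...
LABEL_AIR = 0
LABEL_TISSUE = 1
LABEL_LESION_START = 2

#: Physical domains used when truncating cohort draws.
PARAM_DOMAINS = {
    "D": (1e-6, np.inf),
    "beta": (1e-6, 1.0),
    "mu": (1e-6, np.inf),
    "adc": (0.0, np.inf),
}

#: Benign/malignant cohort moments (mean, SD) per parameter and sequence,
#: from a 73/105-lesion breast study.  D and ADC in µm²/ms, µ in µm.
TABLE_COHORT_MOMENTS = {
    "benign": {
        "SSEPI": {"D": (1.17, 0.34), "beta": (0.86, 0.06), "mu": (3.06, 0.63), "adc": (1.30, 0.36)},
        "SMS": {"D": (1.21, 0.34), "beta": (0.86, 0.05), "mu": (3.20, 0.48), "adc": (1.33, 0.36)},
    },
    "malignant": {
        "SSEPI": {"D": (0.73, 0.18), "beta": (0.77, 0.06), "mu": (3.39, 0.42), "adc": (0.82, 0.20)},
        "SMS": {"D": (0.74, 0.18), "beta": (0.79, 0.05), "mu": (3.50, 0.34), "adc": (0.83, 0.20)},
    },
}

#: Default cross-sequence correlation per parameter (paired readings of one
#: lesion under the two sequences), set to the inter-sequence rank
#: correlations reported for this kind of cohort.
DEFAULT_SEQUENCE_CORRELATION = {"D": 0.95, "beta": 0.75, "mu": 0.65, "adc": 0.97}


@dataclass(frozen=True)
class EllipsoidLesion:
    """An ellipsoidal lesion: voxel-space center, semi-axes, params and S0."""

    center: tuple
    semi_axes: tuple
    params: FrocParams
    s0: float = 1.0


@dataclass
class PhantomSpec:
    """Geometry, tissue properties and noise level of a digital phantom."""

    grid_shape: tuple = (32, 32, 8)
    voxel_size: tuple = (0.9, 0.9, 4.0)
    lesions: Sequence[EllipsoidLesion] = ()
    background: FrocParams = field(default_factory=lambda: FrocParams(D=1.8, beta=0.95, mu=6.0))
    background_s0: float = 1.0
    air_fraction: float = 0.25
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.air_fraction < 1.0):
            raise ValueError("air_fraction must lie in [0, 1)")
        nx = self.grid_shape[0]
        n_air = int(round(self.air_fraction * nx))
        for les in self.lesions:
            lo = np.asarray(les.center) - np.asarray(les.semi_axes)
            hi = np.asarray(les.center) + np.asarray(les.semi_axes)
            if np.any(lo < 0) or np.any(hi > np.asarray(self.grid_shape) - 1):
                raise ValueError(f"lesion at {les.center} extends outside the grid")
            if les.center[0] - les.semi_axes[0] < n_air:
                raise ValueError("lesion overlaps the air slab")


@dataclass
class PhantomMaps:
    """Per-voxel ground-truth maps (D, β, µ, S0) plus a label mask."""

    D: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    s0: np.ndarray
    labels: np.ndarray
    voxel_size: tuple = (0.9, 0.9, 4.0)

    @property
    def shape(self):
        return self.D.shape


@dataclass
class DwiSeries:
    """A 4-D magnitude stack (x, y, z, b-index) tied to its protocol."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size: tuple = (0.9, 0.9, 4.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, b)")
        if self.data.shape[3] != len(self.protocol):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must match the number "
                f"of b-values ({len(self.protocol)})"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def shape(self):
        return self.data.shape


def generate_parameter_maps(spec: PhantomSpec) -> PhantomMaps:
    """Rasterize a phantom spec into voxel-wise ground-truth maps.

    The air slab occupies the low-x face of the grid; lesion labels start at
    2 and later lesions overwrite earlier ones (with a logged warning).
    """
    shape = tuple(spec.grid_shape)
    nx = shape[0]
    n_air = int(round(spec.air_fraction * nx))

    D = np.full(shape, spec.background.D)
    beta = np.full(shape, spec.background.beta)
    mu = np.full(shape, spec.background.mu)
    s0 = np.full(shape, spec.background_s0)
    labels = np.full(shape, LABEL_TISSUE, dtype=np.int32)

    labels[:n_air] = LABEL_AIR
    s0[:n_air] = 0.0

    idx = np.indices(shape, dtype=float)
    for k, les in enumerate(spec.lesions):
        c = np.asarray(les.center, dtype=float)
        a = np.asarray(les.semi_axes, dtype=float)
        r2 = sum(((idx[d] - c[d]) / a[d]) ** 2 for d in range(3))
        inside = r2 <= 1.0
        if np.any(labels[inside] >= LABEL_LESION_START):
            logger.warning("lesion %d overlaps an earlier lesion; later lesion wins", k)
        D[inside] = les.params.D
        beta[inside] = les.params.beta
        mu[inside] = les.params.mu
        s0[inside] = les.s0
        labels[inside] = LABEL_LESION_START + k

    return PhantomMaps(D=D, beta=beta, mu=mu, s0=s0, labels=labels,
                       voxel_size=tuple(spec.voxel_size))


def _rician_mean_of_averages(noiseless, n_avg, sigma, rng):
    """Mean of ``n_avg`` independent Rician magnitude draws per voxel."""
    if sigma == 0:
        return noiseless.copy()
    acc = np.zeros_like(noiseless)
    for _ in range(n_avg):
        re = noiseless + rng.normal(0.0, sigma, size=noiseless.shape)
        im = rng.normal(0.0, sigma, size=noiseless.shape)
        acc += np.hypot(re, im)
    return acc / n_avg


def simulate_dwi_series(maps: PhantomMaps, protocol: AcquisitionProtocol,
                        noise_sigma: float, seed: int) -> DwiSeries:
    """Forward-simulate the 4-D magnitude series from ground-truth maps.

    Each voxel/b entry is the mean of ``n_averages(b)`` independent Rician
    draws around the noiseless FROC signal ``S0 · froc_signal(b)``; with
    ``noise_sigma = 0`` the forward model is reproduced exactly.
    """
    rng = np.random.default_rng(seed)
    shape = maps.shape
    out = np.empty(shape + (len(protocol),))

    # Vectorized over voxels: group by unique parameter triples (a phantom
    # has only a handful) to avoid per-voxel exponent evaluation.
    triples = np.stack([maps.D.ravel(), maps.beta.ravel(), maps.mu.ravel()], axis=1)
    uniq, inv = np.unique(triples, axis=0, return_inverse=True)
    b_arr = np.asarray(protocol.b_values)
    decay = np.empty((len(uniq), len(protocol)))
    for i, (d, be, m) in enumerate(uniq):
        decay[i] = froc_signal(FrocParams(D=d, beta=be, mu=m), b_arr, protocol)
    noiseless4 = (maps.s0.ravel()[:, None] * decay[inv]).reshape(shape + (len(protocol),))

    for j, n_avg in enumerate(protocol.n_averages):
        out[..., j] = _rician_mean_of_averages(noiseless4[..., j], n_avg, noise_sigma, rng)
    return DwiSeries(data=out, protocol=protocol, voxel_size=maps.voxel_size)


def simulate_phantom(spec: PhantomSpec, protocol: AcquisitionProtocol):
    """Convenience: maps + series in one call. Returns ``(maps, series)``."""
    maps = generate_parameter_maps(spec)
    series = simulate_dwi_series(maps, protocol, spec.noise_sigma, spec.seed)
    return maps, series


@dataclass
class CohortSpec:
    """Sampling design of a two-group, two-sequence lesion cohort.

    ``moments[group][sequence][param] = (mean, sd)``; draws outside the
    parameter domain are re-drawn (truncation), and the two sequences of one
    lesion share a latent Gaussian with correlation
    ``sequence_correlation[param]``.
    """

    n_benign: int = 73
    n_malignant: int = 105
    moments: dict = field(default_factory=lambda: TABLE_COHORT_MOMENTS)
    sequence_correlation: dict = field(
        default_factory=lambda: dict(DEFAULT_SEQUENCE_CORRELATION))
    seed: int = 0

    def __post_init__(self):
        if self.n_benign <= 0 or self.n_malignant <= 0:
            raise ValueError("group sizes must be positive")
        for group in self.moments.values():
            for seq in group.values():
                for p, (m, s) in seq.items():
                    if s < 0:
                        raise ValueError(f"SD for {p} must be non-negative")


def _correlated_truncated_pair(rng, n, m1, s1, m2, s2, rho, lo, hi, max_iter=1000):
    """n paired truncated-normal draws with latent correlation rho."""
    w = np.sqrt(rho)
    v = np.sqrt(1.0 - rho)

    def draw(k):
        z = rng.standard_normal((3, k))
        x1 = m1 + s1 * (w * z[0] + v * z[1])
        x2 = m2 + s2 * (w * z[0] + v * z[2])
        return x1, x2

    x1, x2 = draw(n)
    for _ in range(max_iter):
        bad = (x1 < lo) | (x1 > hi) | (x2 < lo) | (x2 > hi)
        if not bad.any():
            break
        r1, r2 = draw(int(bad.sum()))
        x1[bad], x2[bad] = r1, r2
    else:  # pragma: no cover - absurd truncation region
        raise RuntimeError("truncated sampling did not converge")
    return x1, x2


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format lesion cohort table.

    Returns a DataFrame with columns ``lesion_id, group, sequence, D, beta,
    mu, adc`` — two rows (SSEPI, SMS) per lesion.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for group, n in (("benign", spec.n_benign), ("malignant", spec.n_malignant)):
        cols = {"SSEPI": {}, "SMS": {}}
        for param in ("D", "beta", "mu", "adc"):
            m1, s1 = spec.moments[group]["SSEPI"][param]
            m2, s2 = spec.moments[group]["SMS"][param]
            rho = spec.sequence_correlation.get(param, 0.9)
            lo, hi = PARAM_DOMAINS[param]
            if s1 == 0 and s2 == 0:
                x1, x2 = np.full(n, m1), np.full(n, m2)
            else:
                x1, x2 = _correlated_truncated_pair(rng, n, m1, s1, m2, s2, rho, lo, hi)
            cols["SSEPI"][param] = x1
            cols["SMS"][param] = x2
        ids = np.arange(offset, offset + n)
        for seq in ("SSEPI", "SMS"):
            frames.append(pd.DataFrame({
                "lesion_id": ids, "group": group, "sequence": seq,
                **{p: cols[seq][p] for p in ("D", "beta", "mu", "adc")},
            }))
        offset += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# File I/O: NIfTI volumes + b-value / timing sidecars, CSV cohorts
# ---------------------------------------------------------------------------

def _affine(voxel_size):
    return np.diag(list(voxel_size) + [1.0])


def write_series(series: DwiSeries, stem) -> None:
    """Write ``<stem>.nii.gz`` + ``<stem>.bval`` + ``<stem>_timing.yaml``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    nib.save(img, str(stem) + ".nii.gz")
    with open(str(stem) + ".bval", "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in series.protocol.b_values) + "\n")
    with open(str(stem) + "_timing.yaml", "w") as fh:
        yaml.safe_dump({
            "delta": series.protocol.delta,
            "big_delta": series.protocol.big_delta,
            "n_averages": list(series.protocol.n_averages),
        }, fh, sort_keys=False)


def read_series(stem) -> DwiSeries:
    """Inverse of :func:`write_series`; validates volume/b-count consistency."""
    stem = Path(stem)
    img = nib.load(str(stem) + ".nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    with open(str(stem) + ".bval") as fh:
        b_values = [float(tok) for tok in fh.read().split()]
    with open(str(stem) + "_timing.yaml") as fh:
        timing = yaml.safe_load(fh)
    if data.ndim != 4 or data.shape[3] != len(b_values):
        raise ValueError(
            f"NIfTI has {data.shape[3] if data.ndim == 4 else 'non-4D'} volumes "
            f"but the sidecar lists {len(b_values)} b-values"
        )
    protocol = AcquisitionProtocol(
        b_values=b_values, n_averages=timing["n_averages"],
        delta=timing["delta"], big_delta=timing["big_delta"],
    )
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    # Magnitude data cannot be negative; clip float32 round-off at zero.
    return DwiSeries(data=np.clip(data, 0, None), protocol=protocol, voxel_size=voxel_size)


def write_mask(mask: np.ndarray, path, voxel_size=(0.9, 0.9, 4.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask).astype(np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def read_mask(path, expected_shape=None) -> np.ndarray:
    mask = np.asarray(nib.load(str(path)).dataobj)
    if expected_shape is not None and tuple(mask.shape) != tuple(expected_shape):
        raise ValueError(f"mask shape {mask.shape} does not match grid {tuple(expected_shape)}")
    return mask


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lesion_id", "group", "sequence", "D", "beta", "mu", "adc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
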