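"""Signal-to-noise and contrast-to-noise ratios of DWI regions of interest.

Definitions (computed per b-value on magnitude images):

* ``SNR = S_lesion / σ_background`` — mean lesion-ROI intensity over the SD
  of a signal-free air region;
* ``CNR = (S_lesion − S_tissue) / sqrt(σ_lesion² + σ_tissue²)`` — lesion vs
  normal-tissue contrast over the pooled ROI noise.

All SDs are sample SDs (n − 1 denominator).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import DwiSeries

__all__ = ["RoiSample", "snr", "cnr", "roi_sample_from_series", "series_quality_table"]


@dataclass(frozen=True)
class RoiSample:
    """ROI summary statistics entering the SNR/CNR formulas."""

    S_lesion: float
    sigma_lesion: float
    S_tissue: float
    sigma_tissue: float
    sigma_background: float

    def __post_init__(self):
        if min(self.sigma_lesion, self.sigma_tissue, self.sigma_background) < 0:
            raise ValueError("standard deviations must be non-negative")


def snr(sample: RoiSample) -> float:
    """Lesion SNR; requires a strictly positive air-background SD."""
    if sample.sigma_background <= 0:
        raise ValueError("background SD must be positive for SNR")
    return sample.S_lesion / sample.sigma_background


def cnr(sample: RoiSample) -> float:
    """Lesion-vs-tissue CNR; undefined when both ROI SDs are zero."""
    denom = np.hypot(sample.sigma_lesion, sample.sigma_tissue)
    if denom == 0:
        raise ValueError("lesion and tissue SDs cannot both be zero for CNR")
    return (sample.S_lesion - sample.S_tissue) / denom


def roi_sample_from_series(series: DwiSeries, b_index: int, lesion_mask,
                           tissue_mask, background_mask) -> RoiSample:
    """Measure ROI statistics on the b-th volume of a series."""
    vol = series.data[..., b_index]

    def stats(mask):
        vals = vol[np.asarray(mask).astype(bool)]
        if vals.size == 0:
            raise ValueError("ROI is empty")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd

    s_les, sd_les = stats(lesion_mask)
    s_tis, sd_tis = stats(tissue_mask)
    _, sd_bg = stats(background_mask)
    return RoiSample(S_lesion=s_les, sigma_lesion=sd_les, S_tissue=s_tis,
                     sigma_tissue=sd_tis, sigma_background=sd_bg)


def series_quality_table(series: DwiSeries, lesion_mask, tissue_mask,
                         background_mask) -> pd.DataFrame:
    """Per-b-value SNR/CNR table (columns: b, snr, cnr)."""
    rows = []
    for j, b in enumerate(series.protocol.b_values):
        sample = roi_sample_from_series(series, j, lesion_mask, tissue_mask,
                                        background_mask)
        rows.append({"b": b, "snr": snr(sample), "cnr": cnr(sample)})
    return pd.DataFrame(rows)
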