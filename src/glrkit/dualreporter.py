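"""Surface vs total receptor quantification from paired SEP/mCherry images.

SEP (superecliptic pHluorin) is quenched in acidic endosomes and reports
the cell-surface receptor pool; mCherry is pH-insensitive and reports the
total pool.  Over a shared ROI the thresholded integrated densities of
the two channels give a SEP/mCherry ratio that is a proxy for the surface
fraction.  The module covers threshold calibration from control images,
integrated densities, control normalization of ratios, unthresholded soma
totals, and a model-based inversion of the ratio to a surface-fraction
estimate ``f_hat``.

Forward model (per pixel, above background)::

    mCherry = total
    SEP     = total * (f_surf + (1 - f_surf) * (1 - q))

where ``q`` is the quench efficiency of SEP in acidic compartments
(q = 1: internal SEP fully dark).  Hence ratio = f + (1 - f)(1 - q) and
``f_hat = (ratio/cal - (1 - q)) / q`` with ``cal`` the relative
SEP:mCherry brightness scale (1 for synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, NonIdentifiableError
from .puncta import sigma_clipped_stats

__all__ = [
    "ChannelImage",
    "Roi",
    "ThresholdSet",
    "DualChannelQuant",
    "calibrate_thresholds",
    "integrated_density",
    "quantify_pair",
    "normalize_to_control",
    "estimate_surface_fraction",
    "soma_total",
]


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel 2-D image with acquisition metadata."""

    pixels: np.ndarray
    channel: str  # "SEP" or "mCherry"
    acquisition_day: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ConfigurationError("image must be 2-D")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ConfigurationError("pixels must be finite and non-negative")

    @classmethod
    def from_tiff(cls, path, channel: str, acquisition_day: str | None = None) -> "ChannelImage":
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ConfigurationError(f"{path}: expected a single-plane grayscale TIFF")
        return cls(arr.astype(float), channel, acquisition_day)


@dataclass(frozen=True)
class Roi:
    """A region of interest: a rectangle (0-based, half-open) or a pixel mask."""

    rect: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)
    mask_pixels: np.ndarray | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if (self.rect is None) == (self.mask_pixels is None):
            raise ConfigurationError("Roi needs exactly one of rect or mask_pixels")
        if self.mask_pixels is not None:
            m = np.asarray(self.mask_pixels, dtype=bool)
            if m.shape != shape:
                raise ConfigurationError("mask shape does not match image shape")
        else:
            r0, r1, c0, c1 = self.rect
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ConfigurationError("rectangle out of image bounds or empty")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
        if not m.any():
            raise ConfigurationError("ROI is empty")
        return m


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel background thresholds derived from control images."""

    t_sep: float
    t_mcherry: float
    source: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.t_sep < 0 or self.t_mcherry < 0:
            raise ConfigurationError("thresholds must be non-negative")

    def for_channel(self, channel: str) -> float:
        return self.t_sep if channel == "SEP" else self.t_mcherry


@dataclass
class DualChannelQuant:
    """Quantification of one SEP/mCherry image pair over a shared ROI."""

    sep_intden: float
    mch_intden: float
    ratio: float  # NaN when mch_intden == 0 (undefined-ratio flag)
    ratio_norm: float | None = None
    f_hat: float | None = None
    f_hat_clamped: bool = False

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


def calibrate_thresholds(control_pairs: Sequence[tuple[ChannelImage, ChannelImage]],
                         k_sd: float = 4.0) -> ThresholdSet:
    """Average background threshold per channel from control image pairs.

    For each control image the background mean and SD are estimated by the
    same iterative sigma clip used for line scans, applied to the full
    pixel population; the per-image threshold is ``bg_mean + k_sd * bg_sd``
    and the stored channel threshold is the mean over control images.
    Requires at least 3 pairs.
    """
    if len(control_pairs) < 3:
        raise CalibrationError(f"need >= 3 control image pairs, got {len(control_pairs)}")
    per_channel: dict[str, list[float]] = {"SEP": [], "mCherry": []}
    ids: list[str] = []
    for i, (sep, mch) in enumerate(control_pairs):
        for img in (sep, mch):
            if img.channel not in per_channel:
                raise ConfigurationError(f"unknown channel {img.channel!r}")
            bg_mean, bg_sd, _ = sigma_clipped_stats(img.pixels)
            per_channel[img.channel].append(bg_mean + k_sd * bg_sd)
        ids.append(f"pair{i}" if sep.acquisition_day is None else f"{sep.acquisition_day}:{i}")
    if not per_channel["SEP"] or not per_channel["mCherry"]:
        raise CalibrationError("calibration requires both SEP and mCherry images")
    return ThresholdSet(
        t_sep=float(np.mean(per_channel["SEP"])),
        t_mcherry=float(np.mean(per_channel["mCherry"])),
        source=tuple(ids),
    )


def integrated_density(img: ChannelImage, roi: Roi, threshold: float) -> float:
    """Sum of ROI pixel values strictly above ``threshold`` (AU*px).

    Equivalent to area x mean gray intensity of the supra-threshold pixels
    ("limit to threshold" semantics); 0 when no pixel passes.
    """
    m = roi.mask(img.pixels.shape)
    vals = img.pixels[m]
    return float(vals[vals > threshold].sum())


def quantify_pair(sep: ChannelImage, mch: ChannelImage, roi: Roi,
                  thresholds: ThresholdSet) -> DualChannelQuant:
    """Integrated densities of both channels over one shared ROI and their ratio."""
    if sep.pixels.shape != mch.pixels.shape:
        raise ConfigurationError("paired images must share shape")
    s = integrated_density(sep, roi, thresholds.for_channel("SEP"))
    m = integrated_density(mch, roi, thresholds.for_channel("mCherry"))
    ratio = s / m if m > 0 else float("nan")
    return DualChannelQuant(sep_intden=s, mch_intden=m, ratio=ratio)


def normalize_to_control(samples: pd.DataFrame, control_label: str,
                         by_day: bool = True) -> pd.DataFrame:
    """Divide each ratio by the control-group mean of its batch.

    ``samples`` needs columns ``genotype`` and ``ratio``; an optional
    ``day`` column defines batches.  With ``by_day=True`` and a day column
    present, each sample is normalized to the control mean of its own day
    (mirroring same-day control imaging); otherwise the global control
    mean is used.  Returns a copy with a ``ratio_norm`` column; the
    control group mean of ``ratio_norm`` is 1 by construction.
    """
    df = samples.copy()
    if "genotype" not in df.columns or "ratio" not in df.columns:
        raise ConfigurationError("samples need 'genotype' and 'ratio' columns")
    if control_label not in set(df["genotype"]):
        raise ConfigurationError(f"no control samples labelled {control_label!r}")

    def _norm(group: pd.DataFrame) -> pd.Series:
        ctrl = group.loc[group["genotype"] == control_label, "ratio"]
        if ctrl.empty:
            raise ConfigurationError("a batch lacks control samples")
        mean = ctrl.mean()
        if mean == 0 or not np.isfinite(mean):
            raise ConfigurationError("control mean ratio is zero or undefined")
        return group["ratio"] / mean

    if by_day and "day" in df.columns:
        df["ratio_norm"] = (
            df.groupby("day", group_keys=False)[["genotype", "ratio"]].apply(_norm)
        )
    else:
        df["ratio_norm"] = _norm(df)
    return df


def estimate_surface_fraction(ratio: float, q: float = 1.0,
                              cal: float = 1.0) -> tuple[float, bool]:
    """Invert the quenching model to a surface-fraction estimate.

    Solves ``ratio/cal = f + (1 - f)(1 - q)`` for ``f``; the estimate is
    clamped to [0, 1] (noise can push it slightly outside) and the second
    return value flags clamping.  ``q = 0`` makes the SEP channel carry no
    surface information and is rejected.
    """
    if q <= 0 or q > 1:
        raise NonIdentifiableError("quench efficiency q must be in (0, 1]")
    if cal <= 0:
        raise ConfigurationError("cal must be positive")
    f = (ratio / cal - (1.0 - q)) / q
    clamped = f < 0 or f > 1
    return float(min(max(f, 0.0), 1.0)), clamped


def soma_total(img: ChannelImage, roi: Roi) -> tuple[int, float]:
    """Unthresholded ROI area (px) and integrated density (AU*px).

    Intended for maximum-projected soma images, where the ROI is drawn
    around the whole cell body and no background threshold is applied.
    """
    m = roi.mask(img.pixels.shape)
    return int(m.sum()), float(img.pixels[m].sum())
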