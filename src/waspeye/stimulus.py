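"""Stimulus geometry shared by the synthetic generator and the analysis.

A receptive-field raster scan drifts a small dark square (Weber contrast
close to -1) through a square region of interest (ROI) centred on the
receptive field, line by line; bar sweeps drag a long dark bar across the
screen along the four cardinal directions to localize the field first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusSpec"]


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus parameters for bar sweeps and raster scans.

    Angles are in degrees of visual angle on the stimulus screen, speeds in
    deg/s, times in seconds.

    Parameters
    ----------
    bar_size : tuple of float
        (width, length) of the localization bar.  The long dimension spans
        the screen so the bar always crosses the receptive field.
    bar_speed : float
        Sweep speed of the localization bar.
    target_size : float
        Side of the square raster target.  1.5 or 2.0 deg for frontal
        recordings, 3.0 deg for lateral ones.
    target_contrast : float
        Weber contrast (I_target - I_bg)/I_bg of the dark target; carried
        as metadata, the analysis itself operates on voltages.
    drift_speed : float
        Drift speed of the raster target within the ROI.
    roi_size : float
        Side of the square region of interest.
    n_lines : int
        Number of raster lines covering the ROI.
    line_spacing : float or None
        Spacing between raster lines; ``None`` means ``roi_size/(n_lines-1)``
        (0.1 deg with the defaults).
    pre_stimulus : float
        Baseline recording window preceding each sweep/line.
    sample_rate : float or None
        Voltage sampling rate, Hz.  ``None`` means one sample per raster
        cell, ``drift_speed/line_spacing`` (480 Hz with the defaults).
    sweep_span : float
        Angular extent travelled by the localization bar, centred on the
        screen centre.
    """

    bar_size: tuple[float, float] = (5.0, 144.0)
    bar_speed: float = 96.0
    target_size: float = 2.0
    target_contrast: float = -0.998
    drift_speed: float = 48.0
    roi_size: float = 6.0
    n_lines: int = 61
    line_spacing: float | None = None
    pre_stimulus: float = 0.5
    sample_rate: float | None = None
    sweep_span: float = 100.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.target_contrast < 0.0):
            raise ValueError(
                f"target_contrast must lie in [-1, 0), got {self.target_contrast}")
        if self.n_lines < 2:
            raise ValueError(f"n_lines must be >= 2, got {self.n_lines}")
        if self.target_size <= 0:
            raise ValueError(f"target_size must be positive, got {self.target_size}")
        if self.roi_size <= self.target_size:
            raise ValueError(
                f"roi_size ({self.roi_size}) must exceed target_size "
                f"({self.target_size})")
        if self.bar_speed <= 0:
            raise ValueError(f"bar_speed must be positive, got {self.bar_speed}")
        if self.drift_speed <= 0:
            raise ValueError(f"drift_speed must be positive, got {self.drift_speed}")
        if self.pre_stimulus < 0:
            raise ValueError(f"pre_stimulus must be >= 0, got {self.pre_stimulus}")
        if self.line_spacing is not None and self.line_spacing <= 0:
            raise ValueError(f"line_spacing must be positive, got {self.line_spacing}")
        if self.sample_rate is not None and self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.sweep_span <= 0:
            raise ValueError(f"sweep_span must be positive, got {self.sweep_span}")

    @property
    def spacing(self) -> float:
        """Raster grid spacing in degrees."""
        if self.line_spacing is not None:
            return self.line_spacing
        return self.roi_size / (self.n_lines - 1)

    @property
    def rate(self) -> float:
        """Effective sampling rate in Hz."""
        if self.sample_rate is not None:
            return self.sample_rate
        return self.drift_speed / self.spacing

    def offsets(self) -> np.ndarray:
        """Angular offsets of the raster grid relative to the ROI centre.

        The square ROI is sampled identically on both axes: ``n_lines``
        positions spaced by :attr:`spacing`, symmetric about zero.
        """
        idx = np.arange(self.n_lines, dtype=float)
        return (idx - (self.n_lines - 1) / 2.0) * self.spacing

    def to_dict(self) -> dict:
        return {
            "bar_size": list(self.bar_size),
            "bar_speed": self.bar_speed,
            "target_size": self.target_size,
            "target_contrast": self.target_contrast,
            "drift_speed": self.drift_speed,
            "roi_size": self.roi_size,
            "n_lines": self.n_lines,
            "line_spacing": self.line_spacing,
            "pre_stimulus": self.pre_stimulus,
            "sample_rate": self.sample_rate,
            "sweep_span": self.sweep_span,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        if "bar_size" in d:
            d["bar_size"] = tuple(d["bar_size"])
        return cls(**d)
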