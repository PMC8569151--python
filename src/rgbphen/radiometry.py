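"""Panel-based exponential DN-to-reflectance calibration.

The calibration model is ``reflectance = a * b**DN``; fitting is by ordinary
least squares on the log scale, ``ln(reflectance) = ln(a) + DN * ln(b)``,
which is closed-form and deterministic.  Calibrated reflectance may exceed 1
at high DN; values are never clamped (a warning is emitted instead).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BANDS",
    "PanelObservation",
    "ExponentialCalibration",
    "CalibrationSet",
    "fit_panel_calibration",
    "fit_calibration_set",
    "builtin_calibrations",
    "read_panel_csv",
    "write_calibration_json",
    "read_calibration_json",
]

BANDS = ("red", "green", "blue")


@dataclass(frozen=True)
class PanelObservation:
    """One panel shade seen in one band: its mean DN and its known reflectance."""

    shade: int
    band: str
    dn: float
    reflectance: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.dn < 0:
            raise ValueError("DN must be >= 0")
        if self.reflectance <= 0:
            raise ValueError("panel reflectance must be > 0")


@dataclass(frozen=True)
class ExponentialCalibration:
    """Per-band model reflectance = scale_a * base_b ** DN."""

    band: str
    scale_a: float
    base_b: float

    def __post_init__(self) -> None:
        if self.scale_a <= 0:
            raise ValueError("scale_a must be > 0")
        if self.base_b <= 0:
            raise ValueError("base_b must be > 0")

    def apply(self, dn) -> float | np.ndarray:
        """Reflectance at the given DN (scalar or array)."""
        dn = np.asarray(dn, dtype=float)
        if np.any(dn < 0):
            raise ValueError("DN must be >= 0")
        refl = self.scale_a * self.base_b**dn
        if np.any(refl > 1.0):
            warnings.warn(
                f"{self.band}: calibrated reflectance exceeds 1 (max "
                f"{float(np.max(refl)):.4f}); values reported unclamped",
                stacklevel=2,
            )
        return float(refl) if refl.ndim == 0 else refl

    def invert(self, reflectance) -> float | np.ndarray:
        """Real-valued DN at which the model produces the given reflectance."""
        refl = np.asarray(reflectance, dtype=float)
        if np.any(refl <= 0):
            raise ValueError("reflectance must be > 0")
        if self.base_b == 1.0:
            raise ValueError("base_b = 1: calibration is constant, not invertible")
        dn = np.log(refl / self.scale_a) / np.log(self.base_b)
        return float(dn) if dn.ndim == 0 else dn


def apply_calibration(dn, cal: ExponentialCalibration):
    return cal.apply(dn)


def invert_calibration(reflectance, cal: ExponentialCalibration):
    return cal.invert(reflectance)


@dataclass(frozen=True)
class CalibrationSet:
    red: ExponentialCalibration
    green: ExponentialCalibration
    blue: ExponentialCalibration
    label: str = ""

    def __getitem__(self, band: str) -> ExponentialCalibration:
        if band not in BANDS:
            raise KeyError(band)
        return getattr(self, band)

    def bands(self) -> dict[str, ExponentialCalibration]:
        return {b: getattr(self, b) for b in BANDS}


# Published per-campaign calibrations (scale a, base b) per band.
_BUILTIN: dict[str, dict[str, tuple[float, float]]] = {
    "2017": {
        "red": (0.1263, 1.0091),
        "green": (0.1263, 1.0087),
        "blue": (0.1144, 1.0087),
    },
    "2019": {
        "red": (0.0212, 1.0169),
        "green": (0.0211, 1.0165),
        "blue": (0.0167, 1.0167),
    },
}


def builtin_calibrations(campaign: str) -> CalibrationSet:
    """The published calibration set for a campaign label ("2017" or "2019")."""
    try:
        pairs = _BUILTIN[str(campaign)]
    except KeyError:
        raise KeyError(
            f"unknown campaign {campaign!r}; known: {sorted(_BUILTIN)}"
        ) from None
    cals = {
        band: ExponentialCalibration(band, a, b) for band, (a, b) in pairs.items()
    }
    return CalibrationSet(label=str(campaign), **cals)


def fit_panel_calibration(
    observations: Iterable[PanelObservation],
) -> ExponentialCalibration:
    """Fit (a, b) by log-linear least squares on one band's panel points."""
    obs = list(observations)
    if len(obs) < 3:
        raise ValueError("need at least 3 panel observations")
    bands = {o.band for o in obs}
    if len(bands) != 1:
        raise ValueError(f"observations mix bands: {sorted(bands)}")
    dn = np.array([o.dn for o in obs], dtype=float)
    refl = np.array([o.reflectance for o in obs], dtype=float)
    if np.ptp(dn) == 0:
        raise ValueError("zero DN variance: cannot fit a slope")
    X = np.column_stack([np.ones_like(dn), dn])
    coef, *_ = np.linalg.lstsq(X, np.log(refl), rcond=None)
    return ExponentialCalibration(
        band=obs[0].band, scale_a=float(np.exp(coef[0])), base_b=float(np.exp(coef[1]))
    )


def fit_calibration_set(
    observations: Iterable[PanelObservation], label: str = ""
) -> CalibrationSet:
    obs = list(observations)
    cals = {}
    for band in BANDS:
        band_obs = [o for o in obs if o.band == band]
        cals[band] = fit_panel_calibration(band_obs)
    return CalibrationSet(label=label, **cals)


# ---------------------------------------------------------------------------
# I/O: panel CSV (shade,band,dn,reflectance) and calibration JSON


def read_panel_csv(path: str | Path) -> list[PanelObservation]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"shade", "band", "dn", "reflectance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return [
        PanelObservation(
            shade=int(r.shade), band=str(r.band),
            dn=float(r.dn), reflectance=float(r.reflectance),
        )
        for r in df.itertuples()
    ]


def write_calibration_json(cal_set: CalibrationSet, path: str | Path) -> None:
    out = {
        "label": cal_set.label,
        **{
            band: {"scale_a": c.scale_a, "base_b": c.base_b}
            for band, c in cal_set.bands().items()
        },
    }
    Path(path).write_text(json.dumps(out, indent=2))


def read_calibration_json(path: str | Path) -> CalibrationSet:
    data = json.loads(Path(path).read_text())
    cals = {
        band: ExponentialCalibration(
            band, float(data[band]["scale_a"]), float(data[band]["base_b"])
        )
        for band in BANDS
    }
    return CalibrationSet(label=str(data.get("label", "")), **cals)
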