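"""The six RGB vegetation indices computed from plot reflectance triples.

BGI   = blue / green
RGR   = red / green
NPPR  = green / (red + blue)
NGRDI = (green - red) / (green + red)
PPR   = (green - blue) / (green + blue)
NCPI  = (red - blue) / (red + blue)

Indices are computed on plot-averaged reflectance (after two-row averaging),
not per-pixel.  Normalized-difference indices are left unclamped: their
mathematical range is (-1, 1) for strictly positive bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VI_NAMES", "ReflectanceTriple", "VIVector", "compute_vis", "compute_vis_frame"]

VI_NAMES = ("bgi", "rgr", "nppr", "ngrdi", "ppr", "ncpi")


@dataclass(frozen=True)
class ReflectanceTriple:
    red: float
    green: float
    blue: float

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} reflectance must be > 0 (VI denominators)")


@dataclass(frozen=True)
class VIVector:
    bgi: float
    rgr: float
    nppr: float
    ngrdi: float
    ppr: float
    ncpi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in VI_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in VI_NAMES])


def compute_vis(r: ReflectanceTriple) -> VIVector:
    """All six indices for one reflectance triple."""
    red, green, blue = r.red, r.green, r.blue
    denominators = {
        "green": green,
        "red+blue": red + blue,
        "green+red": green + red,
        "green+blue": green + blue,
    }
    zeros = [name for name, d in denominators.items() if d == 0]
    if zeros:
        raise ZeroDivisionError(f"zero VI denominator(s): {zeros}")
    return VIVector(
        bgi=blue / green,
        rgr=red / green,
        nppr=green / (red + blue),
        ngrdi=(green - red) / (green + red),
        ppr=(green - blue) / (green + blue),
        ncpi=(red - blue) / (red + blue),
    )


def compute_vis_frame(df):
    """Vectorized indices for a table with red/green/blue columns.

    Returns a copy with the six VI columns appended; rows with a zero
    denominator raise.
    """
    red = np.asarray(df["red"], dtype=float)
    green = np.asarray(df["green"], dtype=float)
    blue = np.asarray(df["blue"], dtype=float)
    for arr, pair in (
        (green, "green"),
        (red + blue, "red+blue"),
        (green + red, "green+red"),
        (green + blue, "green+blue"),
    ):
        if np.any(arr == 0):
            raise ZeroDivisionError(f"zero VI denominator: {pair}")
    out = df.copy()
    out["bgi"] = blue / green
    out["rgr"] = red / green
    out["nppr"] = green / (red + blue)
    out["ngrdi"] = (green - red) / (green + red)
    out["ppr"] = (green - blue) / (green + blue)
    out["ncpi"] = (red - blue) / (red + blue)
    return out
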