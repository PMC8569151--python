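"""Synthetic field-trial generator: trait tables, model-consistent VI tables,
and rendered orthomosaic-style scenes with a calibration panel.

All generators are deterministic given their seed.  Two presets mirror the
campaign layouts used by the frozen models: "2017" (18 genotypes x 6 reps,
2-row plots, LAI 0.8-2.6, LG 43-75 cm) and "2019" (8 genotypes x 16 reps,
1-row plots, LAI 1.5-5.8, LG 66-111 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .plot_geometry import Affine, BandRaster, Fishnet, PlotPolygon, SceneRaster
from .radiometry import CalibrationSet
from .trait_models import frozen_model
from .vegindices import VI_NAMES, ReflectanceTriple, compute_vis

__all__ = [
    "TrialDesign",
    "SceneConfig",
    "TRIAL_PRESETS",
    "trial_design_preset",
    "generate_trial",
    "validate_ground_truth",
    "generate_vi_table",
    "render_scene",
    "VI_SAMPLING_RANGES",
]


@dataclass(frozen=True)
class TrialDesign:
    """RCBD layout plus target trait ranges for the simulated campaign."""

    genotypes: tuple[str, ...]
    reps: int
    dap_schedule: tuple[int, ...]
    rows_per_plot: int
    lai_range: tuple[float, float]
    lg_range: tuple[float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("need at least 2 replicate blocks")
        if list(self.dap_schedule) != sorted(set(self.dap_schedule)):
            raise ValueError("dap_schedule must be strictly increasing")
        if self.rows_per_plot not in (1, 2):
            raise ValueError("rows_per_plot must be 1 or 2")
        for name, (lo, hi) in (("lai", self.lai_range), ("lg", self.lg_range)):
            if not 0 < lo < hi:
                raise ValueError(f"invalid {name}_range ({lo}, {hi})")


TRIAL_PRESETS: dict[str, dict] = {
    "2017": dict(
        genotypes=tuple(f"G{i:02d}" for i in range(1, 19)),
        reps=6,
        dap_schedule=(30, 35, 40, 45, 50),
        rows_per_plot=2,
        lai_range=(0.8, 2.6),
        lg_range=(43.0, 75.0),
    ),
    "2019": dict(
        genotypes=tuple(f"V{i:02d}" for i in range(1, 9)),
        reps=16,
        dap_schedule=(45, 55, 65, 75),
        rows_per_plot=1,
        lai_range=(1.5, 5.8),
        lg_range=(66.0, 111.0),
    ),
}


def trial_design_preset(campaign: str, seed: int = 0) -> TrialDesign:
    try:
        kwargs = TRIAL_PRESETS[str(campaign)]
    except KeyError:
        raise KeyError(
            f"unknown preset {campaign!r}; known: {sorted(TRIAL_PRESETS)}"
        ) from None
    return TrialDesign(seed=seed, **kwargs)


# default yield link: cubic in mid-season LAI, kg/ha scale
_YIELD_CUBIC = (800.0, 1400.0, 150.0, -12.0)


def generate_trial(
    design: TrialDesign,
    yield_cubic: tuple[float, float, float, float] = _YIELD_CUBIC,
    yield_noise_frac: float = 0.04,
) -> pd.DataFrame:
    """Per plot x DAP ground-truth table.

    Traits follow saturating growth curves anchored at the low end of the
    design's trait range, with genotype, block, and residual plot effects
    scaling the end-of-season maximum; within a plot both traits are
    non-decreasing in DAP.  End-season pod yield is a cubic function of
    mid-season LAI plus multiplicative noise, repeated on each DAP row.

    Columns: plot_id, genotype, rep, dap, lai, lg, pod_yield.
    """
    rng = np.random.default_rng(design.seed)
    daps = np.asarray(design.dap_schedule, dtype=float)
    # growth progress starts off zero so the first date already varies by plot
    progress = 0.15 + 0.85 * (daps - daps[0]) / max(daps[-1] - daps[0], 1.0)
    growth = (1.0 - np.exp(-2.5 * progress)) / (1.0 - np.exp(-2.5))

    geno_frac = {
        g: rng.uniform(0.45, 1.0) for g in design.genotypes
    }
    block_eff = rng.normal(0.0, 0.04, size=design.reps)

    records = []
    mid = len(daps) // 2
    for rep in range(1, design.reps + 1):
        for gi, geno in enumerate(design.genotypes):
            plot_id = f"P{rep:02d}{gi + 1:02d}"
            frac = np.clip(
                geno_frac[geno] + block_eff[rep - 1] + rng.normal(0.0, 0.03),
                0.25,
                1.0,
            )
            lo, hi = design.lai_range
            lai = lo + (lo + (hi - lo) * frac - lo) * growth
            lo_g, hi_g = design.lg_range
            lg = lo_g + (lo_g + (hi_g - lo_g) * frac - lo_g) * growth
            mid_lai = lai[mid]
            c0, c1, c2, c3 = yield_cubic
            base_yield = c0 + c1 * mid_lai + c2 * mid_lai**2 + c3 * mid_lai**3
            pod_yield = max(
                base_yield * (1.0 + rng.normal(0.0, yield_noise_frac)), 0.0
            )
            for dap, l_i, g_i in zip(design.dap_schedule, lai, lg):
                records.append(
                    {
                        "plot_id": plot_id,
                        "genotype": geno,
                        "rep": rep,
                        "dap": int(dap),
                        "lai": float(l_i),
                        "lg": float(g_i),
                        "pod_yield": float(pod_yield),
                    }
                )
    return pd.DataFrame.from_records(records)


def validate_ground_truth(df: pd.DataFrame) -> None:
    required = {"plot_id", "genotype", "rep", "dap", "lai", "lg", "pod_yield"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ground truth missing columns: {sorted(missing)}")
    if (df["lai"] < 0).any() or (df["lg"] < 0).any():
        raise ValueError("traits must be non-negative")
    for pid, sub in df.sort_values("dap").groupby("plot_id"):
        if (np.diff(sub["lai"]) < -1e-12).any() or (np.diff(sub["lg"]) < -1e-12).any():
            raise ValueError(f"plot {pid}: traits must be non-decreasing in DAP")


# ---------------------------------------------------------------------------
# model-consistent VI tables

# plausible per-index sampling ranges (all strictly positive so product-mode
# regressors are well conditioned)
VI_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "bgi": (0.20, 0.95),
    "rgr": (0.20, 0.95),
    "nppr": (0.50, 2.00),
    "ngrdi": (0.02, 0.60),
    "ppr": (0.02, 0.60),
    "ncpi": (0.02, 0.60),
}


def generate_vi_table(
    n_rows: int | pd.DataFrame,
    model_id: str,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent uniform VI draws with the trait computed by a frozen model.

    ``n_rows`` may be a ground-truth table, in which case one VI row is
    generated per table row.  With ``noise_sd`` 0 the table is exactly
    model-consistent; otherwise Gaussian noise is added to the trait.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = len(n_rows) if isinstance(n_rows, pd.DataFrame) else int(n_rows)
    model = frozen_model(model_id)
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in VI_SAMPLING_RANGES.items()}
    )
    trait = model.predict(table)
    if noise_sd > 0:
        trait = trait + rng.normal(0.0, noise_sd, size=n)
    table[model.trait] = trait
    return table


# ---------------------------------------------------------------------------
# scene rendering


@dataclass(frozen=True)
class SceneConfig:
    canopy_reflectance: tuple[float, float, float] = (0.08, 0.18, 0.05)
    soil_reflectance: tuple[float, float, float] = (0.25, 0.22, 0.18)
    extinction_k: float = 0.5
    reflectance_noise_sd: float = 0.0
    gsd: float = 0.05  # m per pixel
    bit_depth: int = 8
    panel_shades: tuple[float, ...] = (
        0.15, 0.19, 0.24, 0.31, 0.40, 0.52, 0.66, 0.85,
    )
    seed: int = 0
    # layout constants (m)
    row_length: float = 2.0
    row_width: float = 0.9
    margin: float = 0.4

    def __post_init__(self) -> None:
        if self.extinction_k <= 0:
            raise ValueError("extinction_k must be > 0")
        if self.reflectance_noise_sd < 0:
            raise ValueError("reflectance_noise_sd must be >= 0")
        if len(self.panel_shades) != 8:
            raise ValueError("panel must have exactly 8 shades")
        canopy = ReflectanceTriple(*self.canopy_reflectance)
        soil = ReflectanceTriple(*self.soil_reflectance)
        if compute_vis(canopy).ppr <= compute_vis(soil).ppr:
            raise ValueError("canopy endmember must have higher PPR than soil")


def _ellipse_mask(cols, rows, cx, cy, rx, ry):
    return ((cols - cx) / rx) ** 2 + ((rows - cy) / ry) ** 2 <= 1.0


def render_scene(
    ground_truth_at_dap: pd.DataFrame,
    config: SceneConfig,
    calibration: CalibrationSet,
    rows_per_plot: int = 1,
) -> tuple[SceneRaster, Fishnet, Fishnet]:
    """Render one measurement date as a DN scene plus fishnets.

    Each plot row is drawn as an ellipse whose lateral (across-row) extent is
    proportional to LG; inside the ellipse each pixel is canopy with
    probability 1 - exp(-k * LAI) and soil otherwise.  Endmember reflectance
    gets optional Gaussian noise, then is inverted through the calibration
    and quantized to DN (round, clip to the bit-depth range).  The 8-shade
    panel is rendered as neutral patches along the left edge.

    Returns (scene, plot fishnet, panel fishnet).  Multi-row plots get one
    polygon per row, with the parent plot id in the ``parent`` property.
    """
    df = ground_truth_at_dap
    if df["plot_id"].duplicated().any():
        raise ValueError("expected one row per plot (a single DAP slice)")
    min_scale = min(c.scale_a for c in calibration.bands().values())
    if min(config.panel_shades) < min_scale:
        raise ValueError("panel shade reflectance below calibration range")

    gsd = config.gsd
    n_plots = len(df)
    n_cols_plots = int(np.ceil(np.sqrt(n_plots)))
    n_rows_plots = int(np.ceil(n_plots / n_cols_plots))
    cell_w = rows_per_plot * config.row_width + config.margin
    cell_h = config.row_length + config.margin
    panel_w = 1.0  # m strip at the left for the calibration panel
    width_m = panel_w + config.margin + n_cols_plots * cell_w + config.margin
    height_m = max(n_rows_plots * cell_h + config.margin, 8 * 0.6 + config.margin)
    ncols = int(np.ceil(width_m / gsd))
    nrows = int(np.ceil(height_m / gsd))

    rng = np.random.default_rng(config.seed)
    soil = np.asarray(config.soil_reflectance)
    canopy = np.asarray(config.canopy_reflectance)

    # start from soil everywhere
    refl = np.empty((nrows, ncols, 3), dtype=float)
    refl[:] = soil

    cols_grid, rows_grid = np.meshgrid(np.arange(ncols), np.arange(nrows))

    plot_polys: list[PlotPolygon] = []
    for idx, rec in enumerate(df.itertuples()):
        ci, ri = idx % n_cols_plots, idx // n_cols_plots
        cell_x0 = panel_w + config.margin + ci * cell_w
        cell_y0 = config.margin / 2 + ri * cell_h
        frac_canopy = 1.0 - np.exp(-config.extinction_k * rec.lai)
        # lateral extent: LG (cm, both sides summed) -> canopy width in m
        canopy_width = min(rec.lg / 100.0, config.row_width * 0.98)
        for row_i in range(1, rows_per_plot + 1):
            row_x0 = cell_x0 + (row_i - 1) * config.row_width
            cx_m = row_x0 + config.row_width / 2
            cy_m = cell_y0 + config.row_length / 2
            rx_px = max(canopy_width / 2 / gsd, 1.0)
            ry_px = max(config.row_length * 0.45 / gsd, 1.0)
            mask = _ellipse_mask(
                cols_grid, rows_grid, cx_m / gsd, cy_m / gsd, rx_px, ry_px
            )
            canopy_mask = mask & (rng.random((nrows, ncols)) < frac_canopy)
            refl[canopy_mask] = canopy
            pid = rec.plot_id if rows_per_plot == 1 else f"{rec.plot_id}.{row_i}"
            ring = [
                (row_x0, cell_y0),
                (row_x0 + config.row_width, cell_y0),
                (row_x0 + config.row_width, cell_y0 + config.row_length),
                (row_x0, cell_y0 + config.row_length),
                (row_x0, cell_y0),
            ]
            plot_polys.append(
                PlotPolygon(
                    plot_id=pid,
                    genotype=str(rec.genotype),
                    rep=int(rec.rep),
                    ring=ring,
                    row=row_i if rows_per_plot > 1 else None,
                    extra={"parent": rec.plot_id},
                )
            )

    # calibration panel: 8 neutral patches down the left edge
    panel_polys: list[PlotPolygon] = []
    patch = 0.5  # m
    for i, shade in enumerate(config.panel_shades):
        x0, y0 = config.margin / 2, config.margin / 2 + i * (patch + 0.1)
        c0, c1 = int(round(x0 / gsd)), int(round((x0 + patch) / gsd))
        r0, r1 = int(round(y0 / gsd)), int(round((y0 + patch) / gsd))
        refl[r0:r1, c0:c1] = shade
        panel_polys.append(
            PlotPolygon(
                plot_id=f"panel_{i + 1}",
                genotype="panel",
                rep=0,
                ring=[(x0, y0), (x0 + patch, y0), (x0 + patch, y0 + patch),
                      (x0, y0 + patch), (x0, y0)],
                extra={"reflectance": shade},
            )
        )

    if config.reflectance_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.reflectance_noise_sd, size=refl.shape)
        refl = np.maximum(refl, min_scale)  # keep invertible

    dn_max = 2**config.bit_depth - 1
    transform = Affine(gsd, 0.0, gsd / 2, 0.0, gsd, gsd / 2)
    bands = {}
    for i, band in enumerate(("red", "green", "blue")):
        cal = calibration[band]
        dn = np.log(refl[:, :, i] / cal.scale_a) / np.log(cal.base_b)
        dn = np.clip(np.floor(dn + 0.5), 0, dn_max)  # round half up
        bands[band] = BandRaster(dn.astype(np.uint16), config.bit_depth, transform)
    scene = SceneRaster(bands["red"], bands["green"], bands["blue"])
    return scene, Fishnet(plot_polys), Fishnet(panel_polys)
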