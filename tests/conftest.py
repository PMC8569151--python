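import numpy as np
import pytest

from rgbphen.plot_geometry import Affine, BandRaster, Fishnet, PlotPolygon, SceneRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(red, green, blue, bit_depth=8, transform=None):
    transform = transform or Affine.identity()
    return SceneRaster(
        BandRaster(np.asarray(red), bit_depth, transform),
        BandRaster(np.asarray(green), bit_depth, transform),
        BandRaster(np.asarray(blue), bit_depth, transform),
    )


def square_plot(plot_id, x0, y0, size, genotype="G", rep=1, **kw):
    ring = [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size), (x0, y0)]
    return PlotPolygon(plot_id, genotype, rep, ring, **kw)


@pytest.fixture
def constant_scene():
    grid = np.full((10, 10), 100, dtype=float)
    return make_scene(grid, grid, grid)


@pytest.fixture
def unit_fishnet():
    return Fishnet([square_plot("p1", -0.5, -0.5, 5.0)])


@pytest.fixture(scope="session")
def campaign_dir(tmp_path_factory):
    """A rendered 2017-preset campaign written to disk once per session."""
    from rgbphen.plot_geometry import write_fishnet, write_scene
    from rgbphen.radiometry import builtin_calibrations
    from rgbphen.synthetic_data import SceneConfig, generate_trial, render_scene, trial_design_preset

    out = tmp_path_factory.mktemp("campaign")
    design = trial_design_preset("2017", seed=7)
    truth = generate_trial(design)
    slice_df = truth[truth["dap"] == design.dap_schedule[-1]]
    cal = builtin_calibrations("2017")
    scene, fishnet, panel = render_scene(
        slice_df, SceneConfig(seed=7), cal, rows_per_plot=design.rows_per_plot
    )
    write_scene(scene, [out / f"scene_{b}.tif" for b in ("red", "green", "blue")])
    write_fishnet(fishnet, out / "fishnet.geojson")
    slice_df.to_csv(out / "truth.csv", index=False)
    return out


def base_config(campaign_dir, out_dir, **kw):
    from rgbphen.workflow import PipelineConfig

    return PipelineConfig(
        scene_paths=[
            str(campaign_dir / f"scene_{b}.tif") for b in ("red", "green", "blue")
        ],
        fishnet_path=str(campaign_dir / "fishnet.geojson"),
        out_dir=str(out_dir),
        calibration="2017",
        ground_truth_path=str(campaign_dir / "truth.csv"),
        seed=7,
        **kw,
    )
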