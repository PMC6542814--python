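"""Contrast-vs-distance curves, threshold extraction, and the 4-factor sweep."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from photoloc import (
    DISTANCE_GRID_MM,
    Shading,
    SparkModel,
    SweepConfig,
    SynthConfig,
    contrast_curve,
    max_detection_distance,
    run_sweep,
)
from photoloc.geometry import DiscGeometry, solid_angle_point
from conftest import flat


class TestContrastCurve:
    def test_spark_off_gives_zero_curve(self, flat_scenario):
        sc = dataclasses.replace(flat_scenario, spark=SparkModel(0.16, flat(0.0)))
        assert np.all(contrast_curve(sc, "achromatic") == 0)
        assert np.all(contrast_curve(sc, "chromatic") == 0)

    def test_strictly_decreasing_with_distance(self, flat_scenario):
        curve = contrast_curve(flat_scenario, "achromatic")
        assert np.all(np.diff(curve) < 0)

    def test_flat_spectrum_michelson_closed_form(self, flat_scenario):
        """For flat spectra, Michelson at d equals dL/(2 L0 + dL) with
        dL = R_cx * rho * L_dw * Omega_spark(d)/pi and L0 = R_nc*sigma*L_dw."""
        curve = contrast_curve(flat_scenario, "achromatic")
        L0 = 0.05 * 0.2 * 1.0
        for d, got in zip(DISTANCE_GRID_MM, curve):
            omega = solid_angle_point(DiscGeometry(0.16, float(d)))
            dL = 0.3 * 1.34 * omega / np.pi
            assert got == pytest.approx(dL / (2 * L0 + dL), rel=1e-9)

    def test_accepts_sweep_channel_aliases(self, flat_scenario):
        a = contrast_curve(flat_scenario, "achromatic_optimistic")
        b = contrast_curve(flat_scenario, "achromatic")
        assert np.array_equal(a, b)

    def test_unknown_channel_rejected(self, flat_scenario):
        with pytest.raises(ValueError, match="channel"):
            contrast_curve(flat_scenario, "ultraviolet")


class TestMaxDetectionDistance:
    def test_all_below_threshold_is_none(self):
        curve = np.full(DISTANCE_GRID_MM.size, 1e-4)
        assert max_detection_distance(curve, 0.008) is None

    def test_all_above_threshold_saturates_at_grid_cap(self):
        curve = np.linspace(0.5, 0.1, DISTANCE_GRID_MM.size)
        assert max_detection_distance(curve, 0.008) == 45

    def test_crossing_between_grid_points(self):
        # contrast 0.009 at 20 mm, 0.007 at 21 mm, threshold 0.008 -> 20 mm
        curve = 0.008 + (20.5 - DISTANCE_GRID_MM.astype(float)) * 0.001
        curve = np.clip(curve, 1e-6, None)
        assert max_detection_distance(curve, 0.008) == 20

    def test_nonmonotone_curve_warns_and_scans_from_far_end(self):
        curve = np.full(DISTANCE_GRID_MM.size, 1e-4)
        curve[5] = 0.05   # isolated bump at 10 mm
        with pytest.warns(UserWarning, match="not monotonically decreasing"):
            assert max_detection_distance(curve, 0.008) == 10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            max_detection_distance(np.ones(3), 0.008)


class TestSweepConfig:
    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="shading_categories"):
            SweepConfig(shading_categories=())

    def test_distance_grid_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[5, 45\]"):
            SweepConfig(distance_grid_mm=(4, 5, 6))

    def test_shading_accepts_names(self):
        cfg = SweepConfig(shading_categories=("none", "strong"))
        assert cfg.shading_categories == (Shading.NONE, Shading.STRONG)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            SweepConfig(channels=("polarisation",))


@pytest.fixture(scope="module")
def small_map():
    cfg = SweepConfig(
        spark_radii_mm=(0.09, 0.17, 0.25),
        spark_radiance_means=(0.63, 1.34, 2.09),
        seed=7,
    )
    return run_sweep(cfg)


class TestRunSweep:

    def test_degenerate_sweep_reduces_to_single_scenario(self):
        from photoloc import build_scenario, scale_spark

        cfg = SweepConfig(
            spark_radii_mm=(0.16,),
            spark_radiance_means=(1.34,),
            ratio_categories=(4.09,),
            shading_categories=(Shading.AVERAGE,),
            channels=("achromatic_optimistic",),
            seed=7,
        )
        dm = run_sweep(cfg)
        assert len(dm.table) == 1
        sc = build_scenario(SynthConfig(seed=7), ratio=4.09, shading=Shading.AVERAGE)
        sc = dataclasses.replace(sc, spark=scale_spark(SparkModel(0.16, sc.spark.rho), 1.34))
        expected = max_detection_distance(contrast_curve(sc, "achromatic"), 0.008)
        got = dm.table.max_distance_mm.iloc[0]
        assert (expected is None and np.isnan(got)) or got == expected

    @staticmethod
    def _dist(df: pd.DataFrame, **cell) -> float:
        sub = df
        for key, val in cell.items():
            sub = sub[sub[key] == val]
        assert len(sub) == 1
        v = sub.max_distance_mm.iloc[0]
        return -np.inf if pd.isna(v) else float(v)

    def test_monotone_along_every_axis(self, small_map):
        """Larger spark, brighter spark, stronger reflector ratio and deeper
        shading each never shrink the detection distance."""
        df = small_map.table[small_map.table.channel == "achromatic_optimistic"]
        radii = sorted(df.spark_radius_mm.unique())
        rads = sorted(df.spark_radiance_mean.unique())
        ratios = sorted(df.ratio.unique())
        shades = ["none", "weak", "average", "strong"]

        def axis_monotone(order, key, fixed):
            prev = -np.inf
            for val in order:
                cur = self._dist(df, **{key: val}, **fixed)
                assert cur >= prev
                prev = cur

        for ratio in ratios:
            for shade in shades:
                axis_monotone(
                    radii, "spark_radius_mm",
                    dict(ratio=ratio, shading=shade, spark_radiance_mean=rads[1]),
                )
                axis_monotone(
                    rads, "spark_radiance_mean",
                    dict(ratio=ratio, shading=shade, spark_radius_mm=radii[1]),
                )
        for r in radii:
            for m in rads:
                axis_monotone(
                    ratios, "ratio",
                    dict(shading="average", spark_radius_mm=r, spark_radiance_mean=m),
                )
                axis_monotone(
                    shades, "shading",
                    dict(ratio=4.09, spark_radius_mm=r, spark_radiance_mean=m),
                )

    def test_optimistic_map_dominates_conservative(self, small_map):
        df = small_map.table
        keys = ["spark_radius_mm", "spark_radiance_mean", "ratio", "shading"]
        opt = df[df.channel == "achromatic_optimistic"].set_index(keys).max_distance_mm
        cons = df[df.channel == "achromatic_conservative"].set_index(keys).max_distance_mm
        o, c = opt.fillna(-np.inf).sort_index(), cons.fillna(-np.inf).sort_index()
        assert np.all(o.values >= c.values)

    def test_chromatic_never_beats_achromatic_optimistic(self, small_map):
        df = small_map.table
        keys = ["spark_radius_mm", "spark_radiance_mean", "ratio", "shading"]
        opt = df[df.channel == "achromatic_optimistic"].set_index(keys).max_distance_mm
        chrom = df[df.channel == "chromatic"].set_index(keys).max_distance_mm
        o = opt.fillna(-np.inf).sort_index()
        c = chrom.fillna(-np.inf).sort_index()
        assert np.all(c.values <= o.values)

    def test_body_control_detection_never_exceeds_five_mm(self):
        cfg = SweepConfig(
            spark_radii_mm=(0.09, 0.25),
            spark_radiance_means=(0.63, 2.09),
            channels=("achromatic_optimistic", "achromatic_conservative"),
            target="body",
            seed=7,
        )
        dm = run_sweep(cfg)
        dist = dm.table.max_distance_mm
        assert np.all(dist.isna() | (dist <= 5))

    def test_deterministic_given_seed(self):
        cfg = SweepConfig(
            spark_radii_mm=(0.16,),
            spark_radiance_means=(1.34,),
            ratio_categories=(4.09,),
            channels=("achromatic_optimistic",),
            seed=3,
        )
        a, b = run_sweep(cfg), run_sweep(cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_pivot_layout(self, small_map):
        wide = small_map.pivot("achromatic_optimistic")
        assert wide.shape == (3 * 4, 3 * 3)

    def test_heatmap_rendering(self, small_map, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from photoloc.plotting import plot_detection_map

        out = tmp_path / "map.png"
        fig = plot_detection_map(small_map, "achromatic_optimistic", out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt

        plt.close(fig)
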