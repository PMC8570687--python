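"""Percent-difference scoring, optimum selection rule, sweep machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brainquant.detect import DetectionParams
from brainquant.masks import MaskParams, detect_tissue
from brainquant.optimize import (
    CLASSIFIER_DSRED,
    CLASSIFIER_GFP,
    DETECTION_THRESHOLD,
    Optimum,
    SweepAnnotation,
    SweepSpec,
    ThresholdSweep,
    percent_difference,
    pooled_region_optimum,
    select_optimum,
)
from brainquant.synthetic import (
    generate_section,
    generate_test_annotations,
    ground_truth_counts,
)
from tests.conftest import small_config, small_tissue_params


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ac, mc, expected",
        [(100, 100, 0.0), (0, 10, -100.0), (120, 100, 20.0), (5, 4, 25.0)],
    )
    def test_worked_examples(self, ac, mc, expected):
        assert percent_difference(ac, mc) == pytest.approx(expected)

    def test_zero_manual_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_difference(3, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        ac=st.integers(0, 10_000),
        mc=st.integers(1, 10_000),
        k=st.integers(1, 100),
    )
    def test_linear_in_ac_and_antisymmetric_about_mc(self, ac, mc, k):
        base = percent_difference(ac, mc)
        assert percent_difference(ac + k, mc) == pytest.approx(base + 100 * k / mc)
        assert percent_difference(2 * mc - ac, mc) == pytest.approx(-base)


def _curve(rows):
    return pd.DataFrame(rows, columns=["value", "mean", "sd"])


class TestSelectOptimum:
    def test_tie_on_abs_mean_broken_by_sd(self):
        opt = select_optimum(_curve([(100, -2, 5), (125, 2, 15)]))
        assert opt.value == 100

    def test_tie_on_sd_prefers_undercounting(self):
        opt = select_optimum(_curve([(150, -1, 4), (175, 1, 4)]))
        assert opt.value == 150

    def test_full_tie_prefers_larger_threshold(self):
        opt = select_optimum(_curve([(200, 0, 0), (225, 0, 0), (250, 0, 0)]))
        assert opt.value == 250

    def test_single_candidate(self):
        assert select_optimum(_curve([(75, -3, 1)])).value == 75

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="scored"):
            select_optimum(_curve([(75, np.nan, np.nan)]))

    def test_ranking_is_returned_for_audit(self):
        opt = select_optimum(_curve([(50, 10, 1), (75, 0, 1), (100, -5, 1)]))
        assert list(opt.ranking["value"]) == [75, 100, 50]


class TestPooledRegionOptimum:
    def test_compromise_between_subregions(self):
        # sub-fields individually optimal at 50 and 100; both near zero at 75
        a = _curve([(50, 0, 1), (75, -1, 1), (100, -30, 1)])
        b = _curve([(50, 30, 1), (75, 1, 1), (100, 0, 1)])
        assert pooled_region_optimum({"dg": a, "ca": b}).value == 75

    def test_identical_curves_reduce_to_plain_selection(self):
        c = _curve([(50, 5, 1), (75, -1, 2), (100, -8, 1)])
        pooled = pooled_region_optimum({"a": c, "b": c.copy()})
        assert pooled.value == select_optimum(c).value

    def test_minimax_matches_brute_force(self):
        rng = np.random.default_rng(0)
        grid = np.arange(50, 301, 25, dtype=float)
        curves = {
            name: _curve(
                [(v, rng.normal(0, 20), rng.uniform(0, 5)) for v in grid]
            )
            for name in ("a", "b", "c")
        }
        best = pooled_region_optimum(curves)
        worst = {
            v: max(abs(c.loc[c["value"] == v, "mean"].iloc[0]) for c in curves.values())
            for v in grid
        }
        assert worst[best.value] == pytest.approx(min(worst.values()))

    def test_mismatched_grids_rejected(self):
        a = _curve([(50, 0, 1)])
        b = _curve([(75, 0, 1)])
        with pytest.raises(ValueError, match="grid"):
            pooled_region_optimum({"a": a, "b": b})


class TestSweepSpec:
    def test_grid_is_inclusive(self):
        spec = SweepSpec(DETECTION_THRESHOLD, 50, 1000, 25)
        assert spec.grid[0] == 50 and spec.grid[-1] == 1000 and len(spec.grid) == 39

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            SweepSpec(DETECTION_THRESHOLD, 50, 100, 0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            SweepSpec("detection.sigma", 1, 2, 1)


@pytest.fixture(scope="module")
def sweep_setup():
    """One small section with tissue mask and ground-truth counts."""
    cfg = small_config(seed=21, large_vessel_count=0)
    img, cells, annots = generate_section(cfg)
    mask = detect_tissue(img, small_tissue_params())
    rects = generate_test_annotations(
        annots, (300, 200), seed=1, pixel_size_um=img.pixel_size_um
    )
    annotations = {}
    for rect in rects:
        annotations[rect.name] = (
            rect,
            ground_truth_counts(cells, rect.to_um(img.pixel_size_um)),
        )
    return img, mask, annotations


class TestRunSweep:
    def test_equal_counts_give_zero_mean_zero_sd(self, sweep_setup):
        """With manual counts set to the automated counts, %difference is
        identically zero across annotations."""
        img, mask, annotations = sweep_setup
        probe = SweepSpec(
            DETECTION_THRESHOLD,
            150,
            150,
            25,
            tuple(
                SweepAnnotation("s", name, rect.geometry, 1)
                for name, (rect, _) in annotations.items()
            ),
        )
        first = ThresholdSweep(probe, {"s": img}, {"s": mask}).fit()
        acs = first.records.set_index("region")["ac"]
        spec = SweepSpec(
            DETECTION_THRESHOLD,
            150,
            150,
            25,
            tuple(
                SweepAnnotation("s", name, rect.geometry, int(acs[name]))
                for name, (rect, _) in annotations.items()
            ),
        )
        res = ThresholdSweep(spec, {"s": img}, {"s": mask}).fit()
        curve = res.curve()
        assert curve["mean"].iloc[0] == pytest.approx(0.0)
        assert curve["sd"].iloc[0] == pytest.approx(0.0)

    def test_detection_curve_has_plateau_and_converges_to_minus_100(
        self, sweep_setup
    ):
        img, mask, annotations = sweep_setup
        spec = SweepSpec(
            DETECTION_THRESHOLD,
            100,
            700,
            100,
            tuple(
                SweepAnnotation("s", name, rect.geometry, counts.total)
                for name, (rect, counts) in annotations.items()
            ),
        )
        curve = ThresholdSweep(spec, {"s": img}, {"s": mask}).fit().curve()
        assert abs(curve["mean"].iloc[0]) < 10  # near zero on the plateau
        assert curve["mean"].iloc[-1] == pytest.approx(-100.0, abs=2)

    def test_classification_sweep_recovers_gap_threshold(self, sweep_setup):
        """The selected GFP threshold separates the configured positive and
        negative intensity distributions and scores ~0 %difference."""
        img, mask, annotations = sweep_setup
        spec = SweepSpec(
            CLASSIFIER_GFP,
            100,
            450,
            25,
            tuple(
                SweepAnnotation("s", name, rect.geometry, counts.gfp)
                for name, (rect, counts) in annotations.items()
                if counts.gfp > 0
            ),
        )
        res = ThresholdSweep(
            spec, {"s": img}, {"s": mask}, DetectionParams(threshold=150)
        ).fit()
        opt = res.select_optimum()
        # below the positive somata's intensity floor, above the grid start
        assert 100 <= opt.value <= 350
        assert abs(opt.mean) < 10
        # and the curve has collapsed towards -100% at the top of the grid
        curve = res.curve()
        assert curve["mean"].iloc[-1] < opt.mean - 25

    def test_annotations_without_manual_counts_are_excluded(self, sweep_setup):
        img, mask, annotations = sweep_setup
        name, (rect, _) = next(iter(annotations.items()))
        spec = SweepSpec(
            CLASSIFIER_DSRED,
            200,
            250,
            25,
            (SweepAnnotation("s", name, rect.geometry, 0),),
        )
        with pytest.warns(UserWarning, match="manual count"):
            res = ThresholdSweep(spec, {"s": img}, {"s": mask}).fit()
        assert res.records.empty
        with pytest.raises(ValueError, match="records"):
            res.curve()

    def test_classification_mean_nonincreasing_in_threshold(self, sweep_setup):
        img, mask, annotations = sweep_setup
        spec = SweepSpec(
            CLASSIFIER_GFP,
            100,
            450,
            50,
            tuple(
                SweepAnnotation("s", name, rect.geometry, max(counts.gfp, 1))
                for name, (rect, counts) in annotations.items()
            ),
        )
        curve = (
            ThresholdSweep(spec, {"s": img}, {"s": mask}, DetectionParams(threshold=150))
            .fit()
            .curve()
        )
        means = curve["mean"].to_numpy()
        assert np.all(np.diff(means) <= 1e-9)

    def test_summary_mentions_regions(self, sweep_setup):
        img, mask, annotations = sweep_setup
        spec = SweepSpec(
            DETECTION_THRESHOLD,
            150,
            200,
            50,
            tuple(
                SweepAnnotation("s", name, rect.geometry, counts.total)
                for name, (rect, counts) in annotations.items()
            ),
        )
        text = ThresholdSweep(spec, {"s": img}, {"s": mask}).fit().summary()
        assert "cortex" in text and "optimum" in text
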