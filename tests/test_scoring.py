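"""Two-channel preprocessing: slopes, normalization, ratios, robust z, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kinscreen import (
    DegenerateDispersionError,
    DegenerateTraceError,
    NormalizationError,
    PlateLayout,
    ScreenDataset,
    UndefinedCorrelationError,
    channel_ratio,
    erod_slope,
    percent_of_neg_controls,
    plate_image_export,
    plate_median_normalize,
    qq_export,
    replicate_correlation,
    robust_z,
    robust_z_scores,
    score_screen,
    simulate_screen,
    summarize_replicates,
)
from kinscreen.scoring import EXCLUDE_LOW_VIABILITY

from conftest import small_config

KAPPA = 1.4826


def brute_median(values):
    """Order-statistic median, independent of numpy."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def brute_robust_z(values, x, kappa=KAPPA):
    med = brute_median(values)
    mad = brute_median([abs(v - med) for v in values])
    return (med - x) / (kappa * mad)


class TestErodSlope:
    def test_exact_line(self):
        assert erod_slope([(0, 100), (5, 150), (10, 200), (15, 250)]) == 10.0

    def test_constant_trace(self):
        assert erod_slope([(0, 7), (15, 7)]) == 0.0

    def test_noisy_trace_matches_polyfit(self, rng):
        t = np.linspace(0, 15, 16)
        f = 20 + 4.0 * t + rng.normal(0, 1, 16)
        expected = np.polyfit(t, f, 1)[0]
        assert erod_slope(np.column_stack([t, f])) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("trace", [[(0, 1)], [(5, 1), (5, 2)], []])
    def test_degenerate_traces(self, trace):
        with pytest.raises(DegenerateTraceError):
            erod_slope(trace)


class TestPercentOfNegControls:
    def layout(self):
        return PlateLayout.default()

    def test_control_mean_sets_scale(self):
        vals = {"A12": 80.0, "B12": 120.0, "G12": 100.0, "H12": 100.0, "B2": 55.0}
        out = percent_of_neg_controls(vals, self.layout())
        assert out["B2"] == 55.0

    def test_identity_case(self):
        vals = {w: 7.0 for w in ("A12", "B12", "G12", "H12", "C3")}
        assert percent_of_neg_controls(vals, self.layout())["C3"] == 100.0

    def test_spread_controls(self):
        vals = {"A12": 50.0, "B12": 50.0, "G12": 150.0, "H12": 150.0, "D4": 200.0}
        assert percent_of_neg_controls(vals, self.layout())["D4"] == 200.0

    def test_missing_controls_error(self):
        with pytest.raises(NormalizationError):
            percent_of_neg_controls({"B2": 5.0}, self.layout())


class TestPlateMedianNormalize:
    def test_constant_plate(self):
        layout = PlateLayout.default()
        vals = {w: 8.0 for w in layout.sample_wells[:5]}
        out = plate_median_normalize(vals, layout, list(vals))
        assert all(v == 1.0 for v in out.values())

    def test_three_wells(self):
        layout = PlateLayout.default()
        wells = layout.sample_wells[:3]
        vals = dict(zip(wells, [2.0, 4.0, 6.0]))
        out = plate_median_normalize(vals, layout, wells)
        assert [out[w] for w in wells] == [0.5, 1.0, 1.5]

    @given(st.lists(st.floats(0.1, 1e4), min_size=3, max_size=40))
    def test_output_sample_median_is_one(self, values):
        layout = PlateLayout.default()
        wells = layout.sample_wells[: len(values)]
        out = plate_median_normalize(dict(zip(wells, values)), layout, wells)
        assert brute_median([out[w] for w in wells]) == pytest.approx(1.0, abs=1e-12)


class TestChannelRatio:
    def test_plain_ratio(self):
        assert channel_ratio(2.0, 1.0, 0.1) == 2.0

    def test_pure_viability_effect_keeps_baseline(self):
        # Both channels reduced proportionally: ratio stays at 1, so a
        # cell-density effect is not mistaken for a pathway effect.
        assert channel_ratio(0.4, 0.4, 0.1) == 1.0

    def test_low_viability_is_excluded_not_raised(self):
        assert channel_ratio(0.5, 0.01, 0.1) == EXCLUDE_LOW_VIABILITY


class TestRobustZ:
    def test_worked_example(self):
        assert robust_z([1, 2, 3, 4, 5], 1.0) == pytest.approx(2 / KAPPA, abs=1e-9)
        assert robust_z([1, 2, 3, 4, 5], 1.0) == pytest.approx(1.3490, abs=1e-4)

    def test_x_at_median_is_zero(self):
        assert robust_z([1, 2, 3, 4, 5], 3.0) == 0.0

    def test_direction_negates(self):
        z = robust_z([1, 2, 3, 4, 5], 1.0)
        assert robust_z([1, 2, 3, 4, 5], 1.0, direction="increase") == -z

    def test_zero_mad_raises(self):
        with pytest.raises(DegenerateDispersionError):
            robust_z([2.0, 2.0, 2.0, 9.0], 1.0)

    def test_agrees_with_brute_force_on_1000_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            vals = rng.normal(0, 3, n)
            x = float(rng.normal())
            assert robust_z(vals, x) == pytest.approx(
                brute_robust_z(vals, x), rel=1e-12
            )

    def test_vectorized_fallback_uses_sd_then_errors(self):
        # >50% identical values: MAD 0, SD > 0 -> finite z under fallback.
        vals = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        with pytest.raises(DegenerateDispersionError):
            robust_z_scores(vals)
        z = robust_z_scores(vals, scale_fallback=True)
        assert np.isfinite(z).all()
        with pytest.raises(DegenerateDispersionError):
            robust_z_scores(np.ones(10), scale_fallback=True)


class TestSummarizeReplicates:
    @pytest.mark.parametrize(
        "values, expected, n",
        [
            ([0.9, 1.0, 1.1], 1.0, 3),
            ([2.5, 2.5, 2.5], 2.5, 3),
            ([1.0, np.nan, 3.0], 2.0, 2),
        ],
    )
    def test_examples(self, values, expected, n):
        z, count = summarize_replicates(values)
        assert z == pytest.approx(expected) and count == n

    def test_all_missing_marks_sirna_missing(self):
        z, count = summarize_replicates([np.nan, np.nan])
        assert np.isnan(z) and count == 0

    @given(st.permutations([0.3, -1.2, 4.5, 0.0]))
    def test_permutation_invariant(self, perm):
        z, n = summarize_replicates(perm)
        z0, n0 = summarize_replicates([0.3, -1.2, 4.5, 0.0])
        assert n == n0 and z == pytest.approx(z0, rel=1e-12)


def _norm_from_vectors(a, b):
    """Minimal NormalizedScreen stand-in for correlation tests."""
    from kinscreen.scoring import NormalizedScreen

    rows = []
    for rep, vec in [(1, a), (2, b)]:
        for i, v in enumerate(vec):
            rows.append(
                {"replicate": rep, "plate": 1, "well": f"A{i+1}",
                 "role": "sample", "sirna": f"s{i}", "score": v, "ratio": v}
            )
    wells = pd.DataFrame(rows)
    return NormalizedScreen(
        wells=wells, sirna_replicate_z=wells, sirna_summary=pd.DataFrame()
    )


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        norm = _norm_from_vectors([1, 2, 3, 4], [1, 2, 3, 4])
        assert replicate_correlation(norm, 1, 2) == pytest.approx(1.0)

    def test_negated_replicates(self):
        norm = _norm_from_vectors([1, 2, 3, 4], [-1, -2, -3, -4])
        assert replicate_correlation(norm, 1, 2) == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        a, b = np.array([1, 2, 3, 4.0]), np.array([2, 4, 5, 4.0])
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        norm = _norm_from_vectors(a, b)
        assert replicate_correlation(norm, 1, 2) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_undefined(self):
        norm = _norm_from_vectors([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(UndefinedCorrelationError):
            replicate_correlation(norm, 1, 2)


class TestQQExport:
    def test_needs_two_values(self):
        with pytest.raises(Exception):
            qq_export([1.0])

    def test_columns_sorted_nondecreasing(self, rng):
        df = qq_export(rng.normal(size=100))
        assert (np.diff(df["theoretical"]) >= 0).all()
        assert (np.diff(df["observed"]) >= 0).all()

    def test_standard_normal_sample_tracks_theoretical(self, rng):
        df = qq_export(rng.normal(size=1000))
        assert np.max(np.abs(df["observed"] - df["theoretical"])) < 0.5


class TestScoreScreen:
    def test_z_distribution_is_centered_and_scaled(self, small_scored):
        norm, _, cfg = small_scored
        sample = norm.wells[norm.wells["role"] == "sample"]
        for _, grp in sample.groupby("replicate"):
            z = grp.loc[~grp["excluded"], "z_erod"].to_numpy()
            assert np.median(z) == pytest.approx(0.0, abs=1e-9)
            assert KAPPA * np.median(np.abs(z)) == pytest.approx(1.0, abs=1e-9)

    def test_plate_scale_invariance(self, small_screen):
        screen, layout, library, _ = small_screen
        base = score_screen(screen, layout, library).sirna_summary
        v = screen.values.copy()
        mask = (v["replicate"] == 1) & (v["plate"] == 2)
        v.loc[mask, "value"] *= 5.3
        scaled = score_screen(ScreenDataset(values=v), layout, library).sirna_summary
        np.testing.assert_allclose(
            base["z_erod"], scaled["z_erod"], atol=1e-9
        )

    def test_single_well_viability_invariance(self, small_screen):
        # Reducing both channels of one well models a pure cell-number loss;
        # the ratio cancels it, so EROD z-scores are untouched.
        screen, layout, library, _ = small_screen
        base = score_screen(screen, layout, library).sirna_summary
        target = library.entries.iloc[10]
        for gamma in (0.25, 0.6, 1.0):
            v = screen.values.copy()
            mask = (
                (v["replicate"] == 2)
                & (v["plate"] == target["plate"])
                & (v["well"] == target["well"])
            )
            v.loc[mask, "value"] *= gamma
            out = score_screen(ScreenDataset(values=v), layout, library).sirna_summary
            np.testing.assert_allclose(base["z_erod"], out["z_erod"], atol=1e-9)

    def test_low_viability_wells_excluded_with_reason(self, small_screen):
        screen, layout, library, _ = small_screen
        v = screen.values.copy()
        target = library.entries.iloc[4]
        mask = (
            (v["replicate"] == 1)
            & (v["plate"] == target["plate"])
            & (v["well"] == target["well"])
            & (v["channel"] == "MB")
        )
        v.loc[mask, "value"] *= 1e-4
        norm = score_screen(ScreenDataset(values=v), layout, library)
        row = norm.wells[
            (norm.wells["replicate"] == 1)
            & (norm.wells["plate"] == target["plate"])
            & (norm.wells["well"] == target["well"])
        ].iloc[0]
        assert row["excluded"] and row["reason"] == EXCLUDE_LOW_VIABILITY
        assert norm.exclusion_counts.get(EXCLUDE_LOW_VIABILITY, 0) >= 1

    def test_kinetic_mode_matches_activity_mode(self):
        cfg_a = small_config(seed=21)
        cfg_k = small_config(seed=21, kinetic=True)
        screen_a, layout, library, _ = simulate_screen(cfg_a)
        screen_k, *_ = simulate_screen(cfg_k)
        a = score_screen(screen_a, layout, library).sirna_summary
        k = score_screen(screen_k, layout, library).sirna_summary
        np.testing.assert_allclose(a["z_erod"], k["z_erod"], atol=1e-9)


class TestPlateImageExport:
    def test_bookkeeping(self, small_screen, small_scored):
        _, layout, library, _ = small_screen
        norm, _, _ = small_scored
        images = plate_image_export(norm.sirna_summary, library, layout)
        n_finite = sum(int(np.isfinite(img.z.to_numpy()).sum()) for img in images.values())
        assert n_finite == len(library.entries)
        img = images[1]
        assert img.roles.loc["A", 12] == "neg_control"
        assert img.roles.loc["G", 1] == "pos_control"

    def test_cell_matches_sirna_z(self, small_screen, small_scored):
        _, layout, library, _ = small_screen
        norm, _, _ = small_scored
        images = plate_image_export(norm.sirna_summary, library, layout)
        entry = library.entries.iloc[0]
        from kinscreen.screen_model import parse_well
        r, c = parse_well(entry["well"])
        z = norm.sirna_summary.set_index("sirna").loc[entry["sirna"], "z_erod"]
        assert images[entry["plate"]].z.iloc[r, c] == pytest.approx(z)
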