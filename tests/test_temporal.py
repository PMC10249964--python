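"""Quadratic trajectory fits, phenology, growth traits, table assembly."""

import numpy as np
import pandas as pd
import pytest

from ricepheno import (
    CohortSpec,
    GrowthGroundTruth,
    assemble_itrait_table,
    derive_growth_traits,
    derive_phenological,
    derive_plant_row,
    detect_heading,
    fit_quadratic,
    quad_through,
    registry,
    simulate_growth_series,
)
from ricepheno.synthetic import culm_organ_traits


class TestFitQuadratic:
    def test_exact_interpolation(self):
        t = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        y = -2 * t**2 + 3 * t + 5
        fit = fit_quadratic(t, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx((-2, 3, 5), rel=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_series(self):
        fit = fit_quadratic([1, 2, 3, 4], [7.0, 7.0, 7.0, 7.0])
        assert (fit.a, fit.b, fit.c) == pytest.approx((0, 0, 7), abs=1e-9)

    def test_normal_equations_residual_orthogonality(self, rng):
        t = np.linspace(40, 180, 15)
        y = rng.normal(size=15)
        fit = fit_quadratic(t, y)
        resid = y - fit.predict(t)
        for basis in (t**2, t, np.ones_like(t)):
            assert abs(resid @ basis) < 1e-6 * max(np.abs(y).max(), 1) * len(t)

    def test_planted_coefficients_recovered_from_noiseless_series(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, seed=0)
        fit = fit_quadratic(s.days, s.values("PlantTPA"))
        np.testing.assert_allclose((fit.a, fit.b, fit.c), gt.tpa_coeffs, rtol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_quadratic([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="identical"):
            fit_quadratic([5, 5, 5, 5], [1, 2, 3, 4])


class TestPhenology:
    def test_argmax_day_of_planted_peak(self):
        # TPA peaks at day 105 exactly on the imaging grid
        gt = GrowthGroundTruth(tpa_coeffs=quad_through(100_000.0, 105.0, 42.0, 10_000.0))
        s = simulate_growth_series(gt, days=list(range(42, 183, 7)), seed=0)
        ph = derive_phenological(s)
        assert ph["PlantTPAD"] == 105

    def test_heading_day_snaps_to_first_imaging_day(self):
        gt = GrowthGroundTruth(heading_day=70)
        days = list(range(42, 183, 7))
        s = simulate_growth_series(gt, days=days, seed=0)
        hs = detect_heading(s, threshold_mm2=50.0)
        assert hs == min(d for d in days if d >= 70 and gt.panicle_tpa(d) > 50.0)

    def test_panicle_phenology_is_relative_to_heading(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, seed=0)
        ph = derive_phenological(s)
        days = np.array(s.days, float)
        pan = s.values("PanicleTPA")
        absolute_argmax = days[int(np.argmax(pan))]
        assert ph["PanicleTPAD"] == absolute_argmax - ph["HS"]

    def test_no_heading_yields_missing_with_warning(self):
        gt = GrowthGroundTruth(heading_day=170)  # panicle stays tiny pre-harvest
        s = simulate_growth_series(gt, days=list(range(42, 140, 7)), seed=0)
        with pytest.warns(UserWarning, match="no heading"):
            ph = derive_phenological(s)
        assert np.isnan(ph["HS"])
        assert np.isnan(ph["PanicleTPAD"])

    def test_senescence_vertex_clamped_into_window(self):
        # monotone rising Ypar whose fitted vertex precedes the window
        gt = GrowthGroundTruth(ypar_coeffs=quad_through(0.0, 30.0, 182.0, 0.6))
        s = simulate_growth_series(gt, days=list(range(60, 183, 7)), seed=0)
        ph = derive_phenological(s)
        assert ph["PlantSD"] == 60.0

    def test_senescence_vertex_recovered_when_interior(self):
        gt = GrowthGroundTruth()  # vertex planted at day 70
        s = simulate_growth_series(gt, seed=0)
        ph = derive_phenological(s)
        assert ph["PlantSD"] == pytest.approx(70.0, abs=1e-6)

    def test_argmax_invariant_under_monotone_rescaling(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, seed=0)
        ph1 = derive_phenological(s)
        for o in s.observations.values():
            o.PlantTPA = np.log(o.PlantTPA)  # monotone transform
        ph2 = derive_phenological(s)
        assert ph1["PlantTPAD"] == ph2["PlantTPAD"]


class TestGrowthTraits:
    def test_linear_series_daily_growth(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, days=list(range(10, 51, 10)), seed=0)
        for d, o in s.observations.items():
            o.PlantH = 4.0 * d
        g = derive_growth_traits(s)
        assert g["PlantHG"] == pytest.approx(4.0)  # (200 - 40) / (50 - 10)

    def test_constant_series_zero_growth(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, days=list(range(10, 51, 10)), seed=0)
        for o in s.observations.values():
            o.PlantH = 500.0
        with pytest.warns(UserWarning, match="daily growth"):
            g = derive_growth_traits(s)
        assert g["PlantHG"] == 0.0

    def test_panicle_coefficients_recovered(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, seed=0)
        g = derive_growth_traits(s)
        np.testing.assert_allclose(
            (g["PanicleYpar_a"], g["PanicleYpar_b"], g["PanicleYpar_c"]),
            gt.panicle_ypar_coeffs, rtol=1e-8,
        )
        np.testing.assert_allclose(
            (g["PanicleTPA_a"], g["PanicleTPA_b"], g["PanicleTPA_c"]),
            gt.panicle_tpa_coeffs, rtol=1e-8,
        )

    def test_end_tpa_is_last_preharvest_observation(self):
        gt = GrowthGroundTruth()
        s = simulate_growth_series(gt, seed=0)
        g = derive_growth_traits(s)
        assert g["PaicleEndTPA"] == pytest.approx(float(gt.panicle_tpa(s.days[-1])))


class TestAssembly:
    def test_full_synthetic_cohort_has_58_columns(self):
        from ricepheno import simulate_cohort

        table, *_ = simulate_cohort(CohortSpec(n_plants=4, seed=0))
        assert list(table.columns) == registry.trait_names()
        assert table.shape[1] == 58

    def test_column_group_counts(self):
        sizes = registry.group_sizes()
        assert [sizes[g] for g in registry.GROUPS] == [7, 5, 6, 8, 12, 10, 10]

    def test_plant_without_heading_keeps_row_with_missing_panicle_cells(self):
        gt = GrowthGroundTruth(plant_id="late", heading_day=170)
        s = simulate_growth_series(gt, days=list(range(42, 140, 7)), seed=0)
        with pytest.warns(UserWarning):
            row = derive_plant_row(s, culm=culm_organ_traits(gt))
        table = assemble_itrait_table({"late": row})
        assert len(table) == 1
        assert np.isnan(table.loc["late", "HS"])
        assert np.isnan(table.loc["late", "PanicleTPA_a"])
        assert np.isfinite(table.loc["late", "PlantTPA"])

    def test_unknown_plant_in_grain_table_rejected(self):
        gt = GrowthGroundTruth(plant_id="p1")
        s = simulate_growth_series(gt, seed=0)
        row = derive_plant_row(s)
        grain = pd.DataFrame({"AveGL": [8.0]}, index=pd.Index(["stranger"], name="plant_id"))
        with pytest.raises(ValueError, match="unknown plant"):
            assemble_itrait_table({"p1": row}, grain)
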