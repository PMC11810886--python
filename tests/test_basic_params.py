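"""Estimation of NR and the soil/fertilizer/manure contribution fractions."""

import numpy as np
import pandas as pd
import pytest

from stcr import (
    Conversions,
    FymSpec,
    MissingStratumError,
    estimate_all,
    fertilizer_contribution,
    fym_contribution,
    nutrient_requirement,
    soil_contribution,
)
from stcr.reference import BASIC_PARAMETERS, CONTROL_MEANS, TREATED_MEANS
from stcr.schema import NUTRIENTS, PLOT_COLUMNS


def make_plots(rows):
    """Plot table from dicts of overrides (defaults: tiny positive values)."""
    base = {c: 0.0 for c in PLOT_COLUMNS}
    base.update({"plot_id": 1, "strip": 1, "yield_kg_ha": 1.0,
                 "u_n": 1e-6, "u_p": 1e-6, "u_k": 1e-6,
                 "s_n": 1.0, "s_p": 1.0, "s_k": 1.0})
    out = []
    for i, row in enumerate(rows, start=1):
        r = dict(base)
        r.update(row, plot_id=i)
        out.append(r)
    return pd.DataFrame(out)[list(PLOT_COLUMNS)]


class TestNutrientRequirement:
    def test_definitional_single_plot(self):
        plots = make_plots([{"f_n": 60.0, "u_n": 38.0, "u_p": 10.0, "u_k": 46.0,
                             "yield_kg_ha": 10000.0}])
        nr = nutrient_requirement(plots)
        assert nr["n"] == pytest.approx(0.38)
        assert nr["p2o5"] == pytest.approx(10 * 2.2914 / 100)
        assert nr["k2o"] == pytest.approx(46 * 1.2046 / 100)

    def test_strip_mean_check_against_reference(self):
        """Uptake and yield means of the fertilized plots give NR within
        0.01 of the published 0.38 kg/q for N (ratio-of-means vs plot-level
        averaging)."""
        plots = make_plots([{"f_n": 120.0, "u_n": TREATED_MEANS["u_n"],
                             "yield_kg_ha": TREATED_MEANS["yield"]}])
        nr = nutrient_requirement(plots)
        assert nr["n"] == pytest.approx(0.372, abs=5e-4)
        assert abs(nr["n"] - BASIC_PARAMETERS.nr["n"]) <= 0.01

    def test_zero_yield_plot_excluded_with_warning(self):
        plots = make_plots([
            {"f_n": 60.0, "u_n": 38.0, "yield_kg_ha": 10000.0},
            {"f_n": 60.0, "u_n": 99.0, "yield_kg_ha": 0.0},
        ])
        with pytest.warns(UserWarning, match="non-positive yield"):
            nr = nutrient_requirement(plots)
        assert nr["n"] == pytest.approx(0.38)

    def test_all_plots_excluded_is_error(self):
        plots = make_plots([{"f_n": 60.0, "yield_kg_ha": 0.0}])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="excluded"):
                nutrient_requirement(plots)


class TestSoilContribution:
    def test_uptake_equal_to_soil_test_gives_100(self):
        plots = make_plots([{"s_n": 50.0, "u_n": 50.0, "s_p": 9.0, "u_p": 9.0,
                             "s_k": 30.0, "u_k": 30.0}])
        cs = soil_contribution(plots)
        assert all(cs[j] == pytest.approx(100.0) for j in NUTRIENTS)

    def test_zero_uptake_gives_zero(self):
        plots = make_plots([{"s_n": 50.0, "u_n": 0.0}])
        assert soil_contribution(plots)["n"] == 0.0

    def test_control_mean_check_against_reference(self):
        plots = make_plots([{"s_n": CONTROL_MEANS["s_n"], "u_n": CONTROL_MEANS["u_n"]}])
        assert soil_contribution(plots)["n"] == pytest.approx(22.19, abs=0.005)

    def test_requires_control_stratum(self):
        plots = make_plots([{"f_n": 60.0}])
        with pytest.raises(MissingStratumError, match="no control stratum"):
            soil_contribution(plots)


class TestFertilizerContribution:
    ALL_DOSES = {"f_n": 120.0, "f_p2o5": 160.0, "f_k2o": 100.0}

    def test_reference_mean_check_n(self):
        plots = make_plots([{**self.ALL_DOSES, "s_n": TREATED_MEANS["s_n"],
                             "u_n": TREATED_MEANS["u_n"]}])
        cf, neg = fertilizer_contribution(plots, BASIC_PARAMETERS.cs_pct)
        assert cf["n"] == pytest.approx(55.4, abs=0.05)
        assert neg["n"] == 0

    def test_reference_mean_check_p_with_oxide_conversion(self):
        plots = make_plots([{**self.ALL_DOSES, "s_p": 197.0, "u_p": 52.45}])
        cf, _ = fertilizer_contribution(plots, BASIC_PARAMETERS.cs_pct)
        assert cf["p2o5"] == pytest.approx(44.0, abs=0.05)

    def test_uptake_equal_to_soil_share_gives_zero(self):
        plots = make_plots([{**self.ALL_DOSES, "s_n": 400.0, "u_n": 0.2025 * 400.0}])
        cf, _ = fertilizer_contribution(plots, BASIC_PARAMETERS.cs_pct)
        assert cf["n"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_ratios_kept_and_counted(self):
        plots = make_plots([
            {**self.ALL_DOSES, "s_n": 400.0, "u_n": 100.0},
            {**self.ALL_DOSES, "s_n": 400.0, "u_n": 62.0},  # below soil share
        ])
        cf, neg = fertilizer_contribution(plots, BASIC_PARAMETERS.cs_pct)
        assert neg["n"] == 1
        per_plot = [100 * (u - 0.2025 * 400) / 120 for u in (100.0, 62.0)]
        assert cf["n"] == pytest.approx(np.mean(per_plot))

    def test_requires_fertilized_fym_free_plots(self):
        plots = make_plots([{"f_n": 120.0, "fym_t_ha": 6.25}])
        with pytest.raises(MissingStratumError, match="FYM-free"):
            fertilizer_contribution(plots, BASIC_PARAMETERS.cs_pct)


class TestFymContribution:
    def test_pure_manure_uptake(self):
        # U 20 against a credit of 58 kg/ha and no soil/fertilizer share
        spec = FymSpec(n_pct=0.58, p_pct=0.58, k_pct=0.58, basis="fresh")
        plots = make_plots([{"fym_t_ha": 10.0, "s_n": 1e-9, "u_n": 20.0,
                             "s_p": 1e-9, "s_k": 1e-9}])
        cs = {j: 0.0 for j in NUTRIENTS}
        cf = {j: 0.0 for j in NUTRIENTS}
        cfym, _ = fym_contribution(plots, cs, cf, spec)
        assert cfym["n"] == pytest.approx(100 * 20 / 58, abs=1e-9)

    def test_uptake_equal_to_soil_plus_fertilizer_gives_zero(self):
        spec = FymSpec()
        u = 0.2025 * 400 + 0.5516 * 120
        plots = make_plots([{"fym_t_ha": 12.5, "f_n": 120.0, "s_n": 400.0, "u_n": u}])
        cfym, _ = fym_contribution(
            plots, {"n": 20.25, "p2o5": 0.0, "k2o": 0.0},
            {"n": 55.16, "p2o5": 0.0, "k2o": 0.0}, spec,
        )
        assert cfym["n"] == pytest.approx(0.0, abs=1e-9)

    def test_requires_manured_stratum(self):
        plots = make_plots([{"f_n": 60.0}])
        with pytest.raises(MissingStratumError, match="no FYM stratum"):
            fym_contribution(plots, {}, {}, FymSpec())


class TestEstimateAll:
    def test_zero_noise_contributions_recovered_exactly(
        self, zero_noise_plots, zero_noise_truth
    ):
        params = estimate_all(zero_noise_plots, nr_method="closure")
        t = zero_noise_truth
        for j in NUTRIENTS:
            assert params.cs_pct[j] == pytest.approx(t.cs_pct[j], abs=1e-9)
            assert params.cf_pct[j] == pytest.approx(t.cf_pct[j], abs=1e-9)
            assert params.cfym_pct[j] == pytest.approx(t.cfym_pct[j], abs=1e-9)
            assert params.nr[j] == pytest.approx(t.nr[j], abs=1e-9)

    def test_recovered_cf_ordering(self, zero_noise_plots):
        cf = estimate_all(zero_noise_plots).cf_pct
        assert cf["k2o"] > cf["n"] > cf["p2o5"]

    def test_plot_order_invariance(self, noisy_plots):
        shuffled = noisy_plots.sample(frac=1.0, random_state=4).reset_index(drop=True)
        for method in ("mean_of_ratios", "ratio_of_means"):
            a = estimate_all(noisy_plots, method=method)
            b = estimate_all(shuffled, method=method)
            for j in NUTRIENTS:
                assert a.nr[j] == pytest.approx(b.nr[j], rel=1e-12)
                assert a.cfym_pct[j] == pytest.approx(b.cfym_pct[j], rel=1e-12)

    def test_missing_control_stratum_named(self, noisy_plots):
        no_controls = noisy_plots[(noisy_plots[["f_n", "f_p2o5", "f_k2o"]] > 0).any(axis=1)]
        with pytest.raises(MissingStratumError, match="no control stratum"):
            estimate_all(no_controls)

    def test_conversion_applied_once(self, zero_noise_plots):
        """Doubling the P conversion factor halves the implied elemental
        credit exactly once in each estimate (unit identity)."""
        params = estimate_all(zero_noise_plots, nr_method="closure")
        big = Conversions(p_to_p2o5=2 * 2.2914)
        params2 = estimate_all(zero_noise_plots, conversions=big, nr_method="closure")
        assert params2.nr["p2o5"] == pytest.approx(2 * params.nr["p2o5"], rel=1e-9)
        assert params2.cf_pct["p2o5"] == pytest.approx(2 * params.cf_pct["p2o5"], rel=1e-6)
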