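"""Tests for order selection, refinement, curves, comparisons, linearity."""

import numpy as np
import pandas as pd
import pytest

from fretolig.equilibrium import OligomerModel, assoc_const_for_fraction
from fretolig.errors import InsufficientDesignError
from fretolig.fitting import (
    MeasurementSet,
    ParameterGrid,
    compare_kdiss,
    fit_oligomer_model,
    fret_vs_acceptor_fraction,
    mse_profile,
    oligo_fraction_curve,
    refine_fit,
    select_order,
)
from fretolig.synthetic import GeneratorConfig, generate, generate_ratio_series


def _noiseless_dimer_set(kdiss=10**2.3, e_tilde=0.55, seed=0):
    """Dimer data exactly on the model surface at a grid-node truth."""
    cfg = GeneratorConfig(
        truth=OligomerModel(2, e_tilde, 1.0 / kdiss),
        sigma_e=0.0,
        sigma_c=0.0,
        seed=seed,
    )
    return generate(cfg)


class TestMseProfile:
    def test_noiseless_grid_node_truth_gives_zero_mse(self):
        # truth at E~ = 0.55 and half-saturation 10^2.3 sits on grid nodes
        data = _noiseless_dimer_set()
        prof = mse_profile(data, None)
        assert prof[2].mse == pytest.approx(0.0, abs=1e-20)
        assert prof[2].e_tilde == pytest.approx(0.55)
        assert prof[2].half_saturation == pytest.approx(10**2.3)
        assert all(prof[n].mse > prof[2].mse for n in (3, 4, 5, 6))

    def test_duplicated_data_identical_profile(self):
        data = _noiseless_dimer_set(seed=3)
        doubled = MeasurementSet(
            pd.concat([data.data, data.data], ignore_index=True), n_experiments=4
        )
        p1 = mse_profile(data, None)
        p2 = mse_profile(doubled, None)
        for n in p1:
            assert p1[n].mse == pytest.approx(p2[n].mse, rel=1e-12)
            assert p1[n].e_tilde == p2[n].e_tilde

    def test_no_association_truth_prefers_weakest_binding(self):
        cfg = GeneratorConfig(
            truth=OligomerModel(2, 0.5, 0.0), sigma_e=0.0, sigma_c=0.0, seed=1
        )
        data = generate(cfg)
        prof = mse_profile(data, None)
        grid = ParameterGrid()
        for n in prof:
            assert prof[n].half_saturation == pytest.approx(grid.half_saturation[-1])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(e_tilde=np.array([]))


class TestSelectOrder:
    def test_strict_minimum_at_two_is_dimer(self):
        mse = {2: 1.0, 3: 2.0, 4: 2.5, 5: 2.6, 6: 2.7}
        assert select_order(mse) == (2, "dimer")

    def test_minimum_at_six_is_cluster(self):
        mse = {2: 3.0, 3: 2.5, 4: 2.0, 5: 1.5, 6: 1.0}
        assert select_order(mse) == (6, "cluster")

    def test_flat_profile_is_cluster(self):
        mse = {n: 1.0 for n in range(2, 7)}
        best_n, cls = select_order(mse)
        assert cls == "cluster"

    def test_partial_tie_with_two_is_ambiguous(self):
        mse = {2: 1.0, 3: 1.001, 4: 1.5, 5: 1.6, 6: 1.7}
        assert select_order(mse) == (2, "ambiguous")

    def test_tolerance_scales_relative(self):
        mse = {2: 1.0, 3: 1.015, 4: 1.5, 5: 1.6, 6: 1.7}
        assert select_order(mse, rel_tol=0.02)[1] == "ambiguous"
        assert select_order(mse, rel_tol=0.01) == (2, "dimer")


class TestRefineFit:
    def test_noiseless_round_trip(self):
        kdiss, e_tilde = 206.0, 0.55
        cfg = GeneratorConfig(
            truth=OligomerModel(2, e_tilde, 1.0 / kdiss), sigma_e=0.0, sigma_c=0.0, seed=2
        )
        data = generate(cfg)
        prof = mse_profile(data, None, n_values=[2])
        fit = refine_fit(data, None, 2, prof[2])
        assert fit.kdiss == pytest.approx(kdiss, rel=1e-3)
        assert fit.e_tilde == pytest.approx(e_tilde, rel=1e-3)
        assert fit.kdiss_ci[0] <= fit.kdiss <= fit.kdiss_ci[1]
        assert fit.e_tilde_ci[0] <= fit.e_tilde <= fit.e_tilde_ci[1]

    def test_refinement_never_increases_grid_mse(self, prox_table):
        cfg = GeneratorConfig(proximity=prox_table, seed=5)
        data = generate(cfg)
        prof = mse_profile(data, prox_table, n_values=[2])
        fit = refine_fit(data, prox_table, 2, prof[2])
        assert fit.refined_mse <= prof[2].mse + 1e-15

    def test_saturated_data_flags_wide_interval(self):
        # every region far above Kdiss: E~ identified, K unconstrained
        cfg = GeneratorConfig(
            truth=OligomerModel(2, 0.55, 1.0 / 0.01),
            expression_range=(500.0, 3000.0),
            sigma_e=0.05,
            sigma_c=0.0,
            seed=8,
        )
        data = generate(cfg)
        prof = mse_profile(data, None, n_values=[2])
        fit = refine_fit(data, None, 2, prof[2])
        assert fit.wide_kdiss_ci
        assert not np.isfinite(fit.kdiss_ci[1])
        assert fit.e_tilde == pytest.approx(0.55, abs=0.02)

    def test_pipeline_recovers_dimer(self, prox_table):
        cfg = GeneratorConfig(proximity=prox_table, seed=1)
        fit = fit_oligomer_model(generate(cfg), prox_table)
        assert fit.best_n == 2
        assert fit.classification == "dimer"
        assert fit.kdiss_ci[0] < fit.kdiss < fit.kdiss_ci[1]
        assert 100 < fit.kdiss < 400


class TestFractionCurve:
    def _fit(self, data, prox=None):
        prof = mse_profile(data, prox, n_values=[2])
        return refine_fit(data, prox, 2, prof[2])

    def test_half_saturation_point(self):
        data = _noiseless_dimer_set(kdiss=206.0)
        fit = self._fit(data)
        curve, bins = oligo_fraction_curve(fit, data, conc_grid=np.array([206.0]))
        assert curve["f_oligo"].iloc[0] == pytest.approx(0.5, rel=1e-3)
        assert len(bins) > 0

    def test_curve_monotone(self, prox_table):
        cfg = GeneratorConfig(proximity=prox_table, seed=6)
        data = generate(cfg)
        prof = mse_profile(data, prox_table, n_values=[2])
        fit = refine_fit(data, prox_table, 2, prof[2])
        curve, _ = oligo_fraction_curve(fit, data, prox_table)
        assert np.all(np.diff(curve["f_oligo"]) >= -1e-12)

    def test_no_association_gives_flat_zero(self):
        cfg = GeneratorConfig(
            truth=OligomerModel(2, 0.5, 0.0), sigma_e=0.0, sigma_c=0.0, seed=1
        )
        data = generate(cfg)
        from fretolig.fitting import FitResult

        fit = FitResult(
            mse_by_n={2: 0.0},
            best_n=2,
            classification="dimer",
            e_tilde=0.5,
            e_tilde_ci=(0.4, 0.6),
            assoc_const=1e-12,
            kdiss=1e12,
            kdiss_ci=(1e11, 1e13),
            delta_g=0.0,
            delta_g_ci=(0.0, 0.0),
            refined_mse=0.0,
            n_points=len(data),
        )
        curve, _ = oligo_fraction_curve(fit, data)
        assert np.all(curve["f_oligo"] < 1e-6)


class TestCompareKdiss:
    def _fit(self, kdiss, seed, prox=None):
        cfg = GeneratorConfig(truth=OligomerModel(2, 0.55, 1.0 / kdiss), seed=seed)
        data = generate(cfg)
        prof = mse_profile(data, None, n_values=[2])
        return refine_fit(data, None, 2, prof[2])

    def test_identical_fits_are_indistinguishable(self):
        fit = self._fit(206.0, seed=1)
        res = compare_kdiss(fit, fit)
        assert res.t_stat == 0.0
        assert res.p_corrected == 1.0
        assert not res.significant

    def test_separated_fits_significant(self):
        fit_a = self._fit(206.0, seed=1)
        fit_b = self._fit(11.0, seed=2)
        res = compare_kdiss(fit_a, fit_b)
        assert res.significant
        assert res.p_corrected < 0.05

    def test_bonferroni_multiplies_raw_p(self):
        fit_a = self._fit(206.0, seed=1)
        fit_b = self._fit(230.0, seed=3)
        r1 = compare_kdiss(fit_a, fit_b, m_comparisons=1)
        r3 = compare_kdiss(fit_a, fit_b, m_comparisons=3)
        assert r3.p_corrected == pytest.approx(min(1.0, 3 * r1.p_value), rel=1e-12)

    def test_symmetry_up_to_sign(self):
        fit_a = self._fit(206.0, seed=1)
        fit_b = self._fit(69.0, seed=4)
        r_ab = compare_kdiss(fit_a, fit_b)
        r_ba = compare_kdiss(fit_b, fit_a)
        assert r_ab.t_stat == pytest.approx(-r_ba.t_stat, rel=1e-12)
        assert r_ab.p_value == pytest.approx(r_ba.p_value, rel=1e-12)

    def test_requires_replicate_counts(self):
        fit = self._fit(206.0, seed=1)
        object.__setattr__(fit, "n_experiments", None)
        with pytest.raises(ValueError, match="independent experiments"):
            compare_kdiss(fit, fit)


class TestLinearityDiagnostic:
    def _series(self, n, e_tilde, seed=11):
        if n == 2:
            truth = OligomerModel(2, e_tilde, 1.0 / 0.01)
        else:
            truth = OligomerModel(n, e_tilde, assoc_const_for_fraction(n, 2.0, 0.5))
        cfg = GeneratorConfig(
            truth=truth, expression_range=(500.0, 3000.0), n_cells=96, seed=seed
        )
        return generate_ratio_series(cfg)

    def test_saturated_dimer_is_linear_with_slope_e_tilde(self):
        res = fret_vs_acceptor_fraction(self._series(2, 0.55))
        assert res.verdict.startswith("linear")
        assert res.slope == pytest.approx(0.55, rel=0.05)

    def test_saturated_hexamer_is_nonlinear(self):
        res = fret_vs_acceptor_fraction(self._series(6, 0.5))
        assert res.verdict.startswith("nonlinear")
        assert res.p_value < 0.05

    def test_single_ratio_design_rejected(self):
        cfg = GeneratorConfig(
            truth=OligomerModel(2, 0.55, 1.0 / 0.01),
            expression_range=(500.0, 3000.0),
            n_cells=96,
            seed=11,
        )
        data = generate(cfg)
        with pytest.raises(InsufficientDesignError):
            fret_vs_acceptor_fraction(data)

    def test_empty_after_density_filter_rejected(self):
        cfg = GeneratorConfig(expression_range=(10.0, 40.0), n_cells=50, seed=2, cell_spread=0.0)
        series = generate_ratio_series(cfg)
        with pytest.raises(ValueError, match="density filter"):
            fret_vs_acceptor_fraction(series, min_total_conc=1000.0)
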