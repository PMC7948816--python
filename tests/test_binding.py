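"""1:1 binding quantification: quadratic fluorescence isotherm against a
bisection mass-balance oracle, and the single-site ITC model with
displaced-volume bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from pepbiophys import binding, synth
from pepbiophys.datatypes import ItcIsotherm, NoiseSpec


def complex_by_bisection(receptor: float, ligand: float, kd: float) -> float:
    """Independent oracle: root of (R-c)(L-c) = Kd*c on c in [0, min(R, L)]."""
    if ligand == 0 or receptor == 0:
        return 0.0

    def f(c):
        return (receptor - c) * (ligand - c) - kd * c

    hi = min(receptor, ligand)
    return brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)


class TestQuadraticEvaluation:
    def test_hand_solved_value(self):
        y = binding.quadratic_binding_signal(
            10.0, f0=0.0, dfmax=1.0, kd=10.0, receptor_total=10.0
        )
        assert y == pytest.approx((30.0 - math.sqrt(500.0)) / 20.0, rel=1e-12)

    def test_zero_ligand(self):
        y = binding.quadratic_binding_signal(
            0.0, f0=0.25, dfmax=1.0, kd=5.0, receptor_total=10.0
        )
        assert y == pytest.approx(0.25, rel=1e-12)

    def test_saturation_asymptote(self):
        y = binding.quadratic_binding_signal(
            1e9, f0=0.25, dfmax=1.0, kd=5.0, receptor_total=10.0
        )
        assert y == pytest.approx(1.25, rel=1e-6)

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            binding.quadratic_binding_signal(
                -1.0, f0=0.0, dfmax=1.0, kd=5.0, receptor_total=10.0
            )

    @settings(max_examples=200, derandomize=True)
    @given(
        kd=st.floats(min_value=0.01, max_value=1000.0),
        ligand=st.floats(min_value=0.0, max_value=100.0),
        receptor=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_matches_bisection_oracle(self, kd, ligand, receptor):
        y = binding.quadratic_binding_signal(
            ligand, f0=0.0, dfmax=1.0, kd=kd, receptor_total=receptor
        )
        oracle = complex_by_bisection(receptor, ligand, kd) / receptor
        assert y == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=50, derandomize=True)
    @given(kd=st.floats(min_value=0.01, max_value=1000.0))
    def test_monotone_and_bounded(self, kd):
        lig = np.linspace(0.0, 200.0, 60)
        y = binding.quadratic_binding_signal(
            lig, f0=0.1, dfmax=1.0, kd=kd, receptor_total=10.0
        )
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y <= 1.1 + 1e-12)

    def test_stoichiometric_limit_closed_form(self):
        # kd -> 0: bound fraction -> min(L, R)/R
        for ligand in (3.0, 10.0, 25.0):
            y = binding.quadratic_binding_signal(
                ligand, f0=0.0, dfmax=1.0, kd=1e-9, receptor_total=10.0
            )
            assert y == pytest.approx(min(ligand, 10.0) / 10.0, rel=1e-4)


class TestFluorescenceFit:
    GRID = np.linspace(0.0, 15.0, 12)

    @pytest.mark.parametrize("kd_true", [8.0, 15.0])
    def test_noise_free_recovery(self, kd_true):
        curve, _ = synth.gen_binding_titration(kd_true, 0.2, 1.0, 10.0, self.GRID)
        fit = binding.fit_fluorescence_titration(curve, 10.0)
        assert fit.converged
        assert fit.params["kd"] == pytest.approx(kd_true, rel=1e-3)
        assert fit.params["f0"] == pytest.approx(0.2, abs=1e-6)
        assert fit.params["dfmax"] == pytest.approx(1.0, rel=1e-4)

    def test_confidence_interval_covers_truth_under_noise(self):
        covered = 0
        n_rep = 25
        for seed in range(n_rep):
            curve, _ = synth.gen_binding_titration(
                8.0, 0.0, 1.0, 10.0, self.GRID, NoiseSpec(sigma=0.02, seed=seed)
            )
            fit = binding.fit_fluorescence_titration(curve, 10.0)
            half = 1.96 * fit.stderr.get("kd", np.inf)
            covered += fit.params["kd"] - half <= 8.0 <= fit.params["kd"] + half
        # nominal 95% coverage; 19/25 keeps the binomial false-alarm rate tiny
        assert covered >= 19

    def test_tight_binding_regime_flagged(self):
        curve, _ = synth.gen_binding_titration(0.01, 0.0, 1.0, 10.0, self.GRID)
        fit = binding.fit_fluorescence_titration(curve, 10.0)
        assert "unidentifiable" in fit.message

    def test_too_few_points_rejected(self):
        curve, _ = synth.gen_binding_titration(8.0, 0.0, 1.0, 10.0, [0.0, 5.0, 10.0])
        with pytest.raises(ValueError):
            binding.fit_fluorescence_titration(curve, 10.0)


ITC_CONDITIONS = dict(cell_conc=30.0, syringe_conc=609.0, cell_vol_ml=1.4)


def simulate_cell_oracle(kd, n, inj_vol_ul, cell=30.0, syringe=609.0, v0_ml=1.4):
    """Independent loop re-deriving the in-cell mass balance and the moles of
    complex formed (in cell plus displaced), for conservation checks."""
    v0 = v0_ml * 1000.0
    m, x, b_prev = cell, 0.0, 0.0
    formed_nmol = 0.0
    bound = []
    for v in inj_vol_ul:
        formed_nmol += b_prev * v * 1e-3  # complex pushed out by this injection
        f = 1.0 - v / v0
        m, x = m * f, x * f + syringe * (v / v0)
        s = n * m + x + kd
        b_prev = 0.5 * (s - math.sqrt(s * s - 4.0 * n * m * x))
        bound.append(b_prev)
    formed_nmol += bound[-1] * v0 * 1e-3
    return np.array(bound), formed_nmol


class TestItc:
    def test_round_trip_recovery(self):
        isotherm, _ = synth.gen_itc_isotherm(11.0, 0.35, **ITC_CONDITIONS)
        fit = binding.fit_itc(isotherm)
        assert fit.converged
        assert fit.params["kd"] == pytest.approx(11.0, rel=1e-2)
        assert fit.params["dh"] == pytest.approx(0.35, rel=1e-2)
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-2)

    def test_zero_enthalpy_unidentifiable(self):
        isotherm, _ = synth.gen_itc_isotherm(11.0, 0.0, **ITC_CONDITIONS)
        fit = binding.fit_itc(isotherm)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_dilution_heats_subtracted(self):
        isotherm, _ = synth.gen_itc_isotherm(11.0, 0.35, **ITC_CONDITIONS)
        offset = np.full(len(isotherm), 0.05)
        shifted = ItcIsotherm(
            isotherm.injection_volumes_ul,
            isotherm.heats_ucal + offset,
            isotherm.cell_conc_uM,
            isotherm.syringe_conc_uM,
            isotherm.cell_volume_ml,
        )
        fit = binding.fit_itc(shifted, dilution_heats_ucal=offset)
        assert fit.params["kd"] == pytest.approx(11.0, rel=1e-2)

    def test_cumulative_heat_conservation(self):
        # sum(q) = dH * (moles of complex formed, in cell + displaced)
        inj = np.full(28, 10.0)
        isotherm, _ = synth.gen_itc_isotherm(11.0, 0.35, inj_vol_ul=inj, **ITC_CONDITIONS)
        _, formed_nmol = simulate_cell_oracle(11.0, 1.0, inj)
        expected_ucal = formed_nmol * 0.35  # nmol * kcal/mol = ucal
        assert np.sum(isotherm.heats_ucal) == pytest.approx(expected_ucal, rel=5e-3)

    def test_partitioning_independence(self):
        # same total volume injected in 10 ul vs 5 ul steps: same total heat
        totals = []
        for v, n_inj in ((10.0, 28), (5.0, 56)):
            isotherm, _ = synth.gen_itc_isotherm(
                11.0, 0.35, inj_vol_ul=np.full(n_inj, v), **ITC_CONDITIONS
            )
            totals.append(np.sum(isotherm.heats_ucal))
        assert totals[1] == pytest.approx(totals[0], rel=5e-3)

    def test_extreme_c_value_warns(self):
        isotherm, _ = synth.gen_itc_isotherm(0.001, 0.35, **ITC_CONDITIONS)
        fit = binding.fit_itc(isotherm)
        assert "low confidence" in fit.message

    def test_too_few_injections_rejected(self):
        isotherm, _ = synth.gen_itc_isotherm(
            11.0, 0.35, inj_vol_ul=np.full(5, 10.0), **ITC_CONDITIONS
        )
        with pytest.raises(ValueError):
            binding.fit_itc(isotherm)
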