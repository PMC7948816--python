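"""Residue-level NMR observables: conformational shifts, CSP, relaxation
fits, heteronuclear NOE and NOE-contact bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepbiophys import nmr, synth
from pepbiophys.datatypes import DecaySeries
from pepbiophys.sequence import WT_C27, C27_START, PeptideSequence


@pytest.fixture
def wt():
    return PeptideSequence(WT_C27, C27_START)


class TestConformationalShift:
    def test_exact_reference_is_random_coil(self):
        rec = nmr.ResidueNmrRecord(191, "W", ha_obs_ppm=4.60, ha_rc_ppm=4.66,
                                   correction_ppm=-0.06)
        label, delta = nmr.conformational_shift(rec)
        assert label == "random-coil" and delta == pytest.approx(0.0, abs=1e-12)

    def test_threshold_crossing(self):
        rec = nmr.ResidueNmrRecord(190, "D", ha_obs_ppm=4.49, ha_rc_ppm=4.64)
        label, delta = nmr.conformational_shift(rec)
        assert label == "non-random-coil" and delta == pytest.approx(-0.15)

    def test_band_edge_is_random_coil(self):
        rec = nmr.ResidueNmrRecord(195, "I", ha_obs_ppm=4.27, ha_rc_ppm=4.17)
        assert nmr.conformational_shift(rec)[0] == "random-coil"

    def test_helix_patch_flagged_in_table(self, wt):
        # upfield H-alpha shifts on Asp190-Arg192 (helix signature) flagged,
        # remaining residues at their coil reference stay unflagged
        observed = {}
        for res in range(188, 196):
            code = wt.residue_at(res)
            next_code = wt.residue_at(res + 1) if res + 1 <= wt.end_number else None
            rc, corr = nmr.random_coil_ha_reference(code, next_code)
            observed[res] = rc + corr + (-0.15 if res in (190, 191, 192) else 0.02)
        table = nmr.secondary_shift_table(wt, observed)
        flagged = set(table.loc[table.classification == "non-random-coil", "residue"])
        assert flagged == {190, 191, 192}

    def test_missing_reference_names_residue(self, wt):
        broken_table = {"ha_ppm": {"A": 4.32}}  # lacks most residues
        with pytest.raises(ValueError, match="W191"):
            nmr.secondary_shift_table(wt, {191: 4.6}, table=broken_table)


class TestCsp:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.0, 0.0, 0.0), (0.3, 0.0, 0.3), (-0.3, 0.0, 0.3), (0.1, 0.5, 0.12206)],
    )
    def test_values(self, dh, dn, expected):
        assert nmr.csp(dh, dn) == pytest.approx(expected, abs=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(
        dh=st.floats(-2, 2, allow_nan=False),
        dn=st.floats(-10, 10, allow_nan=False),
    )
    def test_nonnegative_and_sign_symmetric(self, dh, dn):
        v = nmr.csp(dh, dn)
        assert v >= 0
        assert nmr.csp(-dh, dn) == pytest.approx(v, rel=1e-12)
        assert nmr.csp(dh, -dn) == pytest.approx(v, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nmr.csp(float("inf"), 0.0)


class TestRelaxationFit:
    def test_one_decade_pair_gives_rate_ten(self):
        series, _ = synth.gen_relaxation_series(10.0, i0=100.0)
        fit = nmr.fit_relaxation_rate(series)
        assert fit.params["r"] == pytest.approx(10.0, rel=1e-6)
        assert fit.params["i0"] == pytest.approx(100.0, rel=1e-6)

    def test_constant_series_zero_rate(self):
        fit = nmr.fit_relaxation_rate(DecaySeries([10, 50, 100, 200], np.full(4, 5.0)))
        assert fit.params["r"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("rate", [2.3, 5.1])
    def test_backbone_rate_recovery(self, rate):
        series, _ = synth.gen_relaxation_series(rate, i0=50.0)
        fit = nmr.fit_relaxation_rate(series)
        assert fit.converged
        assert fit.params["r"] == pytest.approx(rate, rel=1e-6)

    def test_matches_loglinear_closed_form(self):
        series, _ = synth.gen_relaxation_series(3.7, i0=80.0)
        fit = nmr.fit_relaxation_rate(series)
        slope = np.polyfit(series.t * 1e-3, np.log(series.intensity), 1)[0]
        assert fit.params["r"] == pytest.approx(-slope, rel=1e-8)

    def test_growing_series_flagged(self):
        series = DecaySeries([10, 50, 100, 200], [1.0, 2.0, 4.0, 8.0])
        fit = nmr.fit_relaxation_rate(series)
        assert not fit.converged


class TestHetNoe:
    def test_equal_intensities(self):
        assert nmr.het_noe(5.0, 5.0)[0] == pytest.approx(1.0)

    def test_ratio_and_propagated_uncertainty(self):
        ratio, sd = nmr.het_noe(0.7, 1.0, noise_sd=0.01)
        assert ratio == pytest.approx(0.70)
        expected = 0.7 * math.sqrt((0.01 / 0.7) ** 2 + (0.01 / 1.0) ** 2)
        assert sd == pytest.approx(expected, rel=1e-12)
        assert sd == pytest.approx(0.0122, abs=5e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nmr.het_noe(0.7, 0.0)

    def test_out_of_band_ratio_warns(self):
        with pytest.warns(UserWarning):
            nmr.het_noe(2.0, 1.0)


def _records(values, start=186):
    return [
        nmr.RelaxationRecord(start + i, r1=r1, r2=r2, noe=noe, r1_err=0.1, r2_err=0.2)
        for i, (r1, r2, noe) in enumerate(values)
    ]


class TestFreeBoundComparison:
    def test_identical_inputs_zero_deltas(self):
        recs = _records([(2.2, 5.0, 0.6), (2.4, 6.0, 0.5)])
        cmp = nmr.compare_free_bound(recs, recs)
        assert np.allclose(cmp.table[["d_r1", "d_r2", "d_noe"]], 0.0)

    def test_binding_increases_r2_and_mean_r1_shift(self):
        free = _records([(2.17, 4.0, 0.6)] * 5)
        bound = _records([(2.32, 7.5, 0.4)] * 5)
        cmp = nmr.compare_free_bound(free, bound)
        assert cmp.table["d_r1"].mean() == pytest.approx(0.15, abs=1e-12)
        assert (cmp.table["d_r2"] > 0).all()

    def test_ranked_by_r2_change(self):
        free = _records([(2.0, 4.0, 0.5), (2.0, 4.0, 0.5), (2.0, 4.0, 0.5)])
        bound = _records([(2.1, 4.5, 0.5), (2.1, 9.0, 0.5), (2.1, 6.0, 0.5)])
        cmp = nmr.compare_free_bound(free, bound)
        assert list(cmp.table["residue"]) == [187, 188, 186]

    def test_unmatched_residue_reported(self):
        free = _records([(2.0, 4.0, 0.5), (2.0, 4.0, 0.5)])
        bound = _records([(2.1, 4.5, 0.5)])  # residue 187 missing, like Arg204's NOE gap
        cmp = nmr.compare_free_bound(free, bound)
        assert cmp.unmatched_free == [187]

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError):
            nmr.compare_free_bound(_records([(2, 4, 0.5)], 186), _records([(2, 4, 0.5)], 200))


class TestNoeSummary:
    def test_empty_contacts_no_calls(self):
        summary = nmr.noe_summary([])
        assert not summary.nascent_helix and not summary.helix_like

    def test_sequential_chain_flags_nascent_helix(self, wt):
        contacts = [nmr.NoeContact(i, i + 1, "NN") for i in range(190, 195)]
        summary = nmr.noe_summary(contacts, sequence=wt)
        assert summary.nascent_helix
        (start, end), = summary.nascent_helix_windows
        assert start <= 191 <= end  # window covers Trp191

    def test_medium_range_contacts_flag_helix_like(self):
        contacts = [
            nmr.NoeContact(191, 194, "alphaN"),
            nmr.NoeContact(191, 195, "alphaN"),
        ]
        summary = nmr.noe_summary(contacts)
        assert summary.helix_like and not summary.nascent_helix

    def test_order_invariance(self):
        contacts = [
            nmr.NoeContact(190, 191, "NN", "strong"),
            nmr.NoeContact(191, 192, "NN", "weak"),
            nmr.NoeContact(192, 193, "NN"),
            nmr.NoeContact(191, 194, "alphaN"),
        ]
        a = nmr.noe_summary(contacts)
        b = nmr.noe_summary(contacts[::-1])
        assert a == b

    def test_short_run_is_not_nascent_helix(self):
        contacts = [nmr.NoeContact(190, 191, "NN"), nmr.NoeContact(191, 192, "NN")]
        assert not nmr.noe_summary(contacts).nascent_helix

    def test_out_of_sequence_contact_rejected(self, wt):
        with pytest.raises(ValueError, match="outside sequence"):
            nmr.noe_summary([nmr.NoeContact(299, 300, "NN")], sequence=wt)

    def test_self_contact_rejected(self):
        with pytest.raises(ValueError):
            nmr.NoeContact(191, 191, "NN")

    def test_intensity_tertile_binning(self):
        classes = nmr.classify_contact_strength([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert classes[0] == "weak" and classes[-1] == "strong"
        assert "medium" in classes
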