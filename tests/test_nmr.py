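"""HSQC analysis: peak matching, CSP, site mapping, KD fits, STD calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hairpinscreen import mir31
from hairpinscreen.nmr import (
    HSQCPeak,
    PeakIdentityError,
    classify_std,
    compute_csp,
    csp_profile,
    dmso_control_check,
    fit_kd_fast,
    fit_kd_intermediate,
    fraction_bound,
    map_binding_site,
    match_peaks,
)
from hairpinscreen.synthetic import reference_peaks


def shift(peak: HSQCPeak, dh=0.0, dc=0.0, volume=None) -> HSQCPeak:
    return HSQCPeak(
        peak.residue, peak.atom_pair, peak.dh + dh, peak.dc + dc,
        peak.volume if volume is None else volume,
    )


class TestComputeCsp:
    def test_hand_arithmetic(self):
        a = HSQCPeak("A40", "C2H2", 7.80, 152.0)
        b = HSQCPeak("A40", "C2H2", 7.81, 152.1)
        # sqrt(0.01^2 + (0.25*0.1)^2) = sqrt(1e-4 + 6.25e-4)
        assert compute_csp(a, b, alpha=0.25) == pytest.approx(0.026926, abs=1e-5)

    def test_identical_peaks_zero(self):
        a = HSQCPeak("A40", "C2H2", 7.80, 152.0)
        assert compute_csp(a, a) == 0.0

    def test_alpha_zero_is_proton_distance(self):
        a = HSQCPeak("A40", "C2H2", 7.80, 152.0)
        b = HSQCPeak("A40", "C2H2", 7.77, 150.0)
        assert compute_csp(a, b, alpha=0.0) == pytest.approx(0.03)

    def test_mismatched_identity_raises(self):
        a = HSQCPeak("A40", "C2H2", 7.8, 152.0)
        b = HSQCPeak("A41", "C2H2", 7.8, 152.0)
        with pytest.raises(PeakIdentityError):
            compute_csp(a, b)

    @given(
        dh=st.floats(-0.5, 0.5), dc=st.floats(-3.0, 3.0), scale=st.floats(0.1, 10.0)
    )
    def test_symmetry_and_linear_scaling(self, dh, dc, scale):
        a = HSQCPeak("A40", "C2H2", 7.8, 152.0)
        b = shift(a, dh, dc)
        assert compute_csp(a, b) == pytest.approx(compute_csp(b, a))
        c = shift(a, scale * dh, scale * dc)
        assert compute_csp(a, c) == pytest.approx(scale * compute_csp(a, b), rel=1e-9)


class TestMatchPeaks:
    def test_identity_map(self):
        ref = reference_peaks()
        matches = match_peaks(ref, ref)
        assert all(isinstance(m, HSQCPeak) for m in matches.values())
        assert len(matches) == len(ref)

    def test_moved_beyond_radius_not_detected(self):
        ref = reference_peaks()
        observed = [shift(p, dh=5.0) if p.residue == "A40" else p for p in ref]
        matches = match_peaks(ref, observed)
        statuses = {k: v for k, v in matches.items() if not isinstance(v, HSQCPeak)}
        assert set(statuses.values()) == {"not_detected"}
        assert all(k[0] == "A40" for k in statuses)

    def test_two_candidates_marked_overlapped(self):
        ref = [HSQCPeak("A40", "C2H2", 7.8, 152.0)]
        obs = [
            HSQCPeak("A40", "C2H2", 7.81, 152.1),
            HSQCPeak("A40", "C2H2", 7.79, 151.9),
        ]
        assert match_peaks(ref, obs)[("A40", "C2H2")] == "overlapped"


class TestCspProfile:
    def test_unperturbed_profile_is_null(self):
        ref = reference_peaks()
        profile = csp_profile(ref, ref)
        assert all(v == 0.0 for v in profile.csp.values())
        assert profile.significant_residues == set()

    def test_planted_site_is_exactly_significant(self, site_residues, rng):
        ref = reference_peaks()
        perturbed = []
        for p in ref:
            if p.residue in site_residues:
                perturbed.append(shift(p, dh=0.05, dc=0.4))  # 10x background
            else:
                perturbed.append(shift(p, dh=rng.normal(0, 0.002), dc=rng.normal(0, 0.02)))
        profile = csp_profile(ref, perturbed)
        assert profile.significant_residues == site_residues

    def test_overlapped_residue_excluded_from_threshold(self, site_residues):
        ref = reference_peaks()
        perturbed = [
            shift(p, dh=0.05, dc=0.4) if p.residue in site_residues else p for p in ref
        ]
        # duplicate C22's peak so it cannot be quantified
        extra = [p for p in perturbed if p.residue == "C22"][0]
        perturbed.append(shift(extra, dh=0.005))
        profile = csp_profile(ref, perturbed)
        assert profile.status["C22"] == "overlapped"
        assert "C22" not in profile.csp
        assert profile.significant_residues == site_residues

    def test_significance_invariant_to_residue_order(self, site_residues, rng):
        ref = reference_peaks()
        perturbed = [
            shift(p, dh=0.06, dc=0.5) if p.residue in site_residues else p for p in ref
        ]
        p1 = csp_profile(ref, perturbed)
        order = rng.permutation(len(ref))
        p2 = csp_profile([ref[i] for i in order], [perturbed[i] for i in order])
        assert p1.significant_residues == p2.significant_residues
        assert p1.significance_threshold == pytest.approx(p2.significance_threshold)


class TestBindingSiteMapping:
    def test_junction_dicing_site_localization(self, site_residues):
        ref = reference_peaks()
        perturbed = [
            shift(p, dh=0.05, dc=0.4) if p.residue in site_residues else p for p in ref
        ]
        report = map_binding_site(
            csp_profile(ref, perturbed), mir31.REGION_ANNOTATION
        )
        assert report["significant_residues"] == ["A40", "A41", "C42", "C43"]
        assert report["modal_region"] == "dicing_site/junction"
        assert not report["non_specific"]

    def test_global_perturbation_flagged_non_specific(self, rng):
        # 10-fold ligand excess moving every resonance
        ref = reference_peaks()
        perturbed = [
            shift(p, dh=rng.uniform(0.03, 0.1), dc=rng.uniform(0.3, 0.8)) for p in ref
        ]
        report = map_binding_site(
            csp_profile(ref, perturbed), mir31.REGION_ANNOTATION
        )
        assert report["non_specific"]

    def test_empty_profile_gives_empty_report(self):
        ref = reference_peaks()
        report = map_binding_site(csp_profile(ref, ref), mir31.REGION_ANNOTATION)
        assert report["region_counts"] == {}
        assert report["modal_region"] is None

    def test_unannotated_residue_bucketed(self, site_residues):
        ref = reference_peaks()
        perturbed = [
            shift(p, dh=0.05, dc=0.4) if p.residue in site_residues else p for p in ref
        ]
        report = map_binding_site(csp_profile(ref, perturbed), {})
        assert report["region_counts"] == {"unannotated": 4}


class TestFractionBound:
    @pytest.mark.parametrize(
        "vb, vf, expected", [(1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_values(self, vb, vf, expected):
        assert fraction_bound(vb, vf) == expected

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            fraction_bound(0.0, 0.0)


class TestKdIntermediate:
    X = np.array([0.0, 5, 10, 20, 40, 60, 80, 100.0])

    def test_noiseless_self_consistency(self):
        b = 1.0 * self.X / (29.10 + self.X)
        fit = fit_kd_intermediate(self.X, b)
        assert fit.kd == pytest.approx(29.10, rel=1e-3)
        assert fit.ns_slope == pytest.approx(0.0, abs=1e-5)

    def test_matches_grid_search_oracle_with_ns(self):
        """Brute-force (KD, NS) grid agrees with the least-squares fit."""
        kd_true, ns_true = 29.10, 0.002
        b = 0.9 * self.X / (kd_true + self.X) + ns_true * self.X

        def sse(kd, ns):
            model = 0.9 * self.X / (kd + self.X) + ns * self.X
            return np.sum((model - b) ** 2)

        kd_grid = np.arange(27.0, 31.0, 0.1)
        ns_grid = np.arange(0.0, 0.005, 1e-4)
        sses = np.array([[sse(k, s) for s in ns_grid] for k in kd_grid])
        ik, isl = np.unravel_index(np.argmin(sses), sses.shape)
        fit = fit_kd_intermediate(self.X, b)
        assert fit.kd == pytest.approx(kd_grid[ik], abs=0.1)
        assert fit.ns_slope == pytest.approx(ns_grid[isl], abs=1e-4)

    def test_flat_series_censored(self):
        fit = fit_kd_intermediate(self.X, np.zeros_like(self.X))
        assert fit.censored
        assert str(fit) == ">100"

    def test_requires_zero_point(self):
        with pytest.raises(ValueError):
            fit_kd_intermediate([1.0, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])


class TestKdFast:
    def test_noiseless_recovery(self):
        x = np.array([0.0, 5, 10, 20, 50, 100, 200.0])
        csp = 0.1 * x / (20.0 + x)
        fit = fit_kd_fast(x, csp)
        assert fit.kd == pytest.approx(20.0, rel=1e-6)

    def test_near_linear_growth_censored(self):
        # no saturation within 0-1000 µM: reported as ">1000"
        x = np.array([0.0, 50, 100, 250, 500, 750, 1000.0])
        csp = 0.2 * x / (5000.0 + x)
        fit = fit_kd_fast(x, csp)
        assert fit.censored
        assert str(fit) == ">1000"

    def test_missing_zero_point_rejected(self):
        with pytest.raises(ValueError):
            fit_kd_fast([5.0, 10, 20, 40], [0.01, 0.02, 0.03, 0.04])


class TestStdClassification:
    def test_signal_above_noise_is_binder(self):
        assert classify_std([10.0], noise_sd=1.0) == "binder"

    def test_no_signal_is_non_binder(self):
        assert classify_std([0.0, 0.0], noise_sd=1.0) == "non_binder"

    def test_no_proton_spectrum_untestable(self):
        assert classify_std([], noise_sd=1.0, has_proton_spectrum=False) == "untestable"


class TestDmsoControl:
    def test_identical_lists_pass(self):
        ref = reference_peaks()
        report = dmso_control_check(ref, ref)
        assert report["passed"] and report["max_csp_ppm"] == 0.0

    def test_shifted_residue_fails(self):
        ref = reference_peaks()
        dmso = [shift(p, dh=0.1) if p.residue == "A40" else p for p in ref]
        report = dmso_control_check(ref, dmso)
        assert not report["passed"]
        assert report["offending_residues"] == ["A40"]

    def test_boundary_is_inclusive(self):
        ref = reference_peaks()
        dmso = [shift(p, dh=0.02) if p.residue == "A40" else p for p in ref]
        assert dmso_control_check(ref, dmso)["passed"]
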