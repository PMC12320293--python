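"""FID assay analysis: dye-affinity fit, %FID statistic, classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hairpinscreen.fid import (
    BindingCurve,
    FIDPlate,
    FIDResult,
    PlateLayoutError,
    classify_displacement,
    fit_dye_affinity,
    flag_artifacts,
    one_site,
    percent_fid,
    run_fid_stage,
)
from hairpinscreen.io import Compound
from hairpinscreen.synthetic import SimConfig, gen_fid_plate

# 13 serial dilutions, 0-20 µM RNA in nM, as in the dye-affinity measurement
CURVE_X = np.array([0, 5, 10, 20, 40, 80, 160, 320, 640, 1250, 2500, 5000, 20000.0])


class TestDyeAffinity:
    def test_noiseless_recovery(self):
        y = one_site(CURVE_X, 1000.0, 458.0)
        fit = fit_dye_affinity(BindingCurve(CURVE_X, y))
        assert fit.kd == pytest.approx(458.0, rel=1e-6)
        assert fit.bmax == pytest.approx(1000.0, rel=1e-6)

    def test_half_saturation_identity(self):
        y = one_site(CURVE_X, 1000.0, 458.0)
        fit = fit_dye_affinity(BindingCurve(CURVE_X, y))
        assert one_site(np.array([fit.kd]), fit.bmax, fit.kd)[0] == pytest.approx(
            fit.bmax / 2.0
        )

    def test_fb01_is_kd_over_nine(self):
        # X at fraction bound 0.1 is KD/9; KD 458.1 nM gives the 50.9 nM
        # working concentration used in the screen
        y = one_site(CURVE_X, 1000.0, 458.1)
        fit = fit_dye_affinity(BindingCurve(CURVE_X, y), fraction=0.1)
        assert fit.fb01_conc == pytest.approx(50.9, abs=0.01)

    def test_parameter_recovery_under_noise(self, rng):
        """KD bias < 5% relative at 2% multiplicative noise, 200 replicates."""
        kds = []
        for _ in range(200):
            y = one_site(CURVE_X, 1000.0, 458.0) * rng.lognormal(
                sigma=0.02, size=len(CURVE_X)
            )
            kds.append(fit_dye_affinity(BindingCurve(CURVE_X, y)).kd)
        assert abs(np.mean(kds) - 458.0) / 458.0 < 0.05

    def test_rejects_short_or_narrow_curves(self):
        with pytest.raises(ValueError):
            fit_dye_affinity(BindingCurve([0, 1, 2], [0, 1, 2]))
        with pytest.raises(ValueError):
            fit_dye_affinity(BindingCurve([10, 20, 30, 40], [1, 2, 3, 4.0]))


class TestPercentFid:
    def test_boundaries_and_worked_example(self):
        assert percent_fid(1000.0, 1000.0) == 0.0
        assert percent_fid(0.0, 1000.0) == 100.0
        assert percent_fid(714.0, 1000.0) == pytest.approx(28.6)

    def test_negative_when_fluorescence_rises(self):
        assert percent_fid(1200.0, 1000.0) == pytest.approx(-20.0)

    def test_invalid_blank_raises(self):
        with pytest.raises(ValueError):
            percent_fid(100.0, 0.0)

    @given(
        f=st.floats(0.0, 1e5),
        f0=st.floats(1e-3, 1e5),
        c=st.floats(1e-3, 1e3),
    )
    def test_gain_invariance(self, f, f0, c):
        # scaling all RFU by a common detector gain leaves %FID unchanged
        assert percent_fid(c * f, c * f0) == pytest.approx(
            percent_fid(f, f0), rel=1e-9, abs=1e-9
        )


class TestClassification:
    @pytest.mark.parametrize(
        "reps, expected",
        [
            ([28.32, 28.88], "hit"),  # 28.6 ± 0.4 displacement
            ([5.69, 9.51], "no_change"),  # 7.6 ± 2.7
            ([6.33, 8.87], "no_change"),  # 7.6 ± 1.8
            ([-20.0, -22.0], "increase"),
            ([16.0, 14.0], "no_change"),  # one replicate inside the window
        ],
    )
    def test_window_rule(self, reps, expected):
        assert classify_displacement(reps) == expected

    def test_requires_duplicates(self):
        with pytest.raises(ValueError):
            classify_displacement([20.0])


class TestArtifactFlags:
    def make_result(self, classification="no_change"):
        return FIDResult("c1", [0.0, 0.0], 0.0, classification)

    def test_dye_interaction_flag(self):
        out = flag_artifacts(self.make_result(), 40.0, 0.0)
        assert out.artifact_flags == {"dye_interaction"}

    def test_no_flags_within_window(self):
        out = flag_artifacts(self.make_result(), 10.0, -12.0)
        assert out.artifact_flags == set()

    def test_flags_never_change_classification(self):
        out = flag_artifacts(self.make_result("increase"), 300.0, 40.0)
        assert out.classification == "increase"
        assert out.artifact_flags == {"dye_interaction", "rna_interaction"}

    def test_missing_control_warns_and_omits_flag(self):
        with pytest.warns(UserWarning):
            out = flag_artifacts(self.make_result(), None, 40.0)
        assert out.artifact_flags == {"rna_interaction"}


class TestPlateStage:
    def test_noiseless_plate_classifications(self):
        cfg = SimConfig(seed=11, noise_cv=0.0)
        compounds = [
            (Compound("strong", "c1ccccc1"), 5.0, 0.0),
            (Compound("inert", "c1ccccc1"), None, 0.0),
            (Compound("glow", "c1ccccc1"), None, 1500.0),
        ]
        results = {r.compound_id: r for r in run_fid_stage(gen_fid_plate(compounds, cfg))}
        assert results["strong"].classification == "hit"
        assert results["inert"].classification == "no_change"
        assert results["inert"].mean_percent_fid == pytest.approx(0.0, abs=1e-4)
        # autofluorescent non-binder: fluorescence rises and the dye control
        # exceeds the dye-only baseline (probable dye-binding artifact)
        assert results["glow"].classification == "increase"
        assert "dye_interaction" in results["glow"].artifact_flags

    def test_stage_equals_hand_computed_percent_fid(self):
        cfg = SimConfig(seed=11, noise_cv=0.0)
        plate = gen_fid_plate([(Compound("c", "C"), 20.0, 100.0)], cfg)
        results = run_fid_stage(plate)
        f0 = plate.rfu("blank").mean()
        expected = [percent_fid(f, f0) for f in plate.rfu("ligand", "c")]
        assert results[0].percent_fid_replicates == pytest.approx(expected)
        assert results[0].percent_fid_replicates[0] == pytest.approx(
            results[0].percent_fid_replicates[1]
        )

    def test_plate_without_blanks_rejected(self):
        cfg = SimConfig(seed=1, noise_cv=0.0)
        plate = gen_fid_plate([(Compound("c", "C"), None, 0.0)], cfg, n_blank=0)
        with pytest.raises(PlateLayoutError):
            run_fid_stage(plate)

    def test_binder_recovery_across_seeds(self):
        """Planted binders (KD <= dye-scale) and non-binders are recovered with
        >= 95% balanced accuracy at 2% plate noise across 100 seeds."""
        tp = tn = fp = fn = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, noise_cv=0.02)
            compounds = [
                (Compound("b1", "C"), 5.0, 0.0),
                (Compound("b2", "C"), 20.0, 0.0),
                (Compound("n1", "C"), None, 0.0),
                (Compound("n2", "C"), None, 0.0),
            ]
            for r in run_fid_stage(gen_fid_plate(compounds, cfg)):
                binder = r.compound_id.startswith("b")
                called = r.classification == "hit"
                tp += binder and called
                fn += binder and not called
                tn += (not binder) and (not called)
                fp += (not binder) and called
        balanced = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
        assert balanced >= 0.95


def test_plate_roundtrip_csv(tmp_path):
    cfg = SimConfig(seed=2, noise_cv=0.02)
    plate = gen_fid_plate([(Compound("c", "C"), 10.0, 0.0)], cfg)
    path = tmp_path / "plate.csv"
    plate.to_csv(path)
    again = FIDPlate.from_csv(path)
    assert np.allclose(again.wells["rfu"], plate.wells["rfu"])
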