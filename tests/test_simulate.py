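"""Synthetic cohort generator: determinism, calibration, noise model, phantom."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from petasym.kinetics import FrameSchedule, TimeActivityCurve, fit_srtm_nls_oracle
from petasym.simulate import (
    REFERENCE_REGION,
    CohortConfig,
    add_noise,
    cohort_to_frame,
    generate_cohort,
    generate_phantom_image,
    schedule_for_centre,
    simulate_reference_tac,
    simulate_subject_tacs,
)


def zero_asym(config: CohortConfig, pair_sd: float = 0.0) -> CohortConfig:
    return dataclasses.replace(
        config,
        asym_rel_diff_pct={r: 0.0 for r in config.asym_rel_diff_pct},
        pair_sd=pair_sd,
    )


class TestGenerateCohort:
    def test_default_cohort_counts(self):
        subjects, truth = generate_cohort(CohortConfig(seed=3))
        assert len(subjects) == 76
        centres = pd.Series([s.centre for s in subjects]).value_counts()
        assert centres["Manchester"] == 50 and centres["Turku"] == 26
        assert truth.params.subject_id.nunique() == 76

    def test_seeded_determinism_field_for_field(self, small_config):
        s1, t1 = generate_cohort(small_config)
        s2, t2 = generate_cohort(small_config)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1.params, t2.params)
        pd.testing.assert_frame_equal(t1.volumes, t2.volumes)

    def test_null_asymmetry_exact_equality(self, small_config):
        _, truth = generate_cohort(zero_asym(small_config))
        wide = truth.params.pivot_table(
            index=["subject_id", "region"], columns="side", values="DVR"
        )
        np.testing.assert_array_equal(wide["left"].to_numpy(), wide["right"].to_numpy())

    def test_dvr_bp_identity_exact(self, small_config):
        _, truth = generate_cohort(small_config)
        np.testing.assert_array_equal(
            truth.params.DVR.to_numpy(), truth.params.BP_ND.to_numpy() + 1.0
        )

    def test_injected_relative_difference_is_exact_without_pair_noise(self):
        config = dataclasses.replace(
            CohortConfig(n_per_centre={"Manchester": 5}, seed=9), pair_sd=0.0
        )
        _, truth = generate_cohort(config)
        wide = truth.params.pivot_table(
            index=["subject_id", "region"], columns="side", values="DVR"
        ).reset_index()
        for region, expected in config.asym_rel_diff_pct.items():
            grp = wide[wide.region == region]
            rel = 200.0 * (grp.right - grp.left) / (grp.left + grp.right)
            np.testing.assert_allclose(rel, expected, rtol=1e-12)

    def test_null_calibration_mean_difference(self):
        """Across subjects, mean(right - left) truth is 0 within 3 SE."""
        config = zero_asym(CohortConfig(seed=17), pair_sd=0.02)
        _, truth = generate_cohort(config)
        wide = truth.params.pivot_table(
            index=["subject_id", "region"], columns="side", values="DVR"
        )
        diff = (wide.right - wide.left).to_numpy()
        assert abs(diff.mean()) < 3 * 0.02 / np.sqrt(diff.size)

    def test_handedness_categories_and_unknowns_present(self):
        subjects, _ = generate_cohort(CohortConfig(seed=2))
        hands = {s.handedness for s in subjects}
        assert hands <= {"right", "left", "unknown"}
        assert "unknown" in hands  # Turku carries a ~31% unknown fraction

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_centre={"Manchester": -1})
        with pytest.raises(ValueError):
            CohortConfig(n_per_centre={"Manchester": 0, "Turku": 0})
        with pytest.raises(ValueError):
            CohortConfig(baseline_dvr={"grey_matter": -0.5})
        with pytest.raises(ValueError):
            CohortConfig(asym_rel_diff_pct={"grey_matter": 250.0})
        with pytest.raises(ValueError):
            CohortConfig(handedness_props={"Manchester": (0.5, 0.2, 0.2)})

    def test_cohort_frame_schema(self, small_config):
        subjects, _ = generate_cohort(small_config)
        df = cohort_to_frame(subjects)
        assert list(df.columns) == [
            "subject_id",
            "centre",
            "age",
            "sex",
            "handedness",
            "injected_activity_MBq",
            "body_weight_kg",
        ]
        assert (df.age > 0).all() and (df.body_weight_kg > 0).all()


class TestReferenceTac:
    def test_background_frame_is_zero(self, manchester):
        tac = simulate_reference_tac(manchester, 50.0, 0.05, 0.5)
        assert tac.values[0] == 0.0

    def test_peak_falls_in_frame_containing_closed_form_maximum(self, manchester):
        """Continuous peak of amp(e^-l1 t - e^-l2 t) is ln(l2/l1)/(l2-l1):
        on a uniform fine schedule the frame-averaged maximum falls in the
        frame containing that time; on the irregular clinical schedule (1-min
        frames abutting a 5-min frame at the peak) the maximising frame may
        only be adjacent, because averaging over the long frame dilutes it."""
        from petasym.kinetics import make_frame_schedule

        lam1, lam2 = 0.05, 0.5
        t_peak = np.log(lam2 / lam1) / (lam2 - lam1)
        assert t_peak == pytest.approx(5.117, abs=1e-3)

        uniform = make_frame_schedule([(60, 1.0)])
        tac = simulate_reference_tac(uniform, 50.0, lam1, lam2)
        k = int(np.argmax(tac.values))
        assert uniform.starts[k] <= t_peak <= uniform.ends[k]

        tac_m = simulate_reference_tac(manchester, 50.0, lam1, lam2)
        k = int(np.argmax(tac_m.values))
        assert manchester.starts[max(k - 1, 0)] <= t_peak <= manchester.ends[
            min(k + 1, manchester.n_frames - 1)
        ]

    def test_amplitude_linearity_exact(self, turku):
        a = simulate_reference_tac(turku, 25.0, 0.05, 0.5)
        b = simulate_reference_tac(turku, 50.0, 0.05, 0.5)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-14)

    def test_surge_shape_requires_lam2_greater(self, turku):
        with pytest.raises(ValueError):
            simulate_reference_tac(turku, 10.0, 0.5, 0.5)


class TestSubjectTacs:
    def _identity_config(self):
        return CohortConfig(
            n_per_centre={"Manchester": 1},
            baseline_dvr={"grey_matter": 1.0},
            asym_rel_diff_pct={"grey_matter": 0.0},
            vol_asym_rel_diff_pct={"grey_matter": 0.0},
            volume_ml={"grey_matter": 600.0},
            subject_sd=0.0,
            pair_sd=0.0,
            r1_mean=1.0,
            r1_sd=0.0,
            seed=5,
        )

    def test_identity_parameters_reproduce_reference(self, manchester, reference_tac):
        subjects, truth = generate_cohort(self._identity_config())
        tacs = simulate_subject_tacs(subjects[0], truth, manchester, reference_tac)
        np.testing.assert_allclose(
            tacs[("grey_matter", "left")].values, reference_tac.values, atol=1e-12
        )

    def test_zero_reference_gives_zero_targets(self, manchester):
        subjects, truth = generate_cohort(self._identity_config())
        zero = TimeActivityCurve(manchester, np.zeros(manchester.n_frames))
        tacs = simulate_subject_tacs(subjects[0], truth, manchester, zero)
        assert np.all(tacs[("grey_matter", "right")].values == 0.0)

    def test_missing_subject_rejected(self, manchester, reference_tac):
        subjects, truth = generate_cohort(self._identity_config())
        truth.params = truth.params[truth.params.subject_id == "nothing"]
        with pytest.raises(KeyError):
            simulate_subject_tacs(subjects[0], truth, manchester, reference_tac)

    def test_forward_oracle_round_trip(self, manchester, reference_tac):
        """Simulated TACs from known truth must be recoverable by the NLS
        oracle to 1e-3 relative (k2 excluded on the degenerate ridge)."""
        config = dataclasses.replace(
            self._identity_config(),
            baseline_dvr={"grey_matter": 1.2},
            r1_mean=1.2,
            k2_ref=0.10 / 1.2,  # target k2 = R1 * k2_ref = 0.10
        )
        subjects, truth = generate_cohort(config)
        row = truth.params.iloc[0]
        tacs = simulate_subject_tacs(subjects[0], truth, manchester, reference_tac)
        fit = fit_srtm_nls_oracle(tacs[(row.region, row.side)], reference_tac)
        assert fit.params.r1 == pytest.approx(row.R1, rel=1e-3)
        assert fit.params.bp_nd == pytest.approx(row.BP_ND, rel=1e-3)


class TestAddNoise:
    def test_zero_noise_identity(self, reference_tac):
        out = add_noise(reference_tac, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, reference_tac.values)

    def test_seeded_determinism(self, reference_tac):
        a = add_noise(reference_tac, 0.5, seed=42)
        b = add_noise(reference_tac, 0.5, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c = add_noise(reference_tac, 0.5, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_negative_alpha_rejected(self, reference_tac):
        with pytest.raises(ValueError):
            add_noise(reference_tac, -0.1, seed=0)

    def test_monte_carlo_sd_matches_formula(self):
        """sigma = alpha sqrt(value/duration): value 10, 5-min frames, alpha 1
        gives sqrt(2); checked over 10,000 independent frames."""
        n = 10_000
        starts = tuple(5.0 * i for i in range(n))
        ends = tuple(5.0 * (i + 1) for i in range(n))
        tac = TimeActivityCurve(FrameSchedule(starts, ends), np.full(n, 10.0))
        noisy = add_noise(tac, 1.0, seed=7)
        sd = float(np.std(noisy.values - tac.values, ddof=1))
        assert sd == pytest.approx(np.sqrt(2.0), rel=0.02)


class TestPhantom:
    def test_round_trip_and_threshold_rule(self):
        from petasym.roi import (
            RegionDefinition,
            binarize_probability_map,
            combine_region_labels,
            extract_region_tac,
        )

        config = CohortConfig(n_per_centre={"Manchester": 1}, seed=4)
        img, labels, pmap, legend, tacs, sched = generate_phantom_image(
            config, shell_value=0.49
        )
        gm = binarize_probability_map(pmap)
        assert not np.any(gm & (pmap < 0.5))  # 0.49 shell excluded
        for lbl, (region, side) in legend.items():
            mask = labels == lbl
            tac, vol = extract_region_tac(img, mask, 4.0, sched)
            key = (region, "bilateral" if region == REFERENCE_REGION else side)
            # voxel averaging of identical values is exact to the last ulp only
            np.testing.assert_allclose(tac.values, tacs[key].values, rtol=1e-14)
            assert vol == pytest.approx(int(mask.sum()) * 4.0**3 / 1000.0)

    def test_mirrored_blob_placement(self):
        config = CohortConfig(n_per_centre={"Manchester": 1}, seed=4)
        _, labels, _, legend, _, _ = generate_phantom_image(config)
        flipped = labels[::-1]
        for lbl, (region, side) in legend.items():
            if side == "left":
                twin = [k for k, v in legend.items() if v == (region, "right")][0]
                np.testing.assert_array_equal(flipped == lbl, labels == twin)

    def test_grid_too_small_rejected(self):
        config = CohortConfig(n_per_centre={"Manchester": 1}, seed=4)
        with pytest.raises(ValueError):
            generate_phantom_image(config, shape=(8, 8, 4))
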