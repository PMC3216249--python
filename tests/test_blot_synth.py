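import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mmrscreen import blot_synth as bs
from mmrscreen import densitometry as ds
from mmrscreen import presets

from conftest import gaussian_area


class TestStimulationMultiplier:
    def test_zero_dose_fresh_gives_unstimulated_fraction(self):
        p = bs.StimulationParams(pha_dose_ug=0.0, time_hr=48.0, E0_frac=0.05)
        assert bs.stimulation_multiplier(p, bs.CellType.FRESH_LYMPHOCYTE) == pytest.approx(0.05)

    def test_immortalized_ignores_dose(self):
        for dose in (0.0, 10.0):
            p = bs.StimulationParams(pha_dose_ug=dose)
            assert bs.stimulation_multiplier(p, bs.CellType.IMMORTALIZED_LYMPHOCYTE) == 1.0

    def test_cell_line_constitutive(self):
        p = bs.StimulationParams(pha_dose_ug=0.0, time_hr=0.0)
        assert bs.stimulation_multiplier(p, bs.CellType.CELL_LINE) == 1.0

    def test_monocyte_never_responds(self):
        for dose, t in [(0, 0), (10, 48), (100, 200)]:
            p = bs.StimulationParams(pha_dose_ug=dose, time_hr=t, E0_frac=0.05)
            assert bs.stimulation_multiplier(p, bs.CellType.MONOCYTE) == pytest.approx(0.05)

    def test_hand_computed_value(self):
        # E0 + (1-E0) * d/(d+K_d) * (1 - exp(-t/tau)) at d=10, t=48
        p = bs.StimulationParams(pha_dose_ug=10.0, time_hr=48.0, K_d=5.0, tau=24.0, E0_frac=0.05)
        expected = 0.05 + 0.95 * (10 / 15) * (1 - math.exp(-2.0))
        got = bs.stimulation_multiplier(p, bs.CellType.FRESH_LYMPHOCYTE)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            bs.StimulationParams(pha_dose_ug=-1.0)
        with pytest.raises(ValueError):
            bs.StimulationParams(time_hr=-0.5)

    @pytest.mark.parametrize("cell_type", list(bs.CellType))
    def test_monotone_in_dose_and_time(self, cell_type):
        doses = np.linspace(0, 50, 12)
        times = np.linspace(0, 120, 12)
        md = [
            bs.stimulation_multiplier(bs.StimulationParams(pha_dose_ug=d, time_hr=48), cell_type)
            for d in doses
        ]
        mt = [
            bs.stimulation_multiplier(bs.StimulationParams(pha_dose_ug=10, time_hr=t), cell_type)
            for t in times
        ]
        assert all(b >= a - 1e-15 for a, b in zip(md, md[1:]))
        assert all(b >= a - 1e-15 for a, b in zip(mt, mt[1:]))

    def test_fresh_multiplier_bounded(self):
        p = bs.StimulationParams(pha_dose_ug=1e6, time_hr=1e6, E0_frac=0.05)
        m = bs.stimulation_multiplier(p, bs.CellType.FRESH_LYMPHOCYTE)
        assert 0.05 <= m < 1.0


class TestSubjectSpec:
    def test_noncarrier_dosage_must_be_one(self):
        with pytest.raises(ValueError):
            bs.SubjectSpec("s", carrier_status=bs.CarrierStatus.NON_CARRIER, dosage_factor=0.5)

    def test_dosage_applies_to_mutated_protein_only(self):
        s = bs.SubjectSpec(
            "s", carrier_status=bs.CarrierStatus.MLH1_CARRIER, dosage_factor=0.5
        )
        assert s.abundance_mlh1 == pytest.approx(0.5)
        assert s.abundance_msh2 == pytest.approx(1.0)
        assert s.true_target_ratio == pytest.approx(0.5)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            bs.SubjectSpec("s", base_abundance_mlh1=-1.0)


class TestSimulateLane:
    def test_equal_abundances_give_equal_peaks(self, noiseless_blot, stim, cell_line_subject):
        profile, _ = bs.simulate_lane(cell_line_subject, stim, noiseless_blot)
        y = profile.intensities
        assert y[noiseless_blot.band_center_mlh1] == pytest.approx(
            y[noiseless_blot.band_center_msh2]
        )

    def test_doubling_load_doubles_net_integrals(self, noiseless_blot, stim, cell_line_subject):
        cfg = ds.DensitometryConfig.from_blot(noiseless_blot)
        nets = {}
        for load in (20.0, 40.0):
            blot = replace(noiseless_blot, protein_load_ug=load)
            profile, _ = bs.simulate_lane(cell_line_subject, stim, blot)
            pair = ds.measure_band_pair(profile, cfg)
            nets[load] = {p: m.net_density for p, m in pair.items()}
        for p in bs.Protein:
            assert nets[40.0][p] == pytest.approx(2.0 * nets[20.0][p], rel=1e-6)

    def test_half_dosage_halves_band_integral(self, noiseless_blot, stim):
        # closed-form Gaussian-area oracle: carrier MLH1 integral is
        # half the MSH2 integral when base abundances are equal
        subject = bs.SubjectSpec(
            "carrier",
            cell_type=bs.CellType.CELL_LINE,
            carrier_status=bs.CarrierStatus.MLH1_CARRIER,
            dosage_factor=0.5,
        )
        profile, truth = bs.simulate_lane(subject, stim, noiseless_blot)
        cfg = ds.DensitometryConfig.from_blot(noiseless_blot)
        pair = ds.measure_band_pair(profile, cfg)
        mlh1, msh2 = pair[bs.Protein.MLH1], pair[bs.Protein.MSH2]
        assert mlh1.net_density == pytest.approx(0.5 * msh2.net_density, rel=1e-3)
        oracle = gaussian_area(
            truth["true_amplitude_mlh1"],
            noiseless_blot.band_sigma,
            mlh1.window,
            noiseless_blot.band_center_mlh1,
        )
        assert mlh1.net_density == pytest.approx(oracle, rel=1e-3)

    def test_linearity_net_integral_proportional_to_abundance(self, noiseless_blot, stim):
        cfg = ds.DensitometryConfig.from_blot(noiseless_blot)
        nets = []
        for ab in (0.25, 0.5, 1.0, 2.0):
            s = bs.SubjectSpec("s", cell_type=bs.CellType.CELL_LINE, base_abundance_mlh1=ab)
            profile, _ = bs.simulate_lane(s, stim, noiseless_blot)
            nets.append(ds.measure_band_pair(profile, cfg)[bs.Protein.MLH1].net_density)
        base = nets[2]
        for ab, net in zip((0.25, 0.5, 1.0, 2.0), nets):
            assert net == pytest.approx(ab * base, rel=1e-3)

    def test_overlapping_band_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            bs.BlotConfig(band_center_msh2=200, band_center_mlh1=210, band_sigma=4.0)


class TestSimulateBlotImage:
    def test_single_lane_column_sum_matches_profile(self, noiseless_blot, stim, cell_line_subject):
        image = bs.simulate_blot_image([(cell_line_subject, stim)], noiseless_blot)
        profile, _ = bs.simulate_lane(cell_line_subject, stim, noiseless_blot)
        lane = ds.extract_lane(image, cell_line_subject.subject_id)
        np.testing.assert_allclose(lane.intensities, profile.intensities, rtol=1e-9)

    def test_zero_lanes_rejected(self, default_blot):
        with pytest.raises(ValueError):
            bs.simulate_blot_image([], default_blot)

    def test_fig1a_control_panel_detectability(self, default_blot, fig1a_lanes):
        image = bs.simulate_blot_image(fig1a_lanes, default_blot)
        cfg = ds.DensitometryConfig.from_blot(default_blot)
        manifest = pd.DataFrame(
            {"sample_id": list(image.lanes), "lane_id": list(image.lanes)}
        )
        out = ds.quantify_sample(image, manifest, cfg)
        det = out.set_index(["sample_id", "protein"])["detectable"]
        assert det[("SW480", "MLH1")] and det[("SW480", "MSH2")]
        assert det[("HCT116", "MSH2")] and not det[("HCT116", "MLH1")]
        assert det[("LoVo", "MLH1")] and not det[("LoVo", "MSH2")]

    def test_fixed_seed_bit_identical(self, default_blot, stim, cell_line_subject):
        a = bs.simulate_blot_image([(cell_line_subject, stim)], default_blot)
        b = bs.simulate_blot_image([(cell_line_subject, stim)], default_blot)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.lanes == b.lanes


class TestDilutionSeries:
    def test_net_integrals_proportional_to_loads(self, noiseless_blot):
        image, truth = bs.simulate_dilution_series(noiseless_blot, [10.0, 20.0, 40.0])
        cfg = ds.DensitometryConfig.from_blot(noiseless_blot)
        nets = []
        for lane_id in image.lane_ids:
            pair = ds.measure_band_pair(ds.extract_lane(image, lane_id), cfg)
            nets.append(pair[bs.Protein.MLH1].net_density)
        assert nets[1] == pytest.approx(2 * nets[0], rel=1e-3)
        assert nets[2] == pytest.approx(4 * nets[0], rel=1e-3)

    def test_single_load_valid(self, default_blot):
        image, truth = bs.simulate_dilution_series(default_blot, [10.0])
        assert image.lane_ids == ["load_10"]
        assert len(truth) == 1

    @pytest.mark.parametrize("loads", [[], [0.0, 10.0], [-5.0]])
    def test_bad_loads_rejected(self, default_blot, loads):
        with pytest.raises(ValueError):
            bs.simulate_dilution_series(default_blot, loads)


class TestSimulateReplicates:
    def test_noiseless_replicates_identical(self):
        preset = bs.ReplicateNoisePreset(
            name="exact", ratio_mean=0.8, ratio_sd=0.0,
            blot=bs.BlotConfig(noise_sd=0.0),
        )
        t = bs.simulate_replicates("s", 4, preset, seed=0)
        assert t["ratio"].nunique() == 1
        assert t["ratio"].iloc[0] == pytest.approx(0.8, rel=1e-3)

    def test_min_reps_enforced(self):
        with pytest.raises(ValueError):
            bs.simulate_replicates("s", 1, "table2-sw480", seed=0)

    def test_sw480_preset_mean_near_reported(self):
        means = [
            bs.simulate_replicates("SW480", 6, "table2-sw480", seed=s)["ratio"].mean()
            for s in range(30)
        ]
        assert 0.97 <= float(np.mean(means)) <= 1.0

    def test_seed_contract(self):
        a = bs.simulate_replicates("s", 6, "table2-wbc2", seed=1)
        b = bs.simulate_replicates("s", 6, "table2-wbc2", seed=2)
        c = bs.simulate_replicates("s", 6, "table2-wbc2", seed=1)
        assert not np.allclose(a["ratio"], b["ratio"])
        pd.testing.assert_frame_equal(a, c)

    def test_direct_mode_folds_above_one(self):
        preset = bs.ReplicateNoisePreset(
            name="wide", ratio_mean=1.0, ratio_sd=0.2, blot=bs.BlotConfig()
        )
        t = bs.simulate_replicates("s", 50, preset, seed=3, mode="direct")
        assert (t["ratio"] <= 1.0).all()
        assert (t["ratio"] > 0.0).all()


class TestSimulateCohort:
    def test_zero_prevalence_all_noncarrier(self):
        cfg = replace(presets.get_cohort_config("figure3"), carrier_prevalence=0.0)
        _, truth = bs.simulate_cohort(cfg)
        assert (truth["carrier_status"] == "non_carrier").all()
        # all target ratios from the non-carrier component (trunc [0.3, 1])
        assert truth["true_target_ratio"].between(0.3, 1.0).all()
        assert truth["true_target_ratio"].mean() == pytest.approx(0.97, abs=0.02)

    def test_full_prevalence_degenerate_carrier_component(self):
        cfg = replace(
            presets.get_cohort_config("figure3"),
            carrier_prevalence=1.0,
            carrier_ratio_sd=0.0,
        )
        _, truth = bs.simulate_cohort(cfg)
        assert (truth["carrier_status"] != "non_carrier").all()
        np.testing.assert_allclose(truth["true_target_ratio"], 0.81, rtol=1e-12)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            replace(presets.get_cohort_config("figure3"), carrier_prevalence=1.5)

    def test_target_ratios_respect_floor_and_cap(self):
        cfg = replace(presets.get_cohort_config("figure3"), n_subjects=500, seed=7)
        _, truth = bs.simulate_cohort(cfg)
        assert truth["true_target_ratio"].between(cfg.ratio_floor, 1.0).all()

    def test_prefix_stability_adding_subjects(self):
        # growing the cohort must not reshuffle earlier subjects
        cfg = presets.get_cohort_config("figure3")
        _, small = bs.simulate_cohort(replace(cfg, n_subjects=20))
        _, big = bs.simulate_cohort(replace(cfg, n_subjects=50))
        pd.testing.assert_frame_equal(small, big.iloc[:20].reset_index(drop=True))

    def test_carrier_fraction_matches_prevalence_at_large_n(self):
        cfg = replace(presets.get_cohort_config("figure3"), n_subjects=10_000, seed=11)
        _, truth = bs.simulate_cohort(cfg)
        frac = (truth["carrier_status"] != "non_carrier").mean()
        se = math.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac - 0.25) < 3 * se

    def test_reproducible_from_config(self):
        cfg = presets.get_cohort_config("figure3")
        _, a = bs.simulate_cohort(cfg)
        _, b = bs.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
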