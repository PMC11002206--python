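"""Synthetic trace, trajectory and cohort generation contracts."""

import numpy as np
import pandas as pd
import pytest

from mitoflux.errors import SpecError
from mitoflux.synthetic_data import (
    BASELINE_ENDPOINTS,
    CohortSpec,
    TraceSpec,
    cohort_trace_specs,
    group_mean,
    make_cohort,
    make_stool_observations,
    make_trace,
    make_weight_trajectory,
)


class TestMakeTrace:
    def test_same_seed_identical_traces(self):
        spec = TraceSpec(kind="respirometry", noise_sd=2.0, seed=9)
        a, b = make_trace(spec), make_trace(spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        base = dict(kind="respirometry", noise_sd=2.0)
        a = make_trace(TraceSpec(seed=1, **base))
        b = make_trace(TraceSpec(seed=2, **base))
        assert not np.array_equal(a.values, b.values)

    def test_infeasible_oxygen_depletion_rejected(self):
        with pytest.raises(SpecError, match="infeasible"):
            make_trace(TraceSpec(kind="respirometry", state3_flux=1000.0,
                                 volume_ml=2.0, o2_start=100.0))

    def test_event_schedule_must_increase(self):
        with pytest.raises(SpecError):
            TraceSpec(kind="respirometry",
                      events=((360.0, "homogenate"), (60.0, "ADP")))

    def test_fluorescence_slope_implements_calibration_model(self):
        spec = TraceSpec(kind="fluorescence", j_h2o2=2.0,
                         calibration_slope=10.0, volume_ml=2.0)
        tr = make_trace(spec)
        slope_au_min = (tr.values[-1] - tr.values[0]) / (
            (tr.times[-1] - tr.times[0]) / 60.0)
        assert slope_au_min == pytest.approx(10.0 * 2.0 / 2.0, rel=1e-9)


class TestWeightTrajectory:
    def test_male_disease_nadir_8_percent(self):
        traj = make_weight_trajectory("male", "IBD", 250.0)
        w = traj.set_index("day")["body_weight_g"]
        assert min(w[2], w[3]) == pytest.approx(0.92 * 250.0)

    def test_female_disease_nadir_11_percent(self):
        traj = make_weight_trajectory("female", "IBD", 200.0)
        w = traj.set_index("day")["body_weight_g"]
        assert min(w[2], w[3]) == pytest.approx(0.89 * 200.0)

    def test_control_never_below_baseline(self):
        traj = make_weight_trajectory("female", "control", 200.0)
        assert (traj["body_weight_g"] >= 200.0 - 1e-9).all()

    def test_disease_recovers_by_day_seven(self):
        traj = make_weight_trajectory("male", "IBD", 250.0)
        w = traj.set_index("day")["body_weight_g"]
        assert w[7] >= 250.0

    def test_mt_arm_halves_female_nadir(self):
        traj = make_weight_trajectory("female", "IBD", 200.0,
                                      mt_arm="MT_prophylaxis")
        w = traj.set_index("day")["body_weight_g"]
        assert min(w[2], w[3]) == pytest.approx(0.945 * 200.0)


class TestMakeCohort:
    def test_zero_cv_equals_group_means(self):
        spec = CohortSpec(n_per_group=3, cv=0.0, seed=1)
        cohort = make_cohort(spec)
        row = cohort[cohort["group"] == "female_IBD"].iloc[0]
        assert row["rcr"] == pytest.approx(2.0)  # 4.0 * 0.5
        assert row["leak_complex_i"] == pytest.approx(2.0)  # 1.0 * 2
        male_ctrl = cohort[cohort["group"] == "male_control"].iloc[0]
        assert male_ctrl["complex_iv"] == pytest.approx(8.0 * 0.7)
        assert male_ctrl["cs_activity"] == pytest.approx(500.0)

    def test_seeding_contract(self):
        a = make_cohort(CohortSpec(seed=1))
        b = make_cohort(CohortSpec(seed=1))
        c = make_cohort(CohortSpec(seed=2))
        pd.testing.assert_frame_equal(a, b)
        assert not a[list(BASELINE_ENDPOINTS)].equals(c[list(BASELINE_ENDPOINTS)])
        # identical design labels regardless of seed
        assert list(a["group"]) == list(c["group"])

    def test_sample_means_converge_to_spec_means(self):
        """Lognormal endpoint noise is mean-one: at n = 10^4 the sample
        mean sits within 2 % of the latent group mean."""
        spec = CohortSpec(
            n_per_group=10_000, cv=0.15, seed=3,
            groups=(("female", "IBD", "none"),),
        )
        cohort = make_cohort(spec)
        for ep in ("rcr", "leak_complex_i", "cs_activity"):
            target = group_mean(spec, ep, "female", "IBD", "none")
            assert cohort[ep].mean() == pytest.approx(target, rel=0.02)

    def test_empty_group_list_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(groups=())

    def test_trace_specs_consistent_with_endpoints(self):
        """Quantifying an animal's synthetic traces reproduces its rcr
        and leak endpoint values."""
        from mitoflux.respirometry import segment_states
        from mitoflux.ros_leak import fit_calibration, h2o2_rate, \
            percent_electron_leak
        from mitoflux.signals import SlopeMode, estimate_slope

        cohort = make_cohort(CohortSpec(n_per_group=2, cv=0.15, seed=4))
        specs = cohort_trace_specs(cohort, volume_ml=2.1,
                                   calibration_slope=10.0)
        cal = fit_calibration([0, 1, 2], [0, 10, 20])
        for _, row in cohort.iterrows():
            pair = specs[row["animal_id"]]
            states = segment_states(make_trace(pair["respirometry"]))
            assert states.rcr == pytest.approx(row["rcr"], rel=1e-6)
            fl = make_trace(pair["fluorescence"])
            fslope = estimate_slope(fl, window=states.state3.source_window,
                                    mode=SlopeMode.FIXED_WINDOW)
            j = h2o2_rate(fslope.slope, cal, 2.1)
            leak = percent_electron_leak(j, states.state3.j_o2)
            assert leak == pytest.approx(row["leak_complex_i"], rel=1e-6)


class TestStoolObservations:
    def test_disease_peak_has_bloody_diarrhea(self):
        cohort = make_cohort(CohortSpec(n_per_group=1, cv=0.0))
        daily = make_stool_observations(cohort, seed=0)
        ibd_peak = daily[(daily["animal_id"].isin(
            cohort[cohort["disease"] == "IBD"]["animal_id"]))
            & (daily["day"] == 2)]
        assert (ibd_peak["stool_consistency"] == "diarrhea").all()
        assert (ibd_peak["stool_color"] == "bloody").all()
        ctrl = daily[daily["animal_id"].isin(
            cohort[cohort["disease"] == "control"]["animal_id"])]
        assert (ctrl["stool_consistency"] == "normal").all()
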