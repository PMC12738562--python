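"""Generator tests: cohort calibration, effect structure, forward model and
phantom contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from guancest import synthetic_data as sd
from guancest.atlas import ALL_REGIONS, CSF_CODE, RIGHT_OFFSET, REGION_CODES


# --------------------------------------------------------------------- cohort

def test_offset_schedule_structure():
    offs = np.asarray(sd.DEFAULT_OFFSETS_PPM)
    assert offs.size == 53
    assert offs[0] == 200.0
    body = offs[1:]
    assert body.max() == 8.0 and body.min() == -2.2
    assert np.allclose(np.diff(body), -0.2)


def test_cohort_sizes_and_determinism():
    a = sd.simulate_clinical_cohort(25, 24, seed=1)
    b = sd.simulate_clinical_cohort(25, 24, seed=1)
    assert len(a) == 49
    assert sd.cohort_to_frame(a).equals(sd.cohort_to_frame(b))
    c = sd.simulate_clinical_cohort(25, 24, seed=2)
    assert not sd.cohort_to_frame(a).equals(sd.cohort_to_frame(c))


def test_cohort_age_within_sampling_error():
    pwpd = [r for r in sd.simulate_clinical_cohort(25, 24, seed=1)
            if r.group == "PwPD"]
    ages = np.array([r.age_years for r in pwpd])
    assert abs(ages.mean() - 67.7) < 3 * 7.1 / math.sqrt(25)


def test_degenerate_single_patient_cohort():
    (rec,) = sd.simulate_clinical_cohort(1, 0, seed=7)
    assert rec.group == "PwPD"
    assert rec.affected_side in ("left", "right")
    assert rec.updrs_total == rec.updrs1 + rec.updrs2 + rec.updrs3 + rec.updrs4
    assert 1 <= rec.hy_stage <= 5


def test_rejects_empty_cohort():
    with pytest.raises(ValueError):
        sd.simulate_clinical_cohort(0, 0, seed=1)


def test_hc_records_flag_pd_fields_not_applicable():
    hc = [r for r in sd.simulate_clinical_cohort(2, 5, seed=3) if r.group == "HC"]
    for r in hc:
        assert r.affected_side == "none"
        assert r.updrs3 == -1 and math.isnan(r.duration_years)


def test_updrs3_sampler_large_n_calibration():
    """Monte-Carlo: the motor-score marginal converges to the truncated
    normal it is configured as (scipy oracle), and sits near the nominal
    cohort mean (the truncation shifts it by ~+0.5)."""
    n = 10000
    cohort = sd.simulate_clinical_cohort(n, 0, seed=3)
    u3 = np.array([r.updrs3 for r in cohort], dtype=float)
    mu, s = 31.24, 14.04
    a = -mu / s
    m_true = sps.truncnorm.mean(a, np.inf, loc=mu, scale=s)
    sd_true = sps.truncnorm.std(a, np.inf, loc=mu, scale=s)
    assert abs(u3.mean() - m_true) < 3 * sd_true / math.sqrt(n)
    assert abs(u3.std() - sd_true) < 3 * sd_true / math.sqrt(2 * n)
    assert abs(u3.mean() - 31.24) < 1.0
    assert (u3 >= 0).all()


def test_hy_stage_distribution_median_and_range():
    cohort = sd.simulate_clinical_cohort(5000, 0, seed=9)
    hy = np.array([r.hy_stage for r in cohort])
    assert np.median(hy) == 2
    assert hy.min() == 1 and hy.max() == 4


# ------------------------------------------------------------- effect truth

def test_zero_effect_config_returns_baseline_exactly():
    eff = sd.EffectConfig(
        regions={"Ca": sd.RegionEffect(1.82, 1.72)}, between_subject_sd_pct=0.0,
        between_subject_sd_amide_pct=0.0)
    subj = sd.SubjectRecord("hc1", "HC", 65.0, "F", "none")
    g, a = sd.true_regional_signal(subj, "Ca", eff, seed=0)
    assert g == 1.82 and a == 1.72


def test_linear_mode_patient_population_mean_at_center_severity():
    """baseline 1.82 + delta -0.15 evaluated at the cohort-average motor
    score gives the patient mean 1.67."""
    eff = sd.EffectConfig(
        regions={"Ca": sd.RegionEffect(1.82, 1.72, group_delta_guan_pct=-0.15,
                                       slope_guan_pct_per_point=-0.01)},
        between_subject_sd_pct=0.0)
    subj = sd.SubjectRecord("pd1", "PwPD", 67.0, "M", "left",
                            updrs3=int(round(eff.severity_center)))
    g, _ = sd.true_regional_signal(subj, "Ca", eff, seed=0)
    assert g == pytest.approx(1.67, abs=0.01 * abs(31 - 31.24) + 1e-12)


def test_unknown_region_rejected():
    subj = sd.SubjectRecord("x", "HC", 60.0, "F", "none")
    with pytest.raises(KeyError):
        sd.true_regional_signal(subj, "nope", sd.EffectConfig(), seed=0)


def test_copula_rho_bound_enforced():
    with pytest.raises(ValueError):
        sd.EffectConfig(regions={"Ca": sd.RegionEffect(1.8, 1.7, copula_rho=1.0)})


def test_copula_kendall_tau_converges_to_target():
    """Large-sample check of tau = (2/pi) arcsin(rho) through the generator's
    own copula construction (integer-rounded severity marginal included)."""
    eff = sd.EffectConfig(association_mode="copula")
    sample = sd.severity_association_sample("TH-IML", 50000, eff, seed=5)
    tau = sps.kendalltau(sample.guan_pct, sample.updrs3).statistic
    assert abs(tau - (-0.44)) < 0.01


def test_scalar_copula_path_matches_vectorized_distribution():
    """true_regional_signal (per subject) and the vectorized sampler draw
    from the same copula: compare means/correlations at moderate n."""
    eff = sd.EffectConfig(association_mode="copula")
    n = 4000
    sample = sd.severity_association_sample("TH-IML", n, eff, seed=21)
    cohort = sd.simulate_clinical_cohort(n, 0, seed=21)
    ss = np.random.SeedSequence(22)
    vals = []
    for subj, child in zip(cohort, ss.spawn(n)):
        g, _ = sd.true_regional_signal(subj, "TH-IML", eff,
                                       np.random.default_rng(child))
        vals.append((g, subj.updrs3))
    vals = np.asarray(vals)
    t1 = sps.kendalltau(vals[:, 0], vals[:, 1]).statistic
    t2 = sps.kendalltau(sample.guan_pct, sample.updrs3).statistic
    assert abs(t1 - t2) < 0.05
    assert abs(vals[:, 0].mean() - sample.guan_pct.mean()) < 0.02


# ------------------------------------------------------------ forward model

def test_empty_pool_list_rejected(acq_noise_free):
    with pytest.raises(ValueError):
        sd.synthesize_zspectrum([], acq_noise_free)


def test_zero_amplitude_pools_give_unit_spectrum(acq_noise_free):
    z = sd.synthesize_zspectrum(sd.default_pools(0.0, 0.0, 0.0)[3:], acq_noise_free)
    assert np.allclose(z, 1.0)


def test_spectrum_length_matches_schedule(acq):
    z = sd.synthesize_zspectrum(sd.default_pools(0.018, 0.017), acq, seed=0)
    assert z.shape == (53,)


def test_single_pool_center_value_closed_form(acq_noise_free):
    pool = sd.PoolParams(2.0, 0.018, 0.5)
    z = sd.synthesize_zspectrum([pool], acq_noise_free)
    offs = np.asarray(acq_noise_free.offsets_ppm)
    assert z[offs == 2.0][0] == pytest.approx(1.0 - 0.018, abs=1e-12)


def test_reference_offset_stays_normalized(acq_noise_free):
    z = sd.synthesize_zspectrum(sd.default_pools(0.02, 0.02), acq_noise_free)
    offs = np.asarray(acq_noise_free.offsets_ppm)
    assert 0.999 <= z[np.abs(offs) >= 50][0] <= 1.001


def test_negative_noise_rejected():
    with pytest.raises(ValueError):
        sd.AcquisitionConfig(noise_sd=-0.1)


def test_duplicate_offsets_rejected():
    with pytest.raises(ValueError):
        sd.AcquisitionConfig(offsets_ppm=(200.0, 2.0, 2.0, 1.0))


# ----------------------------------------------------------------- phantom

@pytest.fixture(scope="module")
def phantom_pair(acq):
    cohort = sd.simulate_clinical_cohort(1, 1, seed=11)
    eff = sd.EffectConfig()
    phs = dict(sd.iter_phantoms(cohort, eff, acq, seed=11,
                                regions=("Ca", "TH-IML"), blob_shape=(3, 3, 3)))
    return cohort, phs


def test_phantom_labels_mirrored(phantom_pair):
    _, phs = phantom_pair
    ph = next(iter(phs.values()))
    lab = ph.label_volume
    for region in ("Ca", "TH-IML"):
        code = REGION_CODES[region]
        left = np.argwhere(lab == code)
        right = np.argwhere(lab == code + RIGHT_OFFSET)
        assert left.size and right.size
        mirrored = left.copy()
        mirrored[:, 0] = lab.shape[0] - 1 - mirrored[:, 0]
        assert {tuple(r) for r in mirrored} == {tuple(r) for r in right}


def test_phantom_csf_low_intensity_and_water_spectrum(phantom_pair, offsets):
    _, phs = phantom_pair
    ph = next(iter(phs.values()))
    csf = ph.label_volume == CSF_CODE
    assert csf.any()
    assert ph.t1w_intensity[csf].max() < 0.25 * np.percentile(ph.t1w_intensity, 99)
    # near-pure water: far-downfield signal close to the reference level
    spec = ph.cest_4d[csf][0]
    ref = spec[np.abs(offsets) >= 50][0]
    downfield = spec[(offsets <= 8) & (offsets >= 5)]
    assert np.all(downfield / ref > 0.95)


def test_phantom_offset_axis_and_determinism(small_cohort, acq):
    eff = sd.EffectConfig()
    a = sd.build_subject_phantom(small_cohort[0], eff, acq, seed=5,
                                 regions=("Ca",), blob_shape=(3, 3, 3))
    b = sd.build_subject_phantom(small_cohort[0], eff, acq, seed=5,
                                 regions=("Ca",), blob_shape=(3, 3, 3))
    assert a.cest_4d.shape[3] == 53
    np.testing.assert_array_equal(a.cest_4d, b.cest_4d)
    np.testing.assert_array_equal(a.spgr_low, b.spgr_low)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_empty_cohort_phantom_rejected(acq):
    with pytest.raises(ValueError):
        sd.build_phantom([], sd.EffectConfig(), acq, seed=1)


def test_hemispheres_carry_identical_truth(phantom_pair, offsets):
    """Region truth is hemisphere-symmetric: mean spectra agree up to noise."""
    _, phs = phantom_pair
    ph = next(iter(phs.values()))
    code = REGION_CODES["Ca"]
    left = ph.cest_4d[ph.label_volume == code].mean(axis=0)
    right = ph.cest_4d[ph.label_volume == code + RIGHT_OFFSET].mean(axis=0)
    assert np.allclose(left, right, atol=5e-3 * 1000)
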