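"""Feature correctness: hand values, oracle equivalence, invariances."""

from __future__ import annotations

import numpy as np
import pytest

import oracles
from emgmh.features import (ALL_FEATURES, FEATURE_SETS, FEATURE_WIDTHS,
                            FeatureParams, ar_to_cepstrum, burg_ar,
                            channel_features, complexity_features,
                            expand_names, extract_matrix,
                            frequency_domain_features, higuchi_fd,
                            maximum_fractal_length, model_coefficient_features,
                            multiwindow_features, power_spectrum,
                            time_domain_features)

FS = 1925.93
P0 = FeatureParams()


# ---------------------------------------------------------------------------
# hand-arithmetic examples

def test_time_domain_hand_values():
    p = FeatureParams(zc_threshold=0.0, myop_threshold=0.4)
    assert time_domain_features(np.array([1.0, -2.0, 3.0]), p)["MAV"] == pytest.approx(2.0)
    assert time_domain_features(np.array([1.0, -1.0, 1.0, -1.0]), p)["ZC"] == 3
    td = time_domain_features(np.array([0.0, 1.0, 3.0, 2.0]), p)
    assert td["WL"] == pytest.approx(4.0)
    assert td["AAC"] == pytest.approx(4.0 / 3.0)
    td = time_domain_features(np.array([0.1, 0.5, 0.9]), p)
    assert td["MYOP"] == pytest.approx(2.0 / 3.0)


def test_mavs_sign_on_ramp_and_constant():
    const = multiwindow_features(np.ones(99), P0)
    assert const["MAVS__1"] == pytest.approx(0.0)
    assert const["MAVS__2"] == pytest.approx(0.0)
    ramp = multiwindow_features(np.linspace(0.1, 2.0, 99), P0)
    assert ramp["MAVS__1"] > 0 and ramp["MAVS__2"] > 0


def test_mhw_on_ones_equals_window_energy():
    x = np.ones(90)
    got = multiwindow_features(x, P0)["MHW"]
    expected = oracles.mhw(list(x), 3)
    assert got == pytest.approx(expected, abs=1e-12)


def test_mfl_hand_values():
    assert maximum_fractal_length(np.array([0.0, 1.0])) == pytest.approx(0.0)
    x = np.random.default_rng(0).standard_normal(200)
    assert maximum_fractal_length(10 * x) == pytest.approx(
        maximum_fractal_length(x) + 1.0)


def test_pure_sinusoid_spectral_landmarks():
    t = np.arange(4096) / FS
    x = np.sin(2 * np.pi * 100.0 * t)
    fd = frequency_domain_features(x, FS, P0)
    df = FS / x.size
    for key in ("MNF", "MDF", "PKF"):
        assert abs(fd[key] - 100.0) <= df, key
    assert fd["PSR"] >= 0.95


def test_white_noise_frequency_ratio_matches_bandwidth_ratio():
    # E[FR] for white noise = (split - 0) / (nyquist - split)
    accs = []
    for seed in range(100):
        x = np.random.default_rng(seed).standard_normal(512)
        accs.append(frequency_domain_features(x, FS, P0)["FR"])
    expected = P0.fr_split / (FS / 2 - P0.fr_split)
    assert np.mean(accs) == pytest.approx(expected, rel=0.10)


def test_cc4_hand_recursion():
    rho = np.array([0.5, -0.25, 0.1, 0.05])
    got = ar_to_cepstrum(-rho, 4)
    a = [0.0, -0.5, 0.25, -0.1, -0.05]
    c1 = -a[1]
    c2 = -a[2] - (1 - 1 / 2) * a[1] * c1
    c3 = -a[3] - ((1 - 1 / 3) * a[1] * c2 + (1 - 2 / 3) * a[2] * c1)
    c4 = -a[4] - ((1 - 1 / 4) * a[1] * c3 + (1 - 2 / 4) * a[2] * c2
                  + (1 - 3 / 4) * a[3] * c1)
    np.testing.assert_allclose(got, [c1, c2, c3, c4], atol=1e-15)


def test_ar_recovery_and_white_noise():
    rng = np.random.default_rng(42)
    a_true = [0.5, -0.25]
    x = np.zeros(4000)
    eps = rng.standard_normal(4000)
    for i in range(2, 4000):
        x[i] = a_true[0] * x[i - 1] + a_true[1] * x[i - 2] + eps[i]
    est = burg_ar(x, 2)
    np.testing.assert_allclose(est, a_true, atol=0.05)
    w = burg_ar(rng.standard_normal(4000), 2)
    assert np.all(np.abs(w) < 3 / np.sqrt(4000))


def test_entropy_orders_sawtooth_below_noise():
    votes = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(400)
        saw = np.tile(np.linspace(-1, 1, 20), 20)
        saw = saw / saw.std() * noise.std()
        c_saw = complexity_features(saw, P0, ("ApEn",))["ApEn"]
        c_noise = complexity_features(noise, P0, ("ApEn",))["ApEn"]
        votes += c_saw < c_noise
    assert votes == 20


# ---------------------------------------------------------------------------
# oracle equivalence: all 42 features vs brute-force references

def _oracle_all(x, fs, p):
    xl = list(x)
    zc_t = p.threshold("zc", x)
    out = {
        "MAV": oracles.mav(xl), "MMAV1": oracles.mmav1(xl), "MMAV2": oracles.mmav2(xl),
        "RMS": oracles.rms(xl), "VAR": oracles.var(xl), "WL": oracles.wl(xl),
        "AAC": oracles.aac(xl), "DASDV": oracles.dasdv(xl),
        "LOG": oracles.log_detector(xl),
        "ZC": oracles.zc(xl, zc_t), "SSC": oracles.ssc(xl, p.threshold("ssc", x)),
        "WAMP": oracles.wamp(xl, p.threshold("wamp", x)),
        "MYOP": oracles.myop(xl, p.threshold("myop", x)),
        "KURT": oracles.kurt(xl), "SKEW": oracles.skew(xl),
        "MTW": oracles.mtw(xl), "MHW": oracles.mhw(xl),
        "HFD": oracles.higuchi(xl, p.hfd_kmax), "DFA": oracles.dfa(x, p.dfa_n_scales),
        "MFL": oracles.mfl(xl),
    }
    for j, v in enumerate(oracles.mavs(xl), start=1):
        out[f"MAVS__{j}"] = v
    freqs, pxx = oracles.periodogram_dft(xl, fs)
    out.update(oracles.spectral_features(freqs, pxx, p.psr_halfband, p.fr_split))
    r = p.entropy_r_mult * x.std()
    out["ApEn"] = oracles.apen(x, p.entropy_m, r)
    out["SampleEn"] = oracles.sampen(x, p.entropy_m, r)
    for j, v in enumerate(oracles.burg(xl, 2), start=1):
        out[f"AR2__{j}"] = v
    ar4 = oracles.burg(xl, 4)
    for j, v in enumerate(ar4, start=1):
        out[f"AR4__{j}"] = v
    for j, v in enumerate(oracles.cepstrum_from_ar(ar4, 4), start=1):
        out[f"CC4__{j}"] = v
    return out


def test_all_features_match_oracles_on_random_segments(rng):
    """Frozen contract: every feature equals its brute-force reference
    within 1e-9 on random segments."""
    features = tuple(f for f in ALL_FEATURES
                     if f not in ("MSA", "MSD", "MSF", "MSS", "MNPPS"))
    n_segments = 100
    for i in range(n_segments):
        n = int(rng.integers(200, 320))
        x = rng.standard_normal(n) * float(rng.uniform(0.5, 3.0))
        got = channel_features(x, FS, P0, features)
        want = _oracle_all(x, FS, P0)
        for name, val in want.items():
            assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-9), (name, i)


# ---------------------------------------------------------------------------
# invariance catalogue

_LINEAR = ("MAV", "RMS", "WL", "DASDV")
_INVARIANT = ("ZC", "MYOP", "HFD", "DFA", "ApEn", "SampleEn", "KURT", "SKEW",
              "MNF", "MDF", "PKF")


def test_scale_covariance_catalogue(rng):
    c = 3.7
    x = rng.standard_normal(400)
    feats = _LINEAR + _INVARIANT + ("MFL",)
    base = channel_features(x, FS, P0, feats)
    scaled = channel_features(c * x, FS, P0, feats)
    for f in _LINEAR:
        assert scaled[f] == pytest.approx(c * base[f], rel=1e-9), f
    for f in _INVARIANT:
        assert scaled[f] == pytest.approx(base[f], rel=1e-7), f
    assert scaled["MFL"] == pytest.approx(base["MFL"] + np.log10(c), abs=1e-9)


def test_time_reversal_invariance(rng):
    x = rng.standard_normal(512)
    feats = ("MAV", "RMS", "VAR", "WL", "ZC", "WAMP", "MYOP",
             "MNF", "MDF", "PKF", "TTP", "PSR")
    fwd = channel_features(x, FS, P0, feats)
    rev = channel_features(x[::-1].copy(), FS, P0, feats)
    for f in feats:
        assert fwd[f] == pytest.approx(rev[f], rel=1e-9), f


# ---------------------------------------------------------------------------
# registry, matrix assembly, degenerate inputs

def test_feature_set_registry_is_exact():
    assert FEATURE_SETS["FS1"] == ("MAV", "SSC", "WL", "ZC")
    assert FEATURE_SETS["FS2"] == ("RMS", "AR2")
    assert FEATURE_SETS["FS3"] == ("MSA", "MSF", "MSS", "MNPPS", "MSD")
    assert FEATURE_SETS["FS4"] == ("MFL", "MYOP")
    assert FEATURE_SETS["FS5"] == ("LOG", "DASDV", "MYOP", "MAVS", "PSR",
                                   "AR4", "ApEn", "MFL", "MSD")
    assert FEATURE_SETS["FS5opt"] == ("PSR", "MFL", "MSD")
    assert len(ALL_FEATURES) == 42
    assert sum(FEATURE_WIDTHS.values()) == 50


def test_matrix_dimensions_follow_expansion_rule(small_segments):
    m1 = extract_matrix(small_segments[:4], feature_list="FS1")
    feat_cols = [c for c in m1.columns if "__" in c]
    assert len(feat_cols) == 4 * 7 == 28
    m2 = extract_matrix(small_segments[:4], feature_list="FS2")
    assert len([c for c in m2.columns if "__" in c]) == (1 + 2) * 7 == 21


def test_empty_segment_list_yields_header_only():
    m = extract_matrix([], feature_list="FS1")
    assert len(m) == 0
    assert len([c for c in m.columns if "__" in c]) == 28


def test_degenerate_segments_produce_sentinels():
    const = np.zeros(512)
    fd = frequency_domain_features(const, FS, P0)
    assert all(np.isnan(v) for v in fd.values())
    mc = model_coefficient_features(const, P0)
    assert all(np.isnan(v) for v in mc.values())
    assert np.isnan(maximum_fractal_length(const))


def test_errors_on_short_segments():
    with pytest.raises(ValueError):
        time_domain_features(np.array([1.0]), P0)
    with pytest.raises(ValueError):
        frequency_domain_features(np.ones(10), FS, P0)
    with pytest.raises(ValueError):
        multiwindow_features(np.ones(2), P0)


def test_expand_names_widths():
    names = expand_names(("MAV", "AR4", "MAVS"))
    assert names == ["MAV", "AR4__1", "AR4__2", "AR4__3", "AR4__4",
                     "MAVS__1", "MAVS__2"]
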