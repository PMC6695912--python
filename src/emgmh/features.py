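"""The 42 sEMG features and the feature-set registry.

Every feature is computed per channel over the whole motion segment, giving
one value (or one block of coefficients) per muscle.  Definitions follow the
standard formulations in the myoelectric-control feature literature; each is
frozen against an independently coded brute-force oracle in the test suite.

Multi-coefficient features expand to one dimension per coefficient:
AR2 (2), AR4 (4), CC4 (4), MAVS (K-1 = 2).  Columns are named
``<channel>__<feature>`` or ``<channel>__<feature>__<i>``, channel-major.

Degenerate segments (all-zero, constant) yield NaN sentinels; rows with any
missing cell are flagged, and imputation is left to the classification stage
(per-fold training-column medians).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from ._entropy import approximate_entropy, sample_entropy
from .io import ID_COLUMNS, LABEL_COLUMN
from .preprocessing import MotionSegment
from .spikes import detect_spikes, spike_shape_features


@dataclass(frozen=True)
class FeatureParams:
    """Tunable feature parameters; threshold ``None`` means 0.01 x segment RMS."""

    zc_threshold: float | None = None
    ssc_threshold: float | None = None
    wamp_threshold: float | None = None
    myop_threshold: float | None = None
    relative_threshold: float = 0.01  # fraction of segment RMS used when None
    k_windows: int = 3
    entropy_m: int = 2
    entropy_r_mult: float = 0.2
    hfd_kmax: int = 8
    dfa_n_scales: int = 10
    ar_orders: tuple[int, int] = (2, 4)
    cc_order: int = 4
    psd_method: str = "periodogram"  # or "welch"
    psr_halfband: float = 10.0
    fr_split: float = 100.0
    spike_amplitude: str = "peak-to-trough"  # or "baseline-to-peak"

    def __post_init__(self) -> None:
        if self.k_windows < 2:
            raise ValueError("k_windows must be >= 2")
        if self.entropy_m < 1:
            raise ValueError("entropy_m must be >= 1")

    def threshold(self, which: str, x: np.ndarray) -> float:
        v = getattr(self, f"{which}_threshold")
        if v is not None:
            return v
        rms = float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0
        return self.relative_threshold * rms


# ---------------------------------------------------------------------------
# feature registry

FEATURE_WIDTHS: dict[str, int] = {
    "MAV": 1, "MMAV1": 1, "MMAV2": 1, "RMS": 1, "VAR": 1, "WL": 1, "AAC": 1,
    "DASDV": 1, "LOG": 1, "ZC": 1, "SSC": 1, "WAMP": 1, "MYOP": 1,
    "KURT": 1, "SKEW": 1,
    "MAVS": 2, "MTW": 1, "MHW": 1,
    "MNF": 1, "MDF": 1, "PKF": 1, "MNP": 1, "TTP": 1,
    "SM1": 1, "SM2": 1, "SM3": 1, "FR": 1, "PSR": 1, "VCF": 1,
    "MSA": 1, "MSD": 1, "MSF": 1, "MSS": 1, "MNPPS": 1,
    "AR2": 2, "AR4": 4, "CC4": 4,
    "ApEn": 1, "SampleEn": 1, "HFD": 1, "DFA": 1, "MFL": 1,
}

ALL_FEATURES: tuple[str, ...] = tuple(FEATURE_WIDTHS)
assert len(ALL_FEATURES) == 42

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS1": ("MAV", "SSC", "WL", "ZC"),
    "FS2": ("RMS", "AR2"),
    "FS3": ("MSA", "MSF", "MSS", "MNPPS", "MSD"),
    "FS4": ("MFL", "MYOP"),
    "FS5": ("LOG", "DASDV", "MYOP", "MAVS", "PSR", "AR4", "ApEn", "MFL", "MSD"),
    "FS5opt": ("PSR", "MFL", "MSD"),
    "all42": ALL_FEATURES,
}

_TIME_DOMAIN = ("MAV", "MMAV1", "MMAV2", "RMS", "VAR", "WL", "AAC", "DASDV",
                "LOG", "ZC", "SSC", "WAMP", "MYOP", "KURT", "SKEW")
_FREQ_DOMAIN = ("MNF", "MDF", "PKF", "MNP", "TTP", "SM1", "SM2", "SM3",
                "FR", "PSR", "VCF")
_SPIKE = ("MSA", "MSD", "MSF", "MSS", "MNPPS")


# ---------------------------------------------------------------------------
# time domain

def time_domain_features(x: np.ndarray, p: FeatureParams) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("segment too short for time-domain features")
    ax = np.abs(x)
    dx = np.diff(x)
    adx = np.abs(dx)

    # MMAV weighting, index i = 1..N
    i = np.arange(1, n + 1)
    w1 = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    w2 = np.ones(n)
    w2[i < 0.25 * n] = 4 * i[i < 0.25 * n] / n
    w2[i > 0.75 * n] = 4 * (n - i[i > 0.75 * n]) / n

    rms = float(np.sqrt(np.mean(x * x)))
    zc_t = p.threshold("zc", x)
    ssc_t = p.threshold("ssc", x)
    wamp_t = p.threshold("wamp", x)
    myop_t = p.threshold("myop", x)

    zc = int(np.sum((x[:-1] * x[1:] < 0) & (adx >= zc_t)))
    mid, lft, rgt = x[1:-1], x[:-2], x[2:]
    ssc = int(np.sum(((mid - lft) * (mid - rgt) > 0)
                     & (np.maximum(np.abs(mid - lft), np.abs(mid - rgt)) >= ssc_t)))

    with np.errstate(divide="ignore"):
        floored = np.maximum(ax, 1e-12 * rms if rms > 0 else 0.0)
        log_det = float(np.exp(np.mean(np.log(floored)))) if rms > 0 else np.nan

    sd = x.std()
    return {
        "MAV": float(ax.mean()),
        "MMAV1": float(np.mean(w1 * ax)),
        "MMAV2": float(np.mean(w2 * ax)),
        "RMS": rms,
        "VAR": float(np.sum(x * x) / (n - 1)),
        "WL": float(adx.sum()),
        "AAC": float(adx.sum() / (n - 1)),
        "DASDV": float(np.sqrt(np.sum(dx * dx) / (n - 1))),
        "LOG": log_det,
        "ZC": float(zc),
        "SSC": float(ssc),
        "WAMP": float(np.sum(adx >= wamp_t)),
        "MYOP": float(np.mean(ax >= myop_t)),
        "KURT": float(stats.kurtosis(x, fisher=False)) if sd > 0 else np.nan,
        "SKEW": float(stats.skew(x)) if sd > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# multi-window

def _trapezoid_window(m: int, ramp: float = 0.25) -> np.ndarray:
    """Flat-top trapezoid with linear ramps over the first/last ``ramp`` fraction."""
    w = np.ones(m)
    k = max(1, int(round(ramp * m)))
    up = (np.arange(1, k + 1)) / k
    w[:k] = up
    w[-k:] = up[::-1]
    return w


def multiwindow_features(x: np.ndarray, p: FeatureParams) -> dict[str, float]:
    """MAVS (K-1 between-window MAV slopes), MTW, MHW (mean windowed energy)."""
    x = np.asarray(x, dtype=float)
    k = p.k_windows
    if x.size < k:
        raise ValueError("segment shorter than the number of windows")
    parts = np.array_split(x, k)
    mavs = [float(np.mean(np.abs(part))) for part in parts]
    out: dict[str, float] = {}
    for j in range(k - 1):
        out[f"MAVS__{j + 1}"] = mavs[j + 1] - mavs[j]
    mtw = [float(np.sum((_trapezoid_window(part.size) * part) ** 2)) for part in parts]
    mhw = [float(np.sum((np.hamming(part.size) * part) ** 2)) for part in parts]
    out["MTW"] = float(np.mean(mtw))
    out["MHW"] = float(np.mean(mhw))
    return out


# ---------------------------------------------------------------------------
# frequency domain

def power_spectrum(x: np.ndarray, fs: float, p: FeatureParams) -> tuple[np.ndarray, np.ndarray]:
    if p.psd_method == "welch":
        return sps.welch(x, fs=fs, nperseg=min(1024, x.size), detrend="constant")
    return sps.periodogram(x, fs=fs, window="boxcar", detrend="constant")


def frequency_domain_features(x: np.ndarray, fs: float, p: FeatureParams) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("segment too short for spectral features (need >= 64 samples)")
    f, pxx = power_spectrum(x, fs, p)
    ttp = float(pxx.sum())
    if ttp <= 0:
        return {k: np.nan for k in _FREQ_DOMAIN}
    sm1 = float(np.sum(pxx * f))
    sm2 = float(np.sum(pxx * f**2))
    sm3 = float(np.sum(pxx * f**3))
    cum = np.cumsum(pxx)
    mdf = float(f[np.searchsorted(cum, ttp / 2.0)])
    pk = int(np.argmax(pxx))
    pkf = float(f[pk])
    psr = float(pxx[np.abs(f - pkf) <= p.psr_halfband].sum() / ttp)
    low = float(pxx[f < p.fr_split].sum())
    high = float(pxx[f >= p.fr_split].sum())
    return {
        "MNF": sm1 / ttp,
        "MDF": mdf,
        "PKF": pkf,
        "MNP": float(pxx.mean()),
        "TTP": ttp,
        "SM1": sm1,
        "SM2": sm2,
        "SM3": sm3,
        "FR": low / high if high > 0 else np.nan,
        "PSR": psr,
        "VCF": sm2 / ttp - (sm1 / ttp) ** 2,
    }


# ---------------------------------------------------------------------------
# model coefficients

def burg_ar(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method AR coefficients, prediction convention
    x(n) = sum_k a_k x(n-k) + e(n)."""
    from statsmodels.regression.linear_model import burg

    rho, _ = burg(np.asarray(x, dtype=float), order=order, demean=True)
    return np.asarray(rho, dtype=float)


def ar_to_cepstrum(a_poly: np.ndarray, order: int) -> np.ndarray:
    """Cepstral coefficients of 1/A(z), A(z) = 1 + sum a_k z^-k.

    c_1 = -a_1;  c_p = -a_p - sum_{m=1}^{p-1} (1 - m/p) a_m c_{p-m}.
    """
    a = np.zeros(order + 1)
    a[1: len(a_poly) + 1] = a_poly[:order]
    c = np.zeros(order + 1)
    c[1] = -a[1]
    for p_ in range(2, order + 1):
        acc = 0.0
        for m in range(1, p_):
            acc += (1.0 - m / p_) * a[m] * c[p_ - m]
        c[p_] = -a[p_] - acc
    return c[1:]


def model_coefficient_features(x: np.ndarray, p: FeatureParams) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    o2, o4 = p.ar_orders
    if x.size < 10 * max(o2, o4, p.cc_order):
        raise ValueError("segment too short for AR estimation")
    out: dict[str, float] = {}
    if x.std() == 0:
        for name, width in (("AR2", o2), ("AR4", o4), ("CC4", p.cc_order)):
            for j in range(width):
                out[f"{name}__{j + 1}"] = np.nan
        return out
    ar2 = burg_ar(x, o2)
    ar4 = burg_ar(x, o4)
    cc4 = ar_to_cepstrum(-ar4, p.cc_order)  # polynomial coeffs a_k = -rho_k
    for j, v in enumerate(ar2):
        out[f"AR2__{j + 1}"] = float(v)
    for j, v in enumerate(ar4):
        out[f"AR4__{j + 1}"] = float(v)
    for j, v in enumerate(cc4):
        out[f"CC4__{j + 1}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# complexity / fractal

def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi's fractal dimension: slope of log L(k) vs log(1/k)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ks = np.arange(1, kmax + 1)
    lk = np.empty(ks.size)
    for idx, k in enumerate(ks):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            if sub.size < 2:
                continue
            norm = (n - 1) / ((sub.size - 1) * k)
            lengths.append(np.sum(np.abs(np.diff(sub))) * norm / k)
        lk[idx] = np.mean(lengths)
    if np.any(lk <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def dfa_exponent(x: np.ndarray, n_scales: int = 10) -> float:
    """Detrended fluctuation analysis exponent (linear detrending)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 16:
        return np.nan
    profile = np.cumsum(x - x.mean())
    scales = np.unique(np.round(
        np.exp(np.linspace(np.log(4), np.log(n // 4), n_scales))
    ).astype(int))
    scales = scales[scales >= 4]
    flucts = []
    for s in scales:
        n_boxes = n // s
        segs = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        # per-box linear detrend
        f2 = 0.0
        for seg in segs:
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            f2 += np.mean(resid**2)
        flucts.append(np.sqrt(f2 / n_boxes))
    flucts = np.asarray(flucts)
    if np.any(flucts <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(scales), np.log(flucts), 1)
    return float(slope)


def maximum_fractal_length(x: np.ndarray) -> float:
    """MFL = log10 of the curve length at the smallest scale."""
    wl2 = float(np.sum(np.diff(np.asarray(x, dtype=float)) ** 2))
    if wl2 <= 0:
        return np.nan
    return float(np.log10(np.sqrt(wl2)))


def complexity_features(x: np.ndarray, p: FeatureParams,
                        names: tuple[str, ...] = ("ApEn", "SampleEn", "HFD", "DFA", "MFL"),
                        ) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    r = p.entropy_r_mult * x.std()
    if "ApEn" in names:
        out["ApEn"] = approximate_entropy(x, p.entropy_m, r) if r > 0 else np.nan
    if "SampleEn" in names:
        out["SampleEn"] = sample_entropy(x, p.entropy_m, r) if r > 0 else np.nan
    if "HFD" in names:
        out["HFD"] = higuchi_fd(x, p.hfd_kmax)
    if "DFA" in names:
        out["DFA"] = dfa_exponent(x, p.dfa_n_scales)
    if "MFL" in names:
        out["MFL"] = maximum_fractal_length(x)
    return out


# ---------------------------------------------------------------------------
# per-channel dispatch and matrix assembly

def expand_names(features: tuple[str, ...] | list[str]) -> list[str]:
    """Expand feature names to per-dimension names (AR4 -> AR4__1..AR4__4)."""
    out = []
    for f in features:
        w = FEATURE_WIDTHS[f]
        if w == 1:
            out.append(f)
        else:
            out.extend(f"{f}__{j + 1}" for j in range(w))
    return out


def channel_features(
    x: np.ndarray,
    fs: float,
    p: FeatureParams,
    features: tuple[str, ...],
    baseline: np.ndarray | None = None,
) -> dict[str, float]:
    """Compute the requested features on one channel; lazy per feature group."""
    wanted = set(features)
    out: dict[str, float] = {}
    if wanted & set(_TIME_DOMAIN):
        td = time_domain_features(x, p)
        out.update({k: v for k, v in td.items() if k in wanted})
    if wanted & {"MAVS", "MTW", "MHW"}:
        mw = multiwindow_features(x, p)
        for k, v in mw.items():
            base = k.split("__")[0]
            if base in wanted:
                out[k] = v
    if wanted & set(_FREQ_DOMAIN):
        fd = frequency_domain_features(x, fs, p)
        out.update({k: v for k, v in fd.items() if k in wanted})
    if wanted & {"AR2", "AR4", "CC4"}:
        mc = model_coefficient_features(x, p)
        for k, v in mc.items():
            if k.split("__")[0] in wanted:
                out[k] = v
    comp = tuple(wanted & {"ApEn", "SampleEn", "HFD", "DFA", "MFL"})
    if comp:
        out.update(complexity_features(x, p, comp))
    if wanted & set(_SPIKE):
        if baseline is None or baseline.size == 0:
            sf = {k: np.nan for k in _SPIKE}
        else:
            train = detect_spikes(x, baseline, fs)
            sf = spike_shape_features(train)
        out.update({k: v for k, v in sf.items() if k in wanted})
    return out


def extract_matrix(
    segments: list[MotionSegment],
    p: FeatureParams | None = None,
    feature_list: tuple[str, ...] | str = "all42",
) -> pd.DataFrame:
    """One row per segment; per-channel feature columns, channel-major.

    Values are the raw per-limb feature values: no cross-limb normalisation
    or adjustment is applied, so healthy and injured limbs of one patient
    remain directly comparable.
    """
    p = p or FeatureParams()
    if isinstance(feature_list, str):
        feature_list = FEATURE_SETS[feature_list]
    per_channel = expand_names(feature_list)

    rows = []
    channels: list[str] | None = None
    for seg in segments:
        channels = seg.channel_names
        row: dict[str, object] = {k: seg.meta.get(k) for k in ID_COLUMNS}
        row[LABEL_COLUMN] = seg.meta.get("label")
        for ci, ch in enumerate(seg.channel_names):
            base = seg.baseline[:, ci] if seg.baseline is not None else None
            try:
                vals = channel_features(
                    seg.samples[:, ci], seg.sampling_rate, p, tuple(feature_list), base
                )
            except ValueError:  # degenerate segment (too short): sentinels
                vals = {name: np.nan for name in per_channel}
            for name in per_channel:
                row[f"{ch}__{name}"] = vals[name]
        rows.append(row)

    if not rows:
        from .cohort import CHANNELS

        cols = ID_COLUMNS + [LABEL_COLUMN] + [
            f"{ch}__{name}" for ch in CHANNELS for name in per_channel
        ]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    feat_cols = [f"{ch}__{name}" for ch in (channels or []) for name in per_channel]
    df = df[ID_COLUMNS + [LABEL_COLUMN] + feat_cols]
    df["qc_missing"] = df[feat_cols].isna().any(axis=1)
    return df


def column_base_feature(col: str) -> str:
    """Map a matrix column name to its base feature (BB__AR4__2 -> AR4)."""
    parts = col.split("__")
    return parts[1] if len(parts) >= 2 else col
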