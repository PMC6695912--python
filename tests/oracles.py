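"""Independent brute-force reference implementations.

Every feature here is coded directly from its textbook formula, in the most
literal way possible (explicit loops, full distance matrices, direct DFT),
deliberately avoiding the vectorised/recursive routes the package uses.
The test suite freezes the package against these references.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# time domain

def mav(x):
    return sum(abs(v) for v in x) / len(x)


def mmav1(x):
    n = len(x)
    s = 0.0
    for i, v in enumerate(x, start=1):
        w = 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
        s += w * abs(v)
    return s / n


def mmav2(x):
    n = len(x)
    s = 0.0
    for i, v in enumerate(x, start=1):
        if i < 0.25 * n:
            w = 4.0 * i / n
        elif i > 0.75 * n:
            w = 4.0 * (n - i) / n
        else:
            w = 1.0
        s += w * abs(v)
    return s / n


def rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def var(x):
    return sum(v * v for v in x) / (len(x) - 1)


def wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def aac(x):
    return wl(x) / (len(x) - 1)


def dasdv(x):
    return math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)) / (len(x) - 1))


def log_detector(x):
    r = rms(x)
    floor = 1e-12 * r
    return math.exp(sum(math.log(max(abs(v), floor)) for v in x) / len(x))


def zc(x, threshold):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def ssc(x, threshold):
    count = 0
    for i in range(1, len(x) - 1):
        a = x[i] - x[i - 1]
        b = x[i] - x[i + 1]
        if a * b > 0 and max(abs(a), abs(b)) >= threshold:
            count += 1
    return count


def wamp(x, threshold):
    return sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) >= threshold)


def myop(x, threshold):
    return sum(1 for v in x if abs(v) >= threshold) / len(x)


def kurt(x):
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return m4 / m2**2


def skew(x):
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    return m3 / m2**1.5


# ---------------------------------------------------------------------------
# multi-window

def equal_splits(n, k):
    """Split points replicating numpy.array_split: first n % k parts longer."""
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    bounds = [0]
    for s in sizes:
        bounds.append(bounds[-1] + s)
    return bounds


def mavs(x, k=3):
    b = equal_splits(len(x), k)
    mavs_ = [mav(x[b[i]:b[i + 1]]) for i in range(k)]
    return [mavs_[i + 1] - mavs_[i] for i in range(k - 1)]


def hamming_window(m):
    return [0.54 - 0.46 * math.cos(2 * math.pi * i / (m - 1)) for i in range(m)]


def trapezoid_window(m, ramp=0.25):
    k = max(1, round(ramp * m))
    w = [1.0] * m
    for i in range(k):
        w[i] = (i + 1) / k
        w[m - 1 - i] = (i + 1) / k
    return w


def mhw(x, k=3):
    b = equal_splits(len(x), k)
    vals = []
    for i in range(k):
        part = x[b[i]:b[i + 1]]
        w = hamming_window(len(part))
        vals.append(sum((wi * v) ** 2 for wi, v in zip(w, part)))
    return sum(vals) / k


def mtw(x, k=3):
    b = equal_splits(len(x), k)
    vals = []
    for i in range(k):
        part = x[b[i]:b[i + 1]]
        w = trapezoid_window(len(part))
        vals.append(sum((wi * v) ** 2 for wi, v in zip(w, part)))
    return sum(vals) / k


# ---------------------------------------------------------------------------
# frequency domain (direct-DFT one-sided periodogram, boxcar, mean removed)

def periodogram_dft(x, fs):
    n = len(x)
    mu = sum(x) / n
    xd = [v - mu for v in x]
    n_freq = n // 2 + 1
    freqs = [fs * k / n for k in range(n_freq)]
    p = []
    for k in range(n_freq):
        re = sum(xd[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(xd[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        scale = 1.0 / (fs * n)
        val = scale * (re * re + im * im)
        if 0 < k < n_freq - 1 or (0 < k and n % 2 == 1):
            val *= 2.0
        p.append(val)
    return freqs, p


def spectral_features(freqs, p, psr_halfband=10.0, fr_split=100.0):
    ttp = sum(p)
    sm1 = sum(pi * f for pi, f in zip(p, freqs))
    sm2 = sum(pi * f**2 for pi, f in zip(p, freqs))
    sm3 = sum(pi * f**3 for pi, f in zip(p, freqs))
    cum = 0.0
    mdf = freqs[-1]
    for f, pi in zip(freqs, p):
        cum += pi
        if cum >= ttp / 2.0:
            mdf = f
            break
    pk = max(range(len(p)), key=lambda k: p[k])
    pkf = freqs[pk]
    psr = sum(pi for f, pi in zip(freqs, p) if abs(f - pkf) <= psr_halfband) / ttp
    low = sum(pi for f, pi in zip(freqs, p) if f < fr_split)
    high = sum(pi for f, pi in zip(freqs, p) if f >= fr_split)
    return {
        "MNF": sm1 / ttp, "MDF": mdf, "PKF": pkf,
        "MNP": ttp / len(p), "TTP": ttp,
        "SM1": sm1, "SM2": sm2, "SM3": sm3,
        "FR": low / high, "PSR": psr,
        "VCF": sm2 / ttp - (sm1 / ttp) ** 2,
    }


# ---------------------------------------------------------------------------
# model coefficients: textbook Burg recursion

def burg(x, order):
    """Burg's method, prediction convention x(n) = sum a_k x(n-k) + e."""
    x = [float(v) for v in x]
    mu = sum(x) / len(x)
    x = [v - mu for v in x]
    n = len(x)
    f = x[:]
    b = x[:]
    a = []
    for m in range(1, order + 1):
        num = sum(f[i] * b[i - 1] for i in range(m, n))
        den = sum(f[i] ** 2 for i in range(m, n)) + sum(b[i - 1] ** 2 for i in range(m, n))
        k = 2.0 * num / den
        a_new = [ai - k * aj for ai, aj in zip(a, reversed(a))] + [k]
        f, b = (
            [f[i] - k * b[i - 1] for i in range(m, n)],
            [b[i - 1] - k * f[i] for i in range(m, n)],
        )
        # re-align: f,b now start at index m; pad front to keep indexing simple
        f = [0.0] * m + f
        b = [0.0] * m + b
        a = a_new
    return a


def cepstrum_from_ar(rho, order):
    """c_1 = -a_1; c_p = -a_p - sum (1 - m/p) a_m c_{p-m}, with a = -rho."""
    a = [0.0] + [-r for r in rho]
    while len(a) < order + 1:
        a.append(0.0)
    c = [0.0] * (order + 1)
    c[1] = -a[1]
    for p in range(2, order + 1):
        c[p] = -a[p] - sum((1 - m / p) * a[m] * c[p - m] for m in range(1, p))
    return c[1:]


# ---------------------------------------------------------------------------
# entropies via full distance matrices (cdist route)

def _embed(x, m):
    return np.array([x[i:i + m] for i in range(len(x) - m + 1)])


def apen(x, m, r):
    x = np.asarray(x, float)

    def phi(mm):
        emb = _embed(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        c = (d <= r).sum(axis=1) / emb.shape[0]
        return np.mean(np.log(c))

    return phi(m) - phi(m + 1)


def sampen(x, m, r):
    x = np.asarray(x, float)
    n = len(x) - m  # both template lengths restricted to n vectors
    emb_m = _embed(x, m)[:n]
    emb_m1 = _embed(x, m + 1)
    db = cdist(emb_m, emb_m, metric="chebyshev")
    da = cdist(emb_m1, emb_m1, metric="chebyshev")
    iu = np.triu_indices(n, k=1)
    b = (db[iu] <= r).sum()
    a = (da[iu] <= r).sum()
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# fractal

def higuchi(x, kmax):
    x = [float(v) for v in x]
    n = len(x)
    ks, ls = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            lm = sum(abs(x[idx[j + 1]] - x[idx[j]]) for j in range(len(idx) - 1))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(lm * norm / k)
        ks.append(k)
        ls.append(sum(lengths) / len(lengths))
    lx = [math.log(1.0 / k) for k in ks]
    ly = [math.log(v) for v in ls]
    mx = sum(lx) / len(lx)
    my = sum(ly) / len(ly)
    return sum((a - mx) * (b - my) for a, b in zip(lx, ly)) / sum((a - mx) ** 2 for a in lx)


def dfa(x, n_scales=10):
    x = np.asarray(x, float)
    n = x.size
    prof = np.cumsum(x - x.mean())
    scales = np.unique(np.round(
        np.exp(np.linspace(np.log(4), np.log(n // 4), n_scales))).astype(int))
    scales = scales[scales >= 4]
    fl = []
    for s in scales:
        nb = n // s
        f2 = []
        for i in range(nb):
            seg = prof[i * s:(i + 1) * s]
            t = np.arange(s)
            coef = np.polyfit(t, seg, 1)
            f2.append(np.mean((seg - np.polyval(coef, t)) ** 2))
        fl.append(math.sqrt(sum(f2) / nb))
    lx = np.log(scales)
    ly = np.log(fl)
    return float(np.polyfit(lx, ly, 1)[0])


def mfl(x):
    return math.log10(math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1))))


# ---------------------------------------------------------------------------
# ReliefF by exhaustive enumeration

def relieff_brute(x, y, k):
    """Literal ReliefF: all instances sampled, range-normalised diffs."""
    x = np.asarray(x, float)
    y = np.asarray(y)
    n, d = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span = np.where(span == 0, 1.0, span)
    xn = (x - x.min(axis=0)) / span
    w = np.zeros(d)
    for i in range(n):
        dists = [(sum(abs(xn[i] - xn[j])), j) for j in range(n) if j != i]
        hits = sorted((dv, j) for dv, j in dists if y[j] == y[i])[:k]
        misses = sorted((dv, j) for dv, j in dists if y[j] != y[i])[:k]
        for f in range(d):
            for _, j in misses:
                w[f] += abs(xn[i, f] - xn[j, f]) / (n * k)
            for _, j in hits:
                w[f] -= abs(xn[i, f] - xn[j, f]) / (n * k)
    return w
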