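"""Independent brute-force oracles used by the test suite.

Everything here is coded directly from the definitions (explicit loops,
closed forms, exhaustive enumeration) and never calls the package's own
implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# feature formulas, by direct loops


def envelope_median(x: np.ndarray) -> float:
    """Median |analytic signal| built from the spectrum by hand."""
    x = np.asarray(x, float)
    if not np.any(x):
        return 0.0
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    analytic = np.fft.ifft(spec * h)
    return float(np.median(np.abs(analytic)))


def brute_time_amplitude_features(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, float)
    n = len(x)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / n
    mav = sum(abs(v) for v in x) / n
    med = float(np.median(np.abs(x)))
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = math.sqrt(var)
    th = 3.0 * sd
    pwra = sum(v * v for v in x) / n
    rms = math.sqrt(pwra)
    if sd > 0:
        akur = sum((v - mean) ** 4 for v in x) / ((n - 1) * sd**4)
        askw = sum((v - mean) ** 3 for v in x) / ((n - 1) * sd**3)
    else:
        akur = askw = float("nan")
    nl = envelope_median(x)
    ane = sum(x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, n - 1)) / (n - 2)
    zc = brute_deadband_crossings(x, nl) / n
    pks = brute_peak_count(x, th) / n
    return {
        "WL": wl, "ZC": zc, "PKS": pks, "MAV": mav, "MED": med, "TH": th,
        "RMS": rms, "AKUR": akur, "ASKW": askw, "NL": nl, "PWRA": pwra,
        "ANE": ane,
    }


def brute_deadband_crossings(x: np.ndarray, deadband: float) -> int:
    """Zero crossings whose flanking excursions both exceed +/-deadband."""
    count = 0
    last_sign = 0
    for v in x:
        if abs(v) > deadband:
            s = 1 if v > 0 else -1
            if last_sign != 0 and s != last_sign:
                count += 1
            last_sign = s
    return count


def brute_peak_count(x: np.ndarray, height: float) -> int:
    count = 0
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > height:
            count += 1
    return count


def brute_welch(x: np.ndarray, fs: int) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD, 1 s Hann windows, 50% overlap, density scaling, mean
    removed per window — coded as an explicit window loop."""
    x = np.asarray(x, float)
    nper = int(fs)
    step = nper // 2
    # periodic Hann: w[k] = 0.5 - 0.5 cos(2 pi k / N)
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)
    n_win = (len(x) - nper) // step + 1
    acc = None
    for w in range(n_win):
        seg = x[w * step : w * step + nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * win)
        p = (np.abs(spec) ** 2) / (fs * np.sum(win**2))
        p[1:] *= 2
        if nper % 2 == 0:
            p[-1] /= 2
        acc = p if acc is None else acc + p
    freqs = np.fft.rfftfreq(nper, 1 / fs)
    return freqs, acc / n_win


def brute_band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    return float(sum(p for f, p in zip(freqs, psd) if lo <= f < hi))


def brute_spectral_features(x: np.ndarray, fs: int) -> dict[str, float]:
    f_d, p_d = brute_welch(x, fs)
    absx = np.abs(x)
    f_r, p_r = brute_welch(absx - absx.mean(), fs)
    out = {}
    vhf = ((300, 1000), (1000, 2000), (2000, 3000))
    hf = ((70, 220), (220, 320))
    lf = ((1, 4), (4, 8), (8, 13), (13, 30), (30, 70))
    vhf_tot = brute_band_power(f_d, p_d, 300, 3000)
    for i, (lo, hi) in enumerate(vhf, 1):
        out[f"powVHFrel_{i}"] = brute_band_power(f_d, p_d, lo, hi) / vhf_tot
    env_tot = brute_band_power(f_r, p_r, 1, 320)
    for i, (lo, hi) in enumerate(hf, 1):
        out[f"powHFrel_{i}"] = brute_band_power(f_r, p_r, lo, hi) / env_tot
    for i, (lo, hi) in enumerate(lf, 1):
        out[f"powLFrel_{i}"] = brute_band_power(f_r, p_r, lo, hi) / env_tot
    return out


def brute_features(x: np.ndarray, fs: int) -> dict[str, float]:
    return {**brute_time_amplitude_features(x), **brute_spectral_features(x, fs)}


# ---------------------------------------------------------------------------
# COV retained run, by exhaustive enumeration


def brute_longest_clean_run(adjacency: np.ndarray) -> tuple[int, int]:
    """Enumerate every contiguous interval; keep the longest whose induced
    adjacency submatrix is all-zero, earliest start on ties."""
    A = np.asarray(adjacency, bool)
    m = A.shape[0]
    best, best_len = (0, 0), 1
    for i in range(m):
        for j in range(i, m):
            if not A[np.ix_(range(i, j + 1), range(i, j + 1))].any():
                if j - i + 1 > best_len:
                    best, best_len = (i, j), j - i + 1
    return best


# ---------------------------------------------------------------------------
# agreement and ANOVA closed forms


def kappa_closed_form(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) / n) * ((a + c) / n) + ((c + d) / n) * ((b + d) / n)
    return (po - pe) / (1 - pe)


def balanced_threeway_main_effect_F(
    y: np.ndarray, fa: np.ndarray, fb: np.ndarray, fc: np.ndarray, which: str
) -> float:
    """Main-effect F in a balanced full-factorial three-way layout with
    replication, from hand-coded sums of squares.

    In the balanced case type II sums of squares reduce to the classical
    between-level sums; the error term is the full-model residual.
    """
    y = np.asarray(y, float)
    factors = {"a": np.asarray(fa), "b": np.asarray(fb), "c": np.asarray(fc)}
    grand = y.mean()

    def ss_main(f):
        return sum(
            np.sum(f == lv) * (y[f == lv].mean() - grand) ** 2
            for lv in np.unique(f)
        )

    # residual: deviations from the full-cell means
    cells = {}
    for i in range(len(y)):
        key = (factors["a"][i], factors["b"][i], factors["c"][i])
        cells.setdefault(key, []).append(y[i])
    ss_err = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in cells.values())
    df_err = len(y) - len(cells)
    f = factors[which]
    df_main = len(np.unique(f)) - 1
    return (ss_main(f) / df_main) / (ss_err / df_err)
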