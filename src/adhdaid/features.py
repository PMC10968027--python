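"""The 33-scalar feature bank and feature-matrix assembly.

Thirty extractors (Hjorth parameters, sequential-variation and energy
measures, four entropies, amplitude statistics, a 4-coefficient
autoregressive model, and five EEG band powers plus the alpha/beta ratio)
yield 33 scalars per signal vector. Applied to the four representations of
every channel of a 19-channel segment this gives 33 x 4 x 19 = 2508
feature columns.

Conventions: variance/std/skewness/kurtosis are population (biased)
moments, kurtosis is non-excess; Shannon and log-energy entropies follow
the wavelet-entropy convention on the unit-norm sample sequence; Renyi
(alpha=2) and Tsallis (q=2) entropies use a 64-bin amplitude histogram;
AR coefficients are Yule-Walker estimates. Degenerate (zero-variance)
inputs map to defined sentinel values so downstream selection never sees
non-finite entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.linalg import solve_toeplitz

from .io_preprocess import Segment
from .mra import (DWTConfig, VMDConfig, REPRESENTATIONS, decompose_segments,
                  representation_fs)
from .montage import site_of

__all__ = [
    "FEATURE_NAMES", "BANDS", "FeatureMatrix",
    "hjorth_features", "amplitude_statistics",
    "energy_and_variation_features", "entropy_features",
    "ar_coefficients", "band_power_features",
    "extract_feature_vector", "build_feature_matrix",
]

_EPS = 1e-12

FEATURE_NAMES: tuple[str, ...] = (
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "lrssv", "mean_curve_length", "mean_energy", "mean_teager_energy",
    "median", "minimum", "maximum",
    "renyi_entropy", "shannon_entropy", "log_energy_entropy",
    "tsallis_entropy",
    "first_difference", "second_difference",
    "norm_first_difference", "norm_second_difference",
    "variance", "std", "skewness", "kurtosis",
    "ar_1", "ar_2", "ar_3", "ar_4",
    "bp_delta", "bp_theta", "bp_alpha", "bp_beta", "bp_gamma",
    "bp_ratio_alpha_beta",
    "mean",
)

#: canonical EEG band edges in Hz
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 60.0),
)


def hjorth_features(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    Activity is the signal variance; mobility the ratio of the first
    difference's RMS dispersion to the signal's; complexity the change of
    mobility under differencing. Zero-variance input returns (0, 0, 0).
    """
    x = np.asarray(x, dtype=float)
    var0 = np.var(x)
    if var0 <= 0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    var1 = np.var(d1)
    mobility = np.sqrt(var1 / var0)
    if var1 <= 0:
        return float(var0), float(mobility), 0.0
    var2 = np.var(np.diff(d1))
    complexity = np.sqrt(var2 / var1) / mobility
    return float(var0), float(mobility), float(complexity)


def amplitude_statistics(x: np.ndarray):
    """(median, min, max, variance, std, skewness, kurtosis, mean).

    Population moments; kurtosis is non-excess (Gaussian -> 3). A
    zero-variance input gets skewness = kurtosis = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d ** 2))
    if m2 > 0:
        skew = float(np.mean(d ** 3)) / m2 ** 1.5
        kurt = float(np.mean(d ** 4)) / m2 ** 2
    else:
        skew = kurt = 0.0
    return (float(np.median(x)), float(x.min()), float(x.max()),
            m2, float(np.sqrt(m2)), skew, kurt, mean)


def energy_and_variation_features(x: np.ndarray):
    """Sequential-variation and energy measures.

    Returns (lrssv, mean_curve_length, mean_energy, mean_teager_energy,
    first_difference, second_difference, norm_first_difference,
    norm_second_difference). lrssv is log10 of the root sum of squared
    first differences, floored at log10(eps) for constant signals; the
    normalised differences divide by the population std (0 when std is 0).
    """
    x = np.asarray(x, dtype=float)
    d1 = np.diff(x)
    lrssv = float(np.log10(max(np.sqrt(np.sum(d1 ** 2)), _EPS)))
    mcl = float(np.mean(np.abs(d1)))
    mean_energy = float(np.mean(x ** 2))
    teager = float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))
    first = mcl
    second = float(np.mean(np.abs(x[2:] - x[:-2])))
    sd = float(np.std(x))
    nf = first / sd if sd > 0 else 0.0
    ns = second / sd if sd > 0 else 0.0
    return lrssv, mcl, mean_energy, teager, first, second, nf, ns


def _histogram_p(x: np.ndarray, bins: int = 64) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins)
    return counts / counts.sum()


def entropy_features(x: np.ndarray, bins: int = 64,
                     renyi_alpha: float = 2.0, tsallis_q: float = 2.0):
    """(renyi, shannon, log_energy, tsallis) entropies.

    Shannon and log-energy follow the wavelet-entropy convention on the
    unit-L2-norm sample sequence s: shannon = -sum s_i^2 ln s_i^2,
    log_energy = sum ln s_i^2, with eps guarding zeros. Renyi and Tsallis
    are computed from a ``bins``-bin amplitude-histogram probability
    vector. An all-zero signal returns four zeros.
    """
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        return 0.0, 0.0, 0.0, 0.0
    s2 = (x / norm) ** 2
    s2g = np.maximum(s2, _EPS)
    shannon = float(-np.sum(s2 * np.log(s2g)))
    log_energy = float(np.sum(np.log(s2g)))
    p = _histogram_p(x, bins)
    sum_pa = float(np.sum(p ** renyi_alpha))
    renyi = float(np.log(max(sum_pa, _EPS)) / (1.0 - renyi_alpha))
    sum_pq = float(np.sum(p ** tsallis_q))
    tsallis = float((1.0 - sum_pq) / (tsallis_q - 1.0))
    return renyi, shannon, log_energy, tsallis


def ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Yule-Walker AR(order) coefficients a_i of x[n] = sum a_i x[n-i] + e.

    Degenerate (constant or too-short) input returns zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * order or np.var(x) <= 0:
        return np.zeros(order)
    d = x - x.mean()
    n = d.size
    # biased autocovariances r_0..r_order
    r = np.array([np.dot(d[: n - k], d[k:]) / n for k in range(order + 1)])
    if r[0] <= 0:
        return np.zeros(order)
    try:
        rho = solve_toeplitz(r[:-1], r[1:])
    except np.linalg.LinAlgError:
        return np.zeros(order)
    if not np.all(np.isfinite(rho)):
        return np.zeros(order)
    return np.asarray(rho, dtype=float)


def band_power_features(x: np.ndarray, fs: float):
    """Absolute Welch band powers for the five EEG bands plus alpha/beta.

    The PSD is estimated with a Hamming window of 2*min(128, L/4) samples
    at 50% overlap and integrated over each band; the gamma band's upper
    edge is clipped below the Nyquist frequency.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(2 * min(128, x.size // 4), x.size)
    freqs, psd = sp_signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False,
    )
    powers = []
    for _, lo, hi in BANDS:
        hi = min(hi, 0.999 * fs / 2)
        mask = (freqs >= lo) & (freqs <= hi)
        powers.append(float(np.trapezoid(psd[mask], freqs[mask]))
                      if mask.sum() > 1 else 0.0)
    delta, theta, alpha, beta, gamma = powers
    ratio = alpha / max(beta, _EPS)
    return delta, theta, alpha, beta, gamma, ratio


def extract_feature_vector(x: np.ndarray, fs: float) -> np.ndarray:
    """The full 33-value feature vector in ``FEATURE_NAMES`` order."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("feature extraction needs at least 64 samples")
    act, mob, comp = hjorth_features(x)
    (lrssv, mcl, me, mte, fd, sd_, nfd, nsd) = energy_and_variation_features(x)
    med, mn, mx, var, std, skew, kurt, mean = amplitude_statistics(x)
    renyi, shannon, log_en, tsallis = entropy_features(x)
    ar = ar_coefficients(x)
    bp = band_power_features(x, fs)
    vec = np.array([
        act, mob, comp,
        lrssv, mcl, me, mte,
        med, mn, mx,
        renyi, shannon, log_en, tsallis,
        fd, sd_, nfd, nsd,
        var, std, skew, kurt,
        *ar,
        *bp,
        mean,
    ])
    assert vec.size == len(FEATURE_NAMES)
    return vec


@dataclass
class FeatureMatrix:
    """Segments x features matrix with per-column provenance.

    ``columns`` holds one (channel, site, representation, feature_name)
    tuple per column, in (channel, representation, feature) order.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("X shape inconsistent with y/columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column provenance tuples must be unique")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_names(self) -> list[str]:
        return [f"{ch}.{rep}.{feat}" for ch, _, rep, feat in self.columns]

    def site_columns(self, sites: str | list[str]) -> np.ndarray:
        """Indices of all columns whose channel lies in the given site(s)."""
        if isinstance(sites, str):
            sites = [sites]
        wanted = set(sites)
        idx = [i for i, (_, site, _, _) in enumerate(self.columns)
               if site in wanted]
        if not idx:
            raise ValueError(f"no columns for sites {sorted(wanted)}")
        return np.asarray(idx)

    def restrict(self, col_idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[:, col_idx],
            y=self.y,
            columns=[self.columns[i] for i in col_idx],
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.column_names())
        df["label"] = self.y
        return df


def build_feature_matrix(
    segments: list[Segment],
    representations: tuple[str, ...] = REPRESENTATIONS,
    vmd_cfg: VMDConfig = VMDConfig(),
    dwt_cfg: DWTConfig = DWTConfig(),
    ewt_max_peaks: int = 9,
) -> FeatureMatrix:
    """Decompose segments and extract every (channel, representation) feature.

    Rows follow segment order; columns are ordered (channel, representation,
    feature) and carry full provenance. For 19 channels and all four
    representations P = 33 * 4 * 19 = 2508.
    """
    if not segments:
        raise ValueError("no segments given")
    channels = segments[0].channels
    fs = segments[0].fs
    if any(s.channels != channels or s.fs != fs for s in segments):
        raise ValueError("all segments must share channel set and rate")
    unknown = [r for r in representations if r not in REPRESENTATIONS]
    if unknown:
        raise ValueError(f"unknown representations {unknown}")

    reps = decompose_segments(segments, vmd_cfg, dwt_cfg, ewt_max_peaks)
    columns = [
        (ch, site_of(ch), rep, feat)
        for ch in channels
        for rep in representations
        for feat in FEATURE_NAMES
    ]
    n_feat = len(FEATURE_NAMES)
    X = np.empty((len(segments), len(columns)))
    for i, rep_map in enumerate(reps):
        col = 0
        for c in range(len(channels)):
            for rep in representations:
                X[i, col:col + n_feat] = extract_feature_vector(
                    rep_map[rep][c], representation_fs(rep, fs)
                )
                col += n_feat
    y = np.array([s.label for s in segments])
    return FeatureMatrix(X=X, y=y, columns=columns)
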