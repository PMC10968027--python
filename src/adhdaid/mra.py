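"""Multi-resolution analysis: VMD, level-1 DWT, and EWT.

Each 4-second segment channel is turned into four "representations" that
feed the feature bank:

``time``
    the channel itself (identity);
``dwt``
    the level-1 discrete-wavelet approximation coefficients, a half-rate
    denoised view of the signal;
``ewt``
    the sum of all empirical-wavelet modes except the highest-frequency
    band (adaptive high-band noise removal);
``vmd``
    the sum of the K variational modes with the residual discarded.

VMD splits a signal into K band-compact intrinsic mode functions by
minimising the summed mode bandwidths subject to (soft) reconstruction,
solved with the standard frequency-domain ADMM. EWT builds a Meyer-type
filter bank whose band edges are placed from the signal's own magnitude
spectrum. Both are deterministic functions of (signal, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io_preprocess import Segment

__all__ = [
    "VMDConfig", "VMDResult", "vmd_decompose", "vmd_denoised",
    "DWTConfig", "DWTResult", "dwt_level1", "dwt_denoised",
    "EWTResult", "ewt_decompose", "ewt_denoised",
    "decompose_all", "decompose_segments", "representation_fs",
]


# ---------------------------------------------------------------------------
# VMD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VMDConfig:
    """Variational mode decomposition parameters.

    K is the number of modes; ``alpha`` the quadratic bandwidth penalty
    (larger = narrower modes); ``tau`` the dual-ascent step for the
    Lagrangian multipliers (0 disables exact reconstruction enforcement,
    which is robust in noise); ``init`` places the initial centre
    frequencies ("uniform" over [0, fs/2) or "zero").
    """

    K: int = 9
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "uniform"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("alpha and tol must be positive, max_iter >= 1")
        if self.init not in ("uniform", "zero"):
            raise ValueError("init must be 'uniform' or 'zero'")


@dataclass
class VMDResult:
    modes: np.ndarray          # K x L
    center_freqs: np.ndarray   # K, in Hz
    residual: np.ndarray       # L
    n_iter: int
    converged: bool


try:  # optional numba acceleration of the ADMM loop; numpy path is identical
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _admm_core(f_hat_plus, freqs, omega, alpha, tau, tol, max_iter):  # pragma: no cover
        B, nf = f_hat_plus.shape
        K = omega.shape[1]
        u = np.zeros((B, K, nf), dtype=np.complex128)
        lam = np.zeros((B, nf), dtype=np.complex128)
        sum_u = np.zeros((B, nf), dtype=np.complex128)
        # each signal iterates independently until its own relative change
        # drops below tol, so results do not depend on batch composition
        active = np.ones(B, dtype=np.bool_)
        iters = np.zeros(B, dtype=np.int64)
        for _ in range(max_iter):
            any_active = False
            for b in range(B):
                if not active[b]:
                    continue
                any_active = True
                iters[b] += 1
                diff_sq = 0.0
                norm_sq = 0.0
                for k in range(K):
                    om = omega[b, k]
                    num_f = 0.0
                    den = 0.0
                    for j in range(nf):
                        old = u[b, k, j]
                        w = freqs[j] - om
                        new = (f_hat_plus[b, j] - (sum_u[b, j] - old)
                               + 0.5 * lam[b, j]) / (1.0 + alpha * w * w)
                        u[b, k, j] = new
                        sum_u[b, j] += new - old
                        p = new.real * new.real + new.imag * new.imag
                        num_f += p * freqs[j]
                        den += p
                        d = new - old
                        diff_sq += d.real * d.real + d.imag * d.imag
                        norm_sq += old.real * old.real + old.imag * old.imag
                    if den > 0.0:
                        omega[b, k] = num_f / den
                if tau != 0.0:
                    for j in range(nf):
                        lam[b, j] += tau * (f_hat_plus[b, j] - sum_u[b, j])
                if diff_sq <= tol * max(norm_sq, 1e-300):
                    active[b] = False
            if not any_active:
                break
        n_iter = int(iters.max()) if B else 0
        converged = not np.any(active)
        return u, omega, n_iter, converged

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _admm_numpy_single(f_hat_plus: np.ndarray, freqs: np.ndarray,
                       omega: np.ndarray, cfg: VMDConfig):
    """Reference (pure-numpy) ADMM for one signal's half-spectrum."""
    K = omega.size
    nf = freqs.size
    u_hat = np.zeros((K, nf), dtype=complex)
    lam = np.zeros(nf, dtype=complex)
    sum_uk = np.zeros(nf, dtype=complex)
    n_iter = 0
    converged = False
    for n_iter in range(1, cfg.max_iter + 1):
        diff_sq = 0.0
        norm_sq = 0.0
        for k in range(K):
            old = u_hat[k].copy()
            sum_uk -= old
            u_hat[k] = (f_hat_plus - sum_uk + lam / 2) / (
                1.0 + cfg.alpha * (freqs - omega[k]) ** 2
            )
            power = np.abs(u_hat[k]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = (power @ freqs) / denom
            sum_uk += u_hat[k]
            d = u_hat[k] - old
            diff_sq += np.vdot(d, d).real
            norm_sq += np.vdot(old, old).real
        if cfg.tau:
            lam = lam + cfg.tau * (f_hat_plus - sum_uk)
        if diff_sq <= cfg.tol * max(norm_sq, 1e-300):
            converged = True
            break
    return u_hat, omega, n_iter, converged


def _vmd_batch(X: np.ndarray, fs: float, cfg: VMDConfig):
    """Run VMD on a batch of signals (B x L) with one shared ADMM loop.

    Returns (modes (B,K,L), omega_hz (B,K), n_iter, converged). Signals are
    mirror-extended before the FFT and cropped after, to suppress edge
    ringing.
    """
    X = np.asarray(X, dtype=float)
    B, L = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("VMD input must be finite")
    if cfg.K > L // 2:
        raise ValueError(f"K={cfg.K} too large for signal length {L}")

    half = L // 2
    # mirror extension to length L + 2*half
    f = np.concatenate([X[:, half - 1::-1] if half else X[:, :0],
                        X,
                        X[:, :L - half - 1:-1]], axis=1)
    T = f.shape[1]
    # with multipliers off and a zero start, the analytic (negative-frequency)
    # half of every mode spectrum stays zero, so iterate on [0, 0.5] only
    freqs = np.fft.rfftfreq(T)                      # cycles/sample
    f_hat_plus = np.fft.rfft(f, axis=1)
    nf = f_hat_plus.shape[1]

    K = cfg.K
    if cfg.init == "uniform":
        omega = np.tile((0.5 / K) * np.arange(K), (B, 1))
    else:
        omega = np.zeros((B, K))

    if _HAVE_NUMBA:
        u_hat, omega, n_iter, converged = _admm_core(
            np.ascontiguousarray(f_hat_plus), freqs, omega,
            float(cfg.alpha), float(cfg.tau), float(cfg.tol), int(cfg.max_iter),
        )
    else:
        u_hat = np.zeros((B, K, nf), dtype=complex)
        n_iter = 0
        converged = True
        for b in range(B):  # per-signal loops keep results batch-invariant
            ub, omega[b], it_b, conv_b = _admm_numpy_single(
                f_hat_plus[b], freqs, omega[b], cfg)
            u_hat[b] = ub
            n_iter = max(n_iter, it_b)
            converged = converged and conv_b

    # back to time: the half-spectrum with hermitian mirroring is exactly
    # what irfft inverts, yielding the real part of each analytic mode
    u = np.fft.irfft(u_hat, n=T, axis=2)
    modes = u[:, :, half: half + L]
    return modes, omega * fs, n_iter, converged


def vmd_decompose(x: np.ndarray, fs: float, cfg: VMDConfig = VMDConfig()) -> VMDResult:
    """Decompose one signal into K band-compact modes plus a residual.

    ``modes + residual`` reconstructs the input exactly by construction
    (the residual is defined as the reconstruction error).
    """
    x = np.asarray(x, dtype=float)
    modes, omega, n_iter, converged = _vmd_batch(x[None, :], fs, cfg)
    modes = modes[0]
    return VMDResult(
        modes=modes,
        center_freqs=np.clip(omega[0], 0.0, fs / 2),
        residual=x - modes.sum(axis=0),
        n_iter=n_iter,
        converged=converged,
    )


def vmd_denoised(result: VMDResult) -> np.ndarray:
    """Sum of the K modes with the residual discarded (noise suppression)."""
    return result.modes.sum(axis=0)


# ---------------------------------------------------------------------------
# DWT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DWTConfig:
    """Level-1 DWT parameters (Symlets-5, periodized, by default)."""

    wavelet: str = "sym5"
    level: int = 1
    extension: str = "periodization"

    def __post_init__(self) -> None:
        if self.level != 1:
            raise ValueError("only level-1 decomposition is supported")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet!r}")


@dataclass
class DWTResult:
    approx: np.ndarray  # A1
    detail: np.ndarray  # D1
    wavelet: str = "sym5"
    extension: str = "periodization"


def dwt_level1(x: np.ndarray, cfg: DWTConfig = DWTConfig()) -> DWTResult:
    """Half-band filter + downsample-by-2 split into A1/D1 coefficients.

    With an orthogonal wavelet and periodization the two coefficient
    sequences each have length ceil(L/2) and conserve the input energy.
    """
    x = np.asarray(x, dtype=float)
    filt_len = pywt.Wavelet(cfg.wavelet).dec_len
    if x.size < filt_len:
        raise ValueError(
            f"signal length {x.size} is shorter than the {cfg.wavelet} "
            f"filter length {filt_len}"
        )
    approx, detail = pywt.dwt(x, cfg.wavelet, mode=cfg.extension)
    return DWTResult(approx=approx, detail=detail,
                     wavelet=cfg.wavelet, extension=cfg.extension)


def dwt_denoised(result: DWTResult) -> np.ndarray:
    """The approximation coefficients A1, used verbatim as the denoised view."""
    return result.approx


# ---------------------------------------------------------------------------
# EWT
# ---------------------------------------------------------------------------

@dataclass
class EWTResult:
    boundaries: np.ndarray   # edge frequencies in [0, pi] radians, incl. ends
    modes: np.ndarray        # n_modes x L
    used_fallback: bool = False


def _beta(x: np.ndarray) -> np.ndarray:
    # Meyer transition polynomial, C^3 ramp from 0 to 1 on [0, 1]
    x = np.clip(x, 0.0, 1.0)
    return x ** 4 * (35 - 84 * x + 70 * x ** 2 - 20 * x ** 3)


def _meyer_bank(boundaries: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Partition-of-unity band responses with Meyer-style smooth crossovers."""
    interior = np.asarray(boundaries, dtype=float)
    edges = np.concatenate([interior, [np.pi]])
    ratios = [(edges[i + 1] - edges[i]) / (edges[i + 1] + edges[i])
              for i in range(len(edges) - 1)]
    gamma = 0.99 * min(ratios) if ratios else 0.5
    n_bands = len(interior) + 1

    # cumulative low-pass response below each interior boundary
    lowpass = np.ones((len(interior) + 1, omega.size))
    for i, w0 in enumerate(interior):
        r = _beta((omega - (1 - gamma) * w0) / (2 * gamma * w0))
        lowpass[i] = np.cos(np.pi / 2 * r) ** 2
    lowpass[-1] = 1.0  # up to pi

    bank = np.empty((n_bands, omega.size))
    below = np.ones(omega.size)
    for b in range(n_bands):
        bank[b] = below * lowpass[b] if b < len(interior) else below
        below = below - bank[b]
    return bank


def ewt_decompose(
    x: np.ndarray,
    fs: float,
    max_peaks: int = 9,
    fallback_wavelet: str = "sym5",
) -> EWTResult:
    """Adaptive band decomposition with spectrum-driven band edges.

    The magnitude spectrum's local maxima are located; the ``max_peaks``
    largest are kept (fewer if fewer exist) and band edges are placed at
    midpoints between consecutive retained peaks. A Meyer-type filter bank
    built on those edges splits the signal into modes that sum back to the
    input exactly. If no spectral peak is detected, a level-one DWT filter
    bank is used instead (``used_fallback`` is set).
    """
    from scipy.signal import find_peaks

    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("EWT needs at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("EWT input must be finite")

    spec = np.abs(np.fft.rfft(x))
    nf = spec.size
    peaks, props = find_peaks(spec, height=1e-12 * max(spec.max(), 1e-300))
    if peaks.size == 0 or spec.max() == 0:
        # flat/empty spectrum: level-one DWT filter bank
        cA, cD = pywt.dwt(x, fallback_wavelet, mode="periodization")
        approx = pywt.idwt(cA, None, fallback_wavelet, mode="periodization")[: x.size]
        detail = pywt.idwt(None, cD, fallback_wavelet, mode="periodization")[: x.size]
        return EWTResult(
            boundaries=np.array([0.0, np.pi / 2, np.pi]),
            modes=np.vstack([approx, detail]),
            used_fallback=True,
        )

    if peaks.size > max_peaks:
        keep = np.sort(np.argsort(props["peak_heights"])[::-1][:max_peaks])
        peaks = peaks[keep]
    peak_w = np.sort(peaks) * np.pi / (nf - 1)

    mids = (peak_w[:-1] + peak_w[1:]) / 2.0
    interior = np.unique(mids[(mids > 1e-9) & (mids < np.pi - 1e-9)])

    omega = np.arange(nf) * np.pi / (nf - 1)
    bank = _meyer_bank(interior, omega)
    x_hat = np.fft.rfft(x)
    modes = np.fft.irfft(x_hat[None, :] * bank, n=x.size, axis=1)
    return EWTResult(
        boundaries=np.concatenate([[0.0], interior, [np.pi]]),
        modes=modes,
        used_fallback=False,
    )


def ewt_denoised(result: EWTResult) -> np.ndarray:
    """Sum of all modes except the highest-frequency band.

    Parallels the VMD residual exclusion: the top band is treated as the
    noise-dominated part. A single-mode result is returned unchanged.
    """
    if result.modes.shape[0] == 0:
        raise ValueError("EWT result has no modes")
    if result.modes.shape[0] == 1:
        return result.modes[0]
    return result.modes[:-1].sum(axis=0)


# ---------------------------------------------------------------------------
# all representations of a segment
# ---------------------------------------------------------------------------

REPRESENTATIONS: tuple[str, ...] = ("time", "dwt", "ewt", "vmd")


def representation_fs(name: str, fs: float) -> float:
    """Effective sampling rate of a representation (DWT approx is half-rate)."""
    return fs / 2 if name == "dwt" else fs


def decompose_segments(
    segments: list[Segment],
    vmd_cfg: VMDConfig = VMDConfig(),
    dwt_cfg: DWTConfig = DWTConfig(),
    ewt_max_peaks: int = 9,
    vmd_chunk: int = 512,
) -> list[dict[str, np.ndarray]]:
    """Four denoised representations per channel for a batch of segments.

    Returns one map per segment, representation name -> (n_channels, length)
    array; the "time" entry is the segment data itself. All channels of up
    to ``vmd_chunk`` signals share one VMD ADMM loop, and the level-1 DWT is
    applied to the whole stack at once; this is purely an implementation
    batching — results equal the per-signal operations.
    """
    if not segments:
        return []
    fs = segments[0].fs
    n_ch = segments[0].data.shape[0]
    if any(s.fs != fs or s.data.shape[0] != n_ch for s in segments):
        raise ValueError("segments must share sampling rate and channel count")

    stack = np.vstack([s.data for s in segments])  # (n_seg*n_ch, L)
    vmd_sum = np.empty_like(stack)
    for lo in range(0, stack.shape[0], vmd_chunk):
        sl = slice(lo, lo + vmd_chunk)
        modes, _, _, _ = _vmd_batch(stack[sl], fs, vmd_cfg)
        vmd_sum[sl] = modes.sum(axis=1)
    approx, _ = pywt.dwt(stack, dwt_cfg.wavelet, mode=dwt_cfg.extension, axis=-1)
    ewt = np.vstack([
        ewt_denoised(ewt_decompose(row, fs, ewt_max_peaks)) for row in stack
    ])

    out = []
    for i, seg in enumerate(segments):
        rows = slice(i * n_ch, (i + 1) * n_ch)
        out.append({
            "time": seg.data.copy(),
            "dwt": approx[rows],
            "ewt": ewt[rows],
            "vmd": vmd_sum[rows],
        })
    return out


def decompose_all(
    segment: Segment,
    vmd_cfg: VMDConfig = VMDConfig(),
    dwt_cfg: DWTConfig = DWTConfig(),
    ewt_max_peaks: int = 9,
) -> dict[str, np.ndarray]:
    """All four denoised representations of every channel of one segment."""
    return decompose_segments(
        [segment], vmd_cfg, dwt_cfg, ewt_max_peaks
    )[0]
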