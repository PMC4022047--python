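"""Per-spectrum preprocessing: wavelet denoising, baseline subtraction,
total-intensity normalization, and signal-to-noise estimation.

The denoising step uses the undecimated (stationary) discrete wavelet
transform with a Daubechies scaling filter, soft thresholding at the
universal threshold, and optional thresholding of the low-pass channel.
The baseline is a windowed low-quantile estimate interpolated with a
shape-preserving piecewise cubic, emulating classic MS baseline
adjustment; negative residuals after subtraction are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import PchipInterpolator

from maldiprof.errors import NormalizationError, ValidationError
from maldiprof.io_spectra import Spectrum

__all__ = [
    "PreprocessConfig",
    "udwt_denoise",
    "subtract_baseline",
    "tic_normalize",
    "estimate_snr",
]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    wavelet_filter_length:
        Number of taps of the Daubechies scaling filter (even, >= 2);
        8 selects ``db4``.
    threshold_rule:
        Detail-coefficient threshold rule; only ``"universal"``
        (sigma * sqrt(2 ln N)) is implemented.
    threshold_lowpass:
        Also soft-threshold the low-pass (approximation) channel.
    baseline_window:
        Width in Thomson of the windows in which the baseline quantile is
        estimated.
    baseline_quantile:
        Quantile (0 < q < 0.5) of intensities taken as the baseline level
        within each window.
    snr_threshold:
        S/N ratio above which a peak is counted in QC summaries.
    """

    wavelet_filter_length: int = 8
    threshold_rule: str = "universal"
    threshold_lowpass: bool = True
    decomposition_level: int = 5
    baseline_window: float = 200.0
    baseline_quantile: float = 0.10
    snr_threshold: float = 6.0

    def __post_init__(self) -> None:
        if self.wavelet_filter_length < 2 or self.wavelet_filter_length % 2:
            raise ValidationError("wavelet_filter_length must be even and >= 2")
        if not 0 < self.baseline_quantile < 0.5:
            raise ValidationError("baseline_quantile must be in (0, 0.5)")
        if self.snr_threshold <= 0:
            raise ValidationError("snr_threshold must be positive")
        if self.decomposition_level < 1:
            raise ValidationError("decomposition_level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValidationError(f"unknown threshold_rule {self.threshold_rule!r}")


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def udwt_denoise(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Denoise a spectrum with the undecimated discrete wavelet transform.

    The signal is symmetrically extended to the next power of two,
    decomposed to ``config.decomposition_level`` (capped by the padded
    length) with a Daubechies filter of
    ``config.wavelet_filter_length`` taps, detail coefficients are
    soft-thresholded at the universal threshold
    ``sigma_hat * sqrt(2 ln N)`` with ``sigma_hat`` the MAD estimate
    ``median(|finest detail|) / 0.6745``, the low-pass channel is
    optionally thresholded as well, and the signal is reconstructed.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensity
    n = y.size
    if n < 2:
        raise ValidationError("spectrum too short for a wavelet decomposition level")
    wavelet = pywt.Wavelet(f"db{config.wavelet_filter_length // 2}")
    n_pad = 1 << int(np.ceil(np.log2(n)))
    pad = n_pad - n
    ext = np.pad(y, (0, pad), mode="symmetric") if pad else y.copy()
    level = min(config.decomposition_level, int(np.log2(n_pad)))
    coeffs = pywt.swt(ext, wavelet, level=level, norm=True)
    finest_detail = coeffs[-1][1]
    sigma = float(np.median(np.abs(finest_detail))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    new_coeffs = []
    for i, (approx, detail) in enumerate(coeffs):
        detail = _soft(detail, thr)
        if config.threshold_lowpass and i == 0:
            approx = _soft(approx, thr)
        new_coeffs.append((approx, detail))
    rec = pywt.iswt(new_coeffs, wavelet, norm=True)[:n]
    out = spectrum.with_(intensity=rec)
    out.history.append("udwt_denoise")
    return out


def subtract_baseline(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Estimate and subtract a slowly varying baseline.

    Within consecutive windows of ``config.baseline_window`` Thomson the
    baseline level is the ``config.baseline_quantile`` quantile of the
    intensities; window centers are interpolated with a monotone
    piecewise-cubic (PCHIP) curve over the full axis and the curve is
    subtracted pointwise. Negative residuals are kept (not clipped).

    Returns the baseline-subtracted spectrum and the baseline array.
    """
    config = config or PreprocessConfig()
    mz, y = spectrum.mz, spectrum.intensity
    span = mz[-1] - mz[0]
    w = config.baseline_window
    if span <= w:
        raise ValidationError(
            f"spectrum span {span:.1f} Th must exceed one baseline window "
            f"({w:.1f} Th); use a smaller baseline_window"
        )
    edges = np.arange(mz[0], mz[-1] + w, w)
    centers, levels = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (mz >= lo) & (mz < hi)
        if not mask.any():
            continue
        level = np.quantile(y[mask], config.baseline_quantile)
        # node sits where the quantile is realized, so a monotone drift
        # within the window does not bias the interpolated curve
        pos = mz[mask][np.argmin(np.abs(y[mask] - level))]
        centers.append(float(pos))
        levels.append(float(level))
    if len(centers) < 2:
        raise ValidationError("too few populated baseline windows")
    centers_arr = np.array(centers)
    levels_arr = np.array(levels)
    keep = np.concatenate([[True], np.diff(centers_arr) > 0])
    interp = PchipInterpolator(centers_arr[keep], levels_arr[keep], extrapolate=True)
    baseline = interp(mz)
    out = spectrum.with_(intensity=y - baseline)
    out.history.append("subtract_baseline")
    return out, baseline


def tic_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide every point by the summed intensity of the whole spectrum.

    The denominator is the sum over the full axis (after denoising and
    baseline subtraction), so the output intensities sum to exactly 1.
    """
    total = float(np.sum(spectrum.intensity))
    if total <= 0:
        raise NormalizationError(
            f"total intensity {total} is not positive; cannot TIC-normalize"
        )
    out = spectrum.with_(intensity=spectrum.intensity / total)
    out.history.append("tic_normalize")
    return out


def estimate_snr(
    spectrum: Spectrum,
    apex_mz: float,
    exclude: list[tuple[float, float]] | None = None,
    half_window: float = 50.0,
) -> float:
    """Signal-to-noise ratio of a peak apex against MAD-scaled local noise.

    Noise is ``1.4826 * median(|residual - median|)`` of the
    baseline-subtracted intensities within ``apex_mz +- half_window`` Th,
    excluding points inside any interval in ``exclude`` (detected peak
    bins). The signal is the intensity at the axis point nearest the apex.
    """
    mz, y = spectrum.mz, spectrum.intensity
    if not mz[0] <= apex_mz <= mz[-1]:
        raise ValidationError(f"apex {apex_mz} outside spectrum axis")
    idx = int(np.argmin(np.abs(mz - apex_mz)))
    signal = float(y[idx])
    mask = np.abs(mz - apex_mz) <= half_window
    if exclude:
        for lo, hi in exclude:
            mask &= ~((mz >= lo) & (mz <= hi))
    noise_pts = y[mask]
    if noise_pts.size == 0:
        raise ValidationError("no noise points left in the S/N neighborhood")
    mad = float(np.median(np.abs(noise_pts - np.median(noise_pts))))
    noise = 1.4826 * mad
    if noise == 0:
        return np.inf if signal > 0 else 0.0
    return signal / noise
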