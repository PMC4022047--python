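"""Total-average-spectrum peak binning and feature-matrix extraction.

Peaks are detected once, in the base-peak-normalized average of all
preprocessed spectra across every group, with a relative height filter.
Each detected peak defines a bin bounded by its full-width-at-half-height
(FWHH) crossings; the per-sample feature value is the maximum normalized
intensity inside the bin, so that every feature receives a value in every
spectrum and there are no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from maldiprof.errors import ValidationError
from maldiprof.io_spectra import Spectrum, _local_maxima

__all__ = [
    "PeakBin",
    "FeatureMatrix",
    "total_average_spectrum",
    "detect_peaks",
    "extract_feature_matrix",
    "count_snr_peaks",
]


@dataclass
class PeakBin:
    """A peak detected in the total average spectrum.

    ``left_bound``/``right_bound`` are the FWHH crossing positions (or the
    adjacent valley when the half height is not reached, clipped against
    neighbouring bins so bins never overlap).
    """

    apex_mz: float
    apex_intensity: float
    left_bound: float
    right_bound: float

    def __post_init__(self) -> None:
        if not self.left_bound < self.apex_mz < self.right_bound:
            raise ValidationError(
                f"bin bounds [{self.left_bound}, {self.right_bound}] must "
                f"bracket the apex {self.apex_mz}"
            )


@dataclass
class FeatureMatrix:
    """Features x samples table of normalized intensities with group labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("values shape inconsistent with ids")
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("feature values must be finite and >= 0")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path, sidecar_groups: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")
        if sidecar_groups is not None:
            pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups}).to_csv(
                sidecar_groups, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, path: str | Path, groups_path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gmap = pd.read_csv(groups_path, sep="\t", dtype=str,
                           keep_default_na=False).set_index("sample_id")["group"]
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=list(df.columns),
            values=df.to_numpy(),
            groups=[gmap[s] for s in df.columns],
        )


def total_average_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of all spectra, base-peak normalized to a maximum of 1."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].mz
    for s in spectra[1:]:
        if len(s) != len(axis) or not np.array_equal(s.mz, axis):
            raise ValidationError("spectra must share a common m/z axis")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    peak = float(np.max(mean))
    if peak <= 0:
        raise ValidationError("total average spectrum has no positive signal")
    return Spectrum(axis, mean / peak, sample_id="__total_average__",
                    history=["total_average_spectrum"])


def _half_height_bound(mz: np.ndarray, y: np.ndarray, apex: int, half: float,
                       direction: int, stop: int) -> float:
    """Walk from the apex towards ``stop`` until the intensity crosses
    ``half`` (linear interpolation) or starts rising again (valley)."""
    i = apex
    while i != stop:
        j = i + direction
        if y[j] <= half:
            # linear interpolation between i and j
            if y[i] == y[j]:
                return float(mz[j])
            frac = (y[i] - half) / (y[i] - y[j])
            return float(mz[i] + frac * (mz[j] - mz[i]))
        if y[j] > y[i]:  # valley before reaching half height
            return float(mz[i])
        i = j
    return float(mz[stop])


def detect_peaks(
    avg: Spectrum,
    height_filter: float = 0.01,
    mz_range: tuple[float, float] = (900.0, 4000.0),
) -> list[PeakBin]:
    """Detect peaks in a base-peak-normalized average spectrum.

    Local maxima inside ``mz_range`` with intensity strictly greater than
    ``height_filter`` (a fraction of the base peak) become apexes; FWHH
    bounds are located by linear interpolation at half the apex height on
    each side, falling back to the adjacent valley where the half height
    is not reached. Bounds of adjacent accepted peaks that would overlap
    are clipped to the position of the connecting valley minimum.
    Plateau apexes take their leftmost index.
    """
    mz, y = avg.mz, avg.intensity
    apexes = _local_maxima(y)
    lo, hi = mz_range
    apexes = [i for i in apexes if lo <= mz[i] <= hi and y[i] > height_filter]
    bins: list[PeakBin] = []
    for k, i in enumerate(apexes):
        half = y[i] / 2.0
        left = _half_height_bound(mz, y, i, half, -1, 0)
        right = _half_height_bound(mz, y, i, half, +1, len(y) - 1)
        # degenerate zero-width side: nudge to the adjacent sample
        if left >= mz[i]:
            left = float(mz[max(i - 1, 0)])
        if right <= mz[i]:
            right = float(mz[min(i + 1, len(y) - 1)])
        bins.append(PeakBin(float(mz[i]), float(y[i]), left, right))
    # clip overlapping neighbours at the connecting valley minimum
    for k in range(len(bins) - 1):
        a, b = bins[k], bins[k + 1]
        if a.right_bound > b.left_bound:
            ia = int(np.searchsorted(mz, a.apex_mz))
            ib = int(np.searchsorted(mz, b.apex_mz))
            valley = float(mz[ia + int(np.argmin(y[ia:ib + 1]))])
            valley = min(max(valley, a.apex_mz), b.apex_mz)
            a.right_bound = min(a.right_bound, valley)
            b.left_bound = max(b.left_bound, valley)
            # keep bounds strictly bracketing the apexes
            if a.right_bound <= a.apex_mz:
                a.right_bound = np.nextafter(valley, np.inf)
            if b.left_bound >= b.apex_mz:
                b.left_bound = np.nextafter(valley, -np.inf)
    return bins


def extract_feature_matrix(
    spectra: Sequence[Spectrum], bins: Sequence[PeakBin]
) -> FeatureMatrix:
    """Max-in-bin feature extraction across all spectra.

    Entry (i, j) is the maximum intensity of spectrum j over the axis
    points inside bin i, floored at 0 (baseline subtraction may leave
    small negatives).
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].mz
    feature_ids = []
    rows = []
    for b in bins:
        mask = (axis >= b.left_bound) & (axis <= b.right_bound)
        if not mask.any():
            raise ValidationError(
                f"bin [{b.left_bound:.4f}, {b.right_bound:.4f}] (apex "
                f"{b.apex_mz:.4f}) covers no axis points"
            )
        feature_ids.append(f"{b.apex_mz:.3f}")
        rows.append([max(0.0, float(np.max(s.intensity[mask]))) for s in spectra])
    values = np.array(rows) if rows else np.empty((0, len(spectra)))
    return FeatureMatrix(
        feature_ids=feature_ids,
        sample_ids=[s.sample_id for s in spectra],
        values=values,
        groups=[s.group for s in spectra],
    )


def count_snr_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 6.0,
    mz_range: tuple[float, float] = (900.0, 4000.0),
    height_filter: float = 0.01,
) -> int:
    """QC metric: isotopically resolved distributions above an S/N threshold.

    Peaks are detected in this single baseline-subtracted spectrum (scaled
    to its own base peak for the height filter), grouped into isotope
    distributions, and distributions whose monoisotopic apex S/N meets the
    threshold are counted.
    """
    from maldiprof.deisotope import DeisotopeConfig, group_isotope_distributions
    from maldiprof.preprocess import estimate_snr

    peak = float(np.max(spectrum.intensity))
    if peak <= 0:
        return 0
    scaled = spectrum.with_(intensity=spectrum.intensity / peak)
    bins = detect_peaks(scaled, height_filter=height_filter, mz_range=mz_range)
    dists = group_isotope_distributions(bins, DeisotopeConfig())
    exclude = [(b.left_bound, b.right_bound) for b in bins]
    count = 0
    for d in dists:
        snr = estimate_snr(spectrum, d.monoisotopic_mz, exclude=exclude)
        if snr >= snr_threshold:
            count += 1
    return count
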