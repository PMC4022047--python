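"""Spectrum I/O, internal recalibration and resampling.

Profile spectra are exchanged as plain-text two-column ASCII files
(m/z, intensity), whitespace- or tab-delimited, with ``#`` comment lines.
A sample manifest (TSV with columns ``path``, ``sample_id``, ``group``,
``experiment``) assigns each file its experimental-design labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from maldiprof.errors import CalibrationError, InputFormatError, RangeError, ValidationError

__all__ = [
    "Spectrum",
    "SampleManifest",
    "CalibrationModel",
    "read_ascii_spectrum",
    "write_ascii_spectrum",
    "internal_calibrate",
    "resample_common_axis",
]


@dataclass
class Spectrum:
    """One profile mass spectrum on a strictly increasing m/z axis.

    Parameters
    ----------
    mz:
        m/z sampling points in Thomson, strictly increasing, finite.
    intensity:
        Intensities in arbitrary units, same length as ``mz``. Raw spectra
        are non-negative; after baseline subtraction small negatives are
        permitted (the step is recorded in ``history``).
    sample_id, group, experiment:
        Sample metadata: unique sample identifier, biological group label
        and replicate-experiment label.
    history:
        Ordered names of processing steps already applied.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str = ""
    experiment: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 1:
            raise ValidationError("spectrum must contain at least one point")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValidationError("spectrum contains non-finite values")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("m/z axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced (history is copied)."""
        changes.setdefault("history", list(self.history))
        return replace(self, **changes)


@dataclass
class CalibrationModel:
    """Affine internal-calibration model ``mz' = slope * mz + offset``."""

    slope: float
    offset: float
    n_matched: int
    residual_ppm: float


@dataclass
class SampleManifest:
    """Assignment of spectrum files to samples, groups and experiments."""

    rows: pd.DataFrame

    REQUIRED = ("path", "sample_id", "group", "experiment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        ids = self.rows["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate sample_ids in manifest: {dupes}")
        if (self.rows.groupby("group").size() < 1).any():  # pragma: no cover
            raise ValidationError("every group needs at least one sample")

    @classmethod
    def read_tsv(cls, path: str | Path, check_files: bool = True) -> "SampleManifest":
        path = Path(path)
        # keep_default_na=False: group labels like "null" are real labels
        rows = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                           keep_default_na=False)
        manifest = cls(rows=rows)
        if check_files:
            base = path.parent
            for p in rows["path"]:
                full = base / p if not Path(p).is_absolute() else Path(p)
                if not full.exists():
                    raise InputFormatError(f"manifest references missing file: {p}")
        return manifest

    def write_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def load_spectra(self, base: str | Path | None = None) -> list[Spectrum]:
        """Read every referenced ASCII spectrum with its metadata attached."""
        spectra = []
        for row in self.rows.itertuples(index=False):
            p = Path(row.path)
            if base is not None and not p.is_absolute():
                p = Path(base) / p
            spectra.append(
                read_ascii_spectrum(p, row.sample_id, row.group, row.experiment)
            )
        return spectra


def read_ascii_spectrum(
    path: str | Path, sample_id: str = "", group: str = "", experiment: str = ""
) -> Spectrum:
    """Parse a two-column (m/z, intensity) ASCII profile spectrum.

    Lines starting with ``#`` and blank lines are skipped. Duplicate m/z
    rows are averaged so the axis is strictly increasing.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}") from exc
    mzs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 2:
            raise InputFormatError(f"{path}: line {lineno}: expected two columns")
        try:
            mzs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise InputFormatError(
                f"{path}: line {lineno}: non-numeric token in {stripped!r}"
            ) from exc
    if len(mzs) < 2:
        raise InputFormatError(f"{path}: fewer than 2 numeric rows")
    mz = np.array(mzs)
    y = np.array(ys)
    order = np.argsort(mz, kind="stable")
    mz, y = mz[order], y[order]
    # average duplicate m/z rows
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if uniq.size < mz.size:
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, y)
        y = sums / counts
        mz = uniq
    return Spectrum(mz, y, sample_id=sample_id, group=group, experiment=experiment,
                    history=["read_ascii"])


def write_ascii_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column ASCII at full float precision."""
    lines = [
        f"{float(m)!r} {float(y)!r}"
        for m, y in zip(spectrum.mz, spectrum.intensity)
    ]
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputFormatError(f"cannot write {path}: {exc}") from exc


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus yield their leftmost index."""
    n = y.size
    if n < 3:
        return np.array([], dtype=int)
    candidates = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                candidates.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(candidates, dtype=int)


def internal_calibrate(
    spectrum: Spectrum,
    reference_masses: Sequence[float],
    search_tol_ppm: float = 200.0,
    min_matches: int = 3,
) -> tuple[Spectrum, CalibrationModel | None]:
    """Realign a spectrum against known reference peak masses.

    For each reference mass, the nearest local intensity maximum within
    ``search_tol_ppm`` is taken as the observed apex. An affine model
    ``mz' = slope * mz + offset`` is least-squares fitted to the
    (observed, reference) pairs and applied to the whole axis.

    If fewer than ``min_matches`` references match, the spectrum is
    returned unchanged with a warning flag in its history and the model
    is ``None`` (a :class:`CalibrationError`-grade condition downgraded to
    a warning so that batch processing can continue).
    """
    refs = np.asarray(list(reference_masses), dtype=float)
    in_range = refs[(refs >= spectrum.mz[0]) & (refs <= spectrum.mz[-1])]
    apex_idx = _local_maxima(spectrum.intensity)
    observed, target = [], []
    if apex_idx.size:
        apex_mz = spectrum.mz[apex_idx]
        for ref in in_range:
            tol = ref * search_tol_ppm * 1e-6
            d = np.abs(apex_mz - ref)
            k = int(np.argmin(d))
            if d[k] <= tol:
                observed.append(apex_mz[k])
                target.append(ref)
    if len(observed) < min_matches:
        warnings.warn(
            f"internal calibration skipped for {spectrum.sample_id or '<spectrum>'}: "
            f"only {len(observed)} of {len(refs)} references matched "
            f"(minimum {min_matches})",
            stacklevel=2,
        )
        out = spectrum.with_()
        out.history.append("internal_calibrate:skipped")
        return out, None
    obs = np.array(observed)
    tgt = np.array(target)
    A = np.column_stack([obs, np.ones_like(obs)])
    (slope, offset), *_ = np.linalg.lstsq(A, tgt, rcond=None)
    fitted = slope * obs + offset
    residual_ppm = float(np.sqrt(np.mean(((fitted - tgt) / tgt * 1e6) ** 2)))
    new_axis = slope * spectrum.mz + offset
    out = spectrum.with_(mz=new_axis)
    out.history.append("internal_calibrate")
    return out, CalibrationModel(float(slope), float(offset), len(observed), residual_ppm)


def resample_common_axis(
    spectra: Sequence[Spectrum], n_points: int | str = "auto"
) -> list[Spectrum]:
    """Linearly interpolate all spectra onto one uniform common m/z axis.

    The common axis spans the intersection of the individual m/z ranges.
    ``n_points="auto"`` uses the median input length.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    lo = max(s.mz[0] for s in spectra)
    hi = min(s.mz[-1] for s in spectra)
    if not lo < hi:
        raise RangeError(f"spectra m/z ranges do not overlap ([{lo}, {hi}])")
    if n_points == "auto":
        n_points = int(np.median([len(s) for s in spectra]))
    n_points = int(n_points)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    axis = np.linspace(lo, hi, n_points)
    out = []
    for s in spectra:
        y = np.interp(axis, s.mz, s.intensity)
        r = s.with_(mz=axis, intensity=y)
        r.history.append("resample")
        out.append(r)
    return out
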