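"""End-to-end profiling pipeline and its plain-text configuration.

The chain mirrors a linear label-free profiling workflow: internal
calibration -> resampling to a common axis -> wavelet denoising ->
baseline subtraction -> total average spectrum -> peak binning -> TIC
normalization -> max-in-bin feature extraction -> deisotoping ->
within-distribution summing -> Kruskal-Wallis/Bonferroni statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from maldiprof import __version__
from maldiprof.binning import (
    FeatureMatrix,
    PeakBin,
    detect_peaks,
    extract_feature_matrix,
    total_average_spectrum,
)
from maldiprof.deisotope import (
    DeisotopeConfig,
    IsotopeDistribution,
    distributions_to_frame,
    group_isotope_distributions,
    sum_distributions,
)
from maldiprof.diffstats import (
    StatsConfig,
    TestResult,
    results_to_frame,
    run_differential_analysis,
)
from maldiprof.errors import ConfigError
from maldiprof.io_spectra import Spectrum, internal_calibrate, resample_common_axis
from maldiprof.preprocess import PreprocessConfig, subtract_baseline, tic_normalize, udwt_denoise

log = logging.getLogger("maldiprof")

__all__ = ["PipelineConfig", "ProfileResult", "run_profile", "config_hash"]


@dataclass
class PipelineConfig:
    """All tunables of the profiling chain in one serializable object."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    deisotope: DeisotopeConfig = field(default_factory=DeisotopeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    height_filter: float = 0.01
    mz_range: tuple[float, float] = (900.0, 4000.0)
    resample_points: int | str = "auto"
    calibration_masses: list[float] = field(default_factory=list)
    calibration_tol_ppm: float = 200.0
    annotation_tol_ppm: float = 100.0
    version: str = __version__

    _SECTIONS = {"preprocess": PreprocessConfig, "deisotope": DeisotopeConfig,
                 "stats": StatsConfig}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key in cls._SECTIONS:
                section_cls = cls._SECTIONS[key]
                allowed = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(value) - allowed
                if unknown:
                    raise ConfigError(
                        f"unknown keys in section {key!r}: {sorted(unknown)}"
                    )
                kwargs[key] = section_cls(**value)
            elif key in top_fields:
                if key == "mz_range":
                    value = tuple(value)
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mz_range"] = list(d["mz_range"])
        return d


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration (for provenance)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ProfileResult:
    """Everything the profiling chain produces for one experiment."""

    average_spectrum: Spectrum
    bins: list[PeakBin]
    distributions: list[IsotopeDistribution]
    bin_matrix: FeatureMatrix
    distribution_matrix: FeatureMatrix
    unassigned_matrix: FeatureMatrix
    test_results: list[TestResult]
    config: PipelineConfig

    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.test_results, self.distribution_matrix)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write matrix/distribution/results TSVs with provenance headers."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = config_hash(self.config)
        header = f"# maldiprof {self.config.version} config_hash={chash}\n"
        paths = {}

        def _write(name: str, frame: pd.DataFrame, index: bool) -> None:
            p = outdir / name
            with open(p, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=index)
            paths[name] = p

        matrix_df = self.distribution_matrix.to_frame()
        matrix_df.index.name = "feature_id"
        _write("feature_matrix.tsv", matrix_df, index=True)
        _write("groups.tsv", pd.DataFrame({
            "sample_id": self.distribution_matrix.sample_ids,
            "group": self.distribution_matrix.groups,
        }), index=False)
        assigned = {f"{b.apex_mz:.3f}" for d in self.distributions for b in d.member_bins}
        leftover = [b for b in self.bins if f"{b.apex_mz:.3f}" not in assigned]
        _write("distributions.tsv", distributions_to_frame(self.distributions, leftover),
               index=False)
        _write("results.tsv", self.results_frame(), index=False)
        return paths


def run_profile(
    spectra: Sequence[Spectrum],
    config: PipelineConfig | None = None,
    run_stats: bool = True,
) -> ProfileResult:
    """Run the full profiling chain on raw spectra of one experiment."""
    config = config or PipelineConfig()
    spectra = list(spectra)
    if config.calibration_masses:
        log.info("internal calibration against %d references",
                 len(config.calibration_masses))
        spectra = [
            internal_calibrate(s, config.calibration_masses,
                               config.calibration_tol_ppm)[0]
            for s in spectra
        ]
    log.info("resampling %d spectra to a common axis", len(spectra))
    spectra = resample_common_axis(spectra, config.resample_points)
    processed = []
    for s in spectra:
        d = udwt_denoise(s, config.preprocess)
        b, _ = subtract_baseline(d, config.preprocess)
        processed.append(b)
    avg = total_average_spectrum(processed)
    bins = detect_peaks(avg, config.height_filter, config.mz_range)
    log.info("detected %d peaks in the total average spectrum", len(bins))
    normalized = [tic_normalize(s) for s in processed]
    bin_matrix = extract_feature_matrix(normalized, bins)
    distributions = group_isotope_distributions(bins, config.deisotope)
    log.info("grouped %d bins into %d isotope distributions",
             len(bins), len(distributions))
    dist_matrix, unassigned = sum_distributions(bin_matrix, distributions)
    results: list[TestResult] = []
    if run_stats and dist_matrix.n_features and len(set(dist_matrix.groups)) >= 2:
        results = run_differential_analysis(dist_matrix, config.stats)
    return ProfileResult(
        average_spectrum=avg,
        bins=bins,
        distributions=distributions,
        bin_matrix=bin_matrix,
        distribution_matrix=dist_matrix,
        unassigned_matrix=unassigned,
        test_results=results,
        config=config,
    )
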