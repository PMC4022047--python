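"""Seeded simulation of reflectron MALDI-TOF profile experiments.

The generator emulates the features of single-brain peptide profiling
data that the pipeline must cope with: ~50 singly charged peptide
isotope envelopes in m/z 500-4000, Gaussian peak shapes with
resolution-dependent width, an exponential-decay chemical baseline,
heteroscedastic (shot-noise-like) detector noise, per-spectrum affine
calibration jitter, per-spectrum variable Na/K adduct fractions, and
lognormal biological abundance variation with group-dependent fold
changes for designated analytes. Every draw flows from one integer seed,
with per-spectrum substreams derived from (seed, group, sample index) so
simulation order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maldiprof.errors import ValidationError
from maldiprof.io_spectra import Spectrum

__all__ = [
    "PanelEntry",
    "GroupDesign",
    "SimulationDesign",
    "AVERAGINE_COMPOSITION",
    "ISOTOPE_SPACING",
    "isotope_envelope",
    "averagine_composition",
    "simulate_spectrum",
    "simulate_experiment",
    "default_design",
]

# mean "averagine" amino-acid elemental composition per 111.1254 Da
AVERAGINE_COMPOSITION = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

# aggregate isotopologue spacing for peptides, Th (for 1+ ions)
ISOTOPE_SPACING = 1.00235

# per-element isotope abundances indexed by extra-neutron count
_ELEMENT_ISOTOPES = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

_ELEMENT_MONO_MASS = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
                      "O": 15.9949146221, "S": 31.97207069}


@dataclass
class PanelEntry:
    """One simulated analyte: a neutral monoisotopic mass and its base
    apex abundance (arbitrary intensity units) in a 1x group."""

    neutral_mass: float
    base_abundance: float
    name: str = ""


@dataclass
class GroupDesign:
    label: str
    n_samples: int
    fold_changes: dict[str, float] = field(default_factory=dict)  # name -> fold


@dataclass
class SimulationDesign:
    """Full specification of a simulated multi-group profiling experiment.

    resolution:
        m/z divided by peak FWHM; 8000 emulates a benchtop reflectron TOF.
    baseline_amplitude / baseline_decay / baseline_floor:
        Baseline b(m) = amplitude * exp(-m / decay) + floor, intensity
        units / Thomson.
    noise_sigma_floor / noise_sigma_scale:
        Heteroscedastic Gaussian noise sigma = floor + scale*sqrt(signal).
    calibration_jitter_ppm:
        SD of the per-spectrum multiplicative axis perturbation; an
        additive offset with SD jitter_offset_th is applied as well.
    adduct_beta_na / adduct_beta_k:
        (alpha, beta) parameters of the per-spectrum Beta-distributed
        sodium and potassium adduct fractions (the remainder ionizes as
        [M+H]+). Potassium is deliberately dispersed to emulate uneven
        residual salt.
    biological_cv:
        Coefficient of variation of the per-sample lognormal abundance.
    """

    panel: list[PanelEntry]
    groups: list[GroupDesign]
    mz_start: float = 500.0
    mz_end: float = 4000.0
    n_axis_points: int = 120_001
    resolution: float = 8000.0
    envelope_peaks: int = 5
    baseline_amplitude: float = 40.0
    baseline_decay: float = 700.0
    baseline_floor: float = 2.0
    noise_sigma_floor: float = 1.0
    noise_sigma_scale: float = 0.05
    calibration_jitter_ppm: float = 30.0
    jitter_offset_th: float = 0.01
    adduct_beta_na: tuple[float, float] = (2.0, 48.0)
    adduct_beta_k: tuple[float, float] = (1.5, 8.5)
    biological_cv: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValidationError("panel must be non-empty")
        if any(e.neutral_mass <= 0 or e.base_abundance < 0 for e in self.panel):
            raise ValidationError("panel masses must be positive, abundances >= 0")
        if any(g.n_samples < 1 for g in self.groups):
            raise ValidationError("group sizes must be >= 1")
        for g in self.groups:
            if any(f < 0 for f in g.fold_changes.values()):
                raise ValidationError("fold changes must be >= 0")
        if self.biological_cv < 0 or self.noise_sigma_floor < 0:
            raise ValidationError("dispersions must be >= 0")


def _power_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    base = dist
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def averagine_composition(neutral_mass: float) -> dict[str, int]:
    """Integer averagine elemental composition for a given neutral mass.

    C, N, O and S counts are rounded from the scaled averagine
    composition; the hydrogen count is then chosen to balance the
    remaining mass (never below zero).
    """
    if neutral_mass <= 0:
        raise ValidationError("neutral_mass must be positive")
    scale = neutral_mass / AVERAGINE_MASS
    counts = {el: int(round(v * scale)) for el, v in AVERAGINE_COMPOSITION.items()
              if el != "H"}
    heavy_mass = sum(_ELEMENT_MONO_MASS[el] * n for el, n in counts.items())
    counts["H"] = max(0, int(round((neutral_mass - heavy_mass) / _ELEMENT_MONO_MASS["H"])))
    return counts


def isotope_envelope(neutral_mass: float, n_peaks: int = 5) -> list[tuple[int, float]]:
    """Aggregate isotopologue abundances from the averagine model.

    The elemental isotope distributions of the rounded averagine
    composition are convolved; the result is truncated to ``n_peaks``
    isotopologues and normalized so the most abundant equals 1. Returns
    (extra-neutron offset, relative abundance) pairs; adjacent
    isotopologues of a 1+ peptide ion are spaced ``ISOTOPE_SPACING`` Th.
    """
    counts = averagine_composition(neutral_mass)
    dist = np.array([1.0])
    for el, n in counts.items():
        if n > 0:
            dist = np.convolve(dist, _power_convolve(_ELEMENT_ISOTOPES[el], n))
    dist = dist[:n_peaks]
    dist = dist / dist.max()
    return [(i, float(a)) for i, a in enumerate(dist)]


def _spectrum_rng(seed: int, group_index: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, group_index, sample_index))
    )


def simulate_spectrum(
    design: SimulationDesign, group: str, sample_index: int
) -> Spectrum:
    """Simulate one profile spectrum, fully determined by
    (design.seed, group, sample_index)."""
    labels = [g.label for g in design.groups]
    if group not in labels:
        raise ValidationError(f"unknown group {group!r}")
    gidx = labels.index(group)
    gdesign = design.groups[gidx]
    rng = _spectrum_rng(design.seed, gidx, sample_index)

    axis = np.linspace(design.mz_start, design.mz_end, design.n_axis_points)
    y = np.zeros_like(axis)

    # per-spectrum adduct split and calibration perturbation
    na_frac = rng.beta(*design.adduct_beta_na)
    k_frac = rng.beta(*design.adduct_beta_k)
    h_frac = max(0.0, 1.0 - na_frac - k_frac)
    slope = 1.0 + rng.normal(0.0, design.calibration_jitter_ppm * 1e-6)
    offset = rng.normal(0.0, design.jitter_offset_th)
    sigma_ln = np.sqrt(np.log1p(design.biological_cv**2)) if design.biological_cv else 0.0

    adduct_masses = {"H": 1.007825, "Na": 22.989770, "K": 38.963707}
    for entry in design.panel:
        fold = gdesign.fold_changes.get(entry.name, 1.0)
        expected = entry.base_abundance * fold
        if expected <= 0:
            continue
        bio = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln) if sigma_ln else 1.0
        abundance = expected * bio
        envelope = isotope_envelope(entry.neutral_mass, design.envelope_peaks)
        for adduct, frac in (("H", h_frac), ("Na", na_frac), ("K", k_frac)):
            if frac <= 0:
                continue
            mono = entry.neutral_mass + adduct_masses[adduct]
            for k, rel in envelope:
                center = mono + k * ISOTOPE_SPACING
                center = slope * center + offset  # calibration jitter
                fwhm = center / design.resolution
                s = fwhm / 2.3548200450309493
                height = abundance * frac * rel
                lo = np.searchsorted(axis, center - 5 * s)
                hi = np.searchsorted(axis, center + 5 * s)
                if hi > lo:
                    y[lo:hi] += height * np.exp(
                        -0.5 * ((axis[lo:hi] - center) / s) ** 2
                    )

    baseline = (
        design.baseline_amplitude * np.exp(-axis / design.baseline_decay)
        + design.baseline_floor
    )
    sigma = design.noise_sigma_floor + design.noise_sigma_scale * np.sqrt(
        np.maximum(y, 0.0)
    )
    noise = rng.normal(0.0, 1.0, size=axis.size) * sigma
    y = np.maximum(y + baseline + noise, 0.0)
    return Spectrum(
        axis, y,
        sample_id=f"{group}_{sample_index:02d}",
        group=group,
        experiment="sim",
        history=["simulate"],
    )


def simulate_experiment(
    design: SimulationDesign,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate all spectra of a multi-group experiment plus ground truth.

    The truth table has one row per (panel entry, group) with the
    expected abundance (base x fold change) and expected mean adduct
    fractions, enabling parameter-recovery tests.
    """
    spectra = []
    rows = []
    a_na, b_na = design.adduct_beta_na
    a_k, b_k = design.adduct_beta_k
    mean_na = a_na / (a_na + b_na)
    mean_k = a_k / (a_k + b_k)
    for g in design.groups:
        for i in range(g.n_samples):
            spectra.append(simulate_spectrum(design, g.label, i))
        for entry in design.panel:
            fold = g.fold_changes.get(entry.name, 1.0)
            rows.append(
                {
                    "name": entry.name,
                    "neutral_mass": entry.neutral_mass,
                    "mono_mz_h": entry.neutral_mass + 1.007825,
                    "group": g.label,
                    "fold_change": fold,
                    "expected_abundance": entry.base_abundance * fold,
                    "mean_na_fraction": mean_na,
                    "mean_k_fraction": mean_k,
                }
            )
    return spectra, pd.DataFrame(rows)


def default_design(seed: int = 0, n_peptides: int = 50,
                   n_per_group: int = 9) -> SimulationDesign:
    """The default three-group differential profiling design.

    Fifty peptide analytes span m/z 900-4000 with log-uniform base
    abundances; one mid-abundance analyte (``"differential"``) is absent
    in the first group, at baseline in the second and five-fold
    overexpressed in the third, emulating a null / wild-type /
    overexpressing strain comparison for a circadian neuropeptide.
    Panel masses and abundances depend deterministically on ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x9A7E1)))
    masses = np.sort(rng.uniform(900.0, 3900.0, size=n_peptides))
    # keep envelopes separated by > 6 Th so bins never straddle analytes
    for i in range(1, n_peptides):
        masses[i] = max(masses[i], masses[i - 1] + 6.5)
    abundances = 10 ** rng.uniform(np.log10(20.0), np.log10(400.0), size=n_peptides)
    panel = [
        PanelEntry(float(m), float(a), name=f"pep{i:02d}")
        for i, (m, a) in enumerate(zip(masses, abundances))
    ]
    # designate a mid-mass, mid-abundance analyte as the differential one
    mid = sorted(range(n_peptides), key=lambda i: abs(panel[i].neutral_mass - 1971.0))[0]
    panel[mid] = PanelEntry(panel[mid].neutral_mass, 80.0, name="differential")
    groups = [
        GroupDesign("null", n_per_group, {"differential": 0.0}),
        GroupDesign("wt", n_per_group, {}),
        GroupDesign("overexpressing", n_per_group, {"differential": 5.0}),
    ]
    return SimulationDesign(panel=panel, groups=groups, seed=seed)
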