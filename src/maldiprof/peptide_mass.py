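"""Peptide monoisotopic mass, PTM, adduct and fragment-ion arithmetic.

Neutral monoisotopic masses are sums of standard residue masses plus
water, adjusted by modification deltas (C-terminal amidation, N-terminal
pyroglutamate from Gln, Met oxidation, Tyr sulfation). Singly charged
cation adducts ([M+H]+, [M+Na]+, [M+K]+) default to the *atom*
convention — adding the neutral atom mass, with no electron
correction — which matches how calculated m/z values are conventionally
printed to three decimals in MALDI profiling tables; the physically
exact *ion* convention (subtracting the electron mass) is available.

A reference table of Drosophila melanogaster neuropeptides (14 confirmed
by MS/MS plus 30 tentative mass-matched assignments) ships with the
package for annotation of observed peaks.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from maldiprof.errors import ValidationError

__all__ = [
    "Peptide",
    "Annotation",
    "ReferenceTable",
    "MONOISOTOPIC_RESIDUE_MASS",
    "neutral_monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_peaks",
    "fragment_ions",
    "confirm_identification",
    "parse_sequence_notation",
    "load_reference_table",
]

# standard monoisotopic residue (amino-acid minus water) masses, Da
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
HYDROGEN_ATOM = 1.007825
ELECTRON = 0.000549
CO = 27.994915

ADDUCT_ATOM_MASS = {"H": HYDROGEN_ATOM, "Na": 22.989770, "K": 38.963707}

DELTA_AMIDATION = -0.984016
DELTA_PYROGLUTAMATE = -17.026549
DELTA_OXIDATION = +15.994915
DELTA_SULFATION = +79.956815


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with its modification state.

    ``pyroglutamate`` requires an N-terminal Gln (Q); ``n_oxidations``
    cannot exceed the Met count nor ``n_sulfations`` the Tyr count.
    """

    sequence: str
    amidated: bool = False
    pyroglutamate: bool = False
    n_oxidations: int = 0
    n_sulfations: int = 0
    name: str = ""
    precursor: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("sequence must be non-empty")
        bad = sorted(set(self.sequence) - set(MONOISOTOPIC_RESIDUE_MASS))
        if bad:
            raise ValidationError(f"non-canonical residue(s) {bad} in {self.sequence!r}")
        if self.pyroglutamate and self.sequence[0] != "Q":
            raise ValidationError("pyroglutamate requires an N-terminal Q")
        if self.n_oxidations > self.sequence.count("M") or self.n_oxidations < 0:
            raise ValidationError("oxidation count exceeds number of Met residues")
        if self.n_sulfations > self.sequence.count("Y") or self.n_sulfations < 0:
            raise ValidationError("sulfation count exceeds number of Tyr residues")

    @property
    def mod_key(self) -> tuple:
        return (self.amidated, self.pyroglutamate, self.n_oxidations, self.n_sulfations)


@dataclass
class Annotation:
    """A peptide/adduct assignment for one observed m/z value."""

    observed_mz: float
    peptide: Peptide
    adduct: str
    calc_mz: float
    ppm_error: float


def neutral_monoisotopic_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + mod deltas."""
    mass = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in peptide.sequence) + WATER
    if peptide.amidated:
        mass += DELTA_AMIDATION
    if peptide.pyroglutamate:
        mass += DELTA_PYROGLUTAMATE
    mass += peptide.n_oxidations * DELTA_OXIDATION
    mass += peptide.n_sulfations * DELTA_SULFATION
    return mass


def adduct_mz(neutral_mass: float, adduct: str, convention: str = "atom") -> float:
    """m/z of the singly charged [M+X]+ ion for X in {H, Na, K}.

    ``atom`` adds the neutral atom mass; ``ion`` additionally subtracts
    the electron mass.
    """
    if neutral_mass <= 0:
        raise ValidationError("neutral_mass must be positive")
    try:
        add = ADDUCT_ATOM_MASS[adduct]
    except KeyError:
        raise ValidationError(f"unknown adduct {adduct!r}; expected H, Na or K") from None
    if convention == "atom":
        return neutral_mass + add
    if convention == "ion":
        return neutral_mass + add - ELECTRON
    raise ValidationError(f"unknown convention {convention!r}")


def ppm_error(observed: float, calculated: float) -> float:
    """(observed - calculated) / calculated * 1e6."""
    if calculated <= 0:
        raise ValidationError("calculated m/z must be positive")
    return (observed - calculated) / calculated * 1e6


_NOTATION = re.compile(r"^(?:[A-Z]\.)?(p?)([A-Z]+)(a?)(?:\.[A-Z])?$")


def parse_sequence_notation(notation: str) -> Peptide:
    """Parse dotted flanking-residue notation into a :class:`Peptide`.

    ``R.NSELINSLLSLPKNMNDAa.G`` denotes the core sequence with its
    precursor-flanking residues around the dots; a trailing lowercase
    ``a`` marks C-terminal amidation and a leading ``p`` (before Q) marks
    N-terminal pyroglutamate.
    """
    m = _NOTATION.match(notation.strip())
    if not m:
        raise ValidationError(f"cannot parse sequence notation {notation!r}")
    pyro, seq, amid = m.groups()
    return Peptide(sequence=seq, amidated=bool(amid), pyroglutamate=bool(pyro))


@dataclass
class ReferenceTable:
    """Neuropeptide reference entries, unique by (sequence, modifications)."""

    peptides: list[Peptide]
    rows: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.peptides:
            key = (p.sequence, p.mod_key)
            if key in seen:
                raise ValidationError(f"duplicate reference entry {p.sequence}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peptides)


def load_reference_table(path: str | Path | None = None) -> ReferenceTable:
    """Load the packaged (or a user-supplied) neuropeptide reference TSV.

    The packaged table holds the Drosophila neuropeptides observable in
    single-brain MALDI-TOF profiling, with their sequences in dotted
    modification notation, the observed profile m/z, and the adduct form
    under which each was observed. Entries appearing multiple times
    (e.g. once as [M+H]+ and once as [M+Na]+) are deduplicated by
    (sequence, modifications).
    """
    if path is None:
        source = importlib.resources.files("maldiprof.data") / "reference_peptides.tsv"
        with importlib.resources.as_file(source) as p:
            rows = pd.read_csv(p, sep="\t")
    else:
        rows = pd.read_csv(path, sep="\t")
    peptides = []
    seen = set()
    for row in rows.itertuples(index=False):
        pep = parse_sequence_notation(row.notation)
        pep = Peptide(
            sequence=pep.sequence,
            amidated=pep.amidated,
            pyroglutamate=pep.pyroglutamate,
            name=str(row.name),
            precursor=str(row.precursor),
        )
        key = (pep.sequence, pep.mod_key)
        if key in seen:
            continue
        seen.add(key)
        peptides.append(pep)
    return ReferenceTable(peptides=peptides, rows=rows)


def match_peaks(
    observed: Sequence[float],
    table: ReferenceTable,
    adducts: Iterable[str] = ("H", "Na", "K"),
    tol_ppm: float = 100.0,
    convention: str = "atom",
) -> list[Annotation]:
    """Annotate observed m/z values against the reference table by mass.

    Every (peptide, adduct) combination within ``tol_ppm`` of an observed
    value yields an annotation; one observed value may carry several
    annotations (convolved peaks). Results are sorted by |ppm error|.
    """
    if tol_ppm < 0:
        raise ValidationError("tol_ppm must be non-negative")
    adducts = list(adducts)
    out: list[Annotation] = []
    for pep in table.peptides:
        neutral = neutral_monoisotopic_mass(pep)
        for adduct in adducts:
            calc = adduct_mz(neutral, adduct, convention)
            for obs in observed:
                err = ppm_error(obs, calc)
                if abs(err) < tol_ppm or (tol_ppm > 0 and abs(err) == tol_ppm):
                    out.append(Annotation(obs, pep, adduct, calc, err))
    out.sort(key=lambda a: abs(a.ppm_error))
    return out


def fragment_ions(
    peptide: Peptide, series: Iterable[str] = ("b", "y"), convention: str = "atom"
) -> list[tuple[str, float]]:
    """Singly protonated b/y/a fragment-ion ladders.

    ``b_i`` is the sum of the first i residue masses plus a proton
    (N-terminal modifications apply); ``y_i`` the sum of the last i
    residues plus water and a proton (C-terminal amidation applies);
    ``a_i = b_i - CO``. Internal positional modifications (Met oxidation,
    Tyr sulfation) are not localized and are rejected here.
    """
    if peptide.n_oxidations or peptide.n_sulfations:
        raise ValidationError(
            "fragment ladders require localized modifications; oxidation/"
            "sulfation positions are not tracked"
        )
    series = set(series)
    unknown = series - {"a", "b", "y"}
    if unknown:
        raise ValidationError(f"unknown ion series {sorted(unknown)}")
    proton = HYDROGEN_ATOM if convention == "atom" else HYDROGEN_ATOM - ELECTRON
    res = [MONOISOTOPIC_RESIDUE_MASS[r] for r in peptide.sequence]
    n = len(res)
    out: list[tuple[str, float]] = []
    nterm_delta = DELTA_PYROGLUTAMATE if peptide.pyroglutamate else 0.0
    cterm_delta = DELTA_AMIDATION if peptide.amidated else 0.0
    prefix = 0.0
    for i in range(1, n + 1):
        prefix += res[i - 1]
        if "b" in series:
            out.append((f"b{i}", prefix + nterm_delta + proton))
        if "a" in series:
            out.append((f"a{i}", prefix + nterm_delta + proton - CO))
    suffix = 0.0
    for i in range(1, n + 1):
        suffix += res[n - i]
        if "y" in series:
            out.append((f"y{i}", suffix + WATER + cterm_delta + proton))
    return out


def confirm_identification(
    observed_fragments: Sequence[float], candidate: Peptide, tol: float = 0.5
) -> tuple[bool, list[tuple[str, float, float]]]:
    """Apply the consecutive-ion confirmation rule to MS/MS fragments.

    The b and y ladders of the candidate are matched against the observed
    fragment m/z list within ``tol`` Th. The identification is confirmed
    when at least 3 consecutive indices of a single series are matched.
    Returns the flag and the matched ions as (label, calc m/z, observed).
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    ladder = fragment_ions(candidate, series=("b", "y"))
    matched: list[tuple[str, float, float]] = []
    matched_idx: dict[str, set[int]] = {"b": set(), "y": set()}
    for label, calc in ladder:
        series, idx = label[0], int(label[1:])
        best = None
        for obs in observed_fragments:
            d = abs(obs - calc)
            if d <= tol and (best is None or d < abs(best - calc)):
                best = obs
        if best is not None:
            matched.append((label, calc, best))
            matched_idx[series].add(idx)
    confirmed = False
    for series, idxs in matched_idx.items():
        run = 1
        for i in sorted(idxs):
            run = run + 1 if i - 1 in idxs else 1
            if run >= 3:
                confirmed = True
    return confirmed, matched
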