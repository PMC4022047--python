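"""Rule-based grouping of peak bins into singly charged isotope envelopes.

A chain of detected peaks is accepted as one isotopically resolved
distribution when (i) it has at least three members, (ii) consecutive
apex spacings are 1 +- 0.03 Th, (iii) for distributions below 1700 m/z
the monoisotopic (first) peak is the most abundant in the total average
spectrum, and (iv) the second peak is more abundant than the third, and
than the fourth when one exists. Assignment is greedy from low to high
m/z with exclusive bin membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from maldiprof.binning import FeatureMatrix, PeakBin
from maldiprof.errors import ValidationError

__all__ = [
    "DeisotopeConfig",
    "IsotopeDistribution",
    "chain_is_valid",
    "group_isotope_distributions",
    "sum_distributions",
]


@dataclass
class DeisotopeConfig:
    """Constants of the isotope-envelope acceptance rules."""

    spacing_center: float = 1.0
    spacing_tol: float = 0.03
    min_members: int = 3
    mono_max_below: float = 1700.0

    def __post_init__(self) -> None:
        if self.spacing_tol <= 0:
            raise ValidationError("spacing_tol must be positive")
        if self.min_members < 3:
            raise ValidationError("min_members must be >= 3")


@dataclass
class IsotopeDistribution:
    """An accepted envelope: ordered member bins and the monoisotopic m/z."""

    member_bins: list[PeakBin]

    @property
    def monoisotopic_mz(self) -> float:
        return self.member_bins[0].apex_mz

    @property
    def n_members(self) -> int:
        return len(self.member_bins)

    @property
    def feature_id(self) -> str:
        return f"{self.monoisotopic_mz:.3f}"


def chain_is_valid(bins: Sequence[PeakBin], config: DeisotopeConfig) -> bool:
    """Independent validity check of one candidate chain against all rules."""
    if len(bins) < config.min_members:
        return False
    apexes = [b.apex_mz for b in bins]
    if any(b.apex_mz <= a.apex_mz for a, b in zip(bins, bins[1:])):
        return False
    lo = config.spacing_center - config.spacing_tol
    hi = config.spacing_center + config.spacing_tol
    spacings = np.diff(apexes)
    if not np.all((spacings >= lo) & (spacings <= hi)):
        return False
    heights = [b.apex_intensity for b in bins]
    if apexes[0] < config.mono_max_below and heights[0] < max(heights):
        return False
    if not heights[1] > heights[2]:
        return False
    if len(heights) >= 4 and not heights[1] > heights[3]:
        return False
    return True


def group_isotope_distributions(
    bins: Sequence[PeakBin], config: DeisotopeConfig | None = None
) -> list[IsotopeDistribution]:
    """Greedy low-to-high m/z assignment of bins to isotope distributions.

    Each unassigned bin in ascending m/z order is tried as a monoisotopic
    candidate. The chain is extended as long as some later unassigned bin
    lies within ``spacing_center +- spacing_tol`` of the previous member
    (the bin with spacing closest to ``spacing_center`` is taken when
    several qualify). A maximal chain is accepted if and only if it
    satisfies every acceptance rule (see :func:`chain_is_valid`); accepted
    members are marked assigned and excluded from later chains.
    """
    config = config or DeisotopeConfig()
    bins = list(bins)
    apexes = [b.apex_mz for b in bins]
    if any(b <= a for a, b in zip(apexes, apexes[1:])):
        raise ValidationError("bins must be sorted by strictly increasing apex_mz")
    lo = config.spacing_center - config.spacing_tol
    hi = config.spacing_center + config.spacing_tol
    assigned = [False] * len(bins)
    out: list[IsotopeDistribution] = []
    for start in range(len(bins)):
        if assigned[start]:
            continue
        chain = [start]
        while True:
            last_mz = bins[chain[-1]].apex_mz
            candidates = [
                j
                for j in range(chain[-1] + 1, len(bins))
                if not assigned[j] and lo <= bins[j].apex_mz - last_mz <= hi
            ]
            if not candidates:
                break
            nxt = min(
                candidates,
                key=lambda j: (abs(bins[j].apex_mz - last_mz - config.spacing_center), j),
            )
            chain.append(nxt)
        members = [bins[j] for j in chain]
        if chain_is_valid(members, config):
            for j in chain:
                assigned[j] = True
            out.append(IsotopeDistribution(member_bins=members))
    out.sort(key=lambda d: d.monoisotopic_mz)
    return out


def sum_distributions(
    matrix: FeatureMatrix, distributions: Sequence[IsotopeDistribution]
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Collapse the bin-level matrix to one summed row per distribution.

    Each output row is the columnwise sum of the member-bin rows of a
    distribution. Bin rows not belonging to any distribution are returned
    separately as an "unassigned" matrix (kept for QC, excluded from the
    statistical comparison).
    """
    index = {fid: i for i, fid in enumerate(matrix.feature_ids)}
    rows, ids = [], []
    used: set[int] = set()
    for d in distributions:
        member_rows = []
        for b in d.member_bins:
            fid = f"{b.apex_mz:.3f}"
            if fid not in index:
                raise ValidationError(f"member bin {fid} missing from feature matrix")
            member_rows.append(index[fid])
        used.update(member_rows)
        rows.append(matrix.values[member_rows].sum(axis=0))
        ids.append(d.feature_id)
    summed = FeatureMatrix(
        feature_ids=ids,
        sample_ids=list(matrix.sample_ids),
        values=np.array(rows) if rows else np.empty((0, len(matrix.sample_ids))),
        groups=list(matrix.groups),
    )
    left = [i for i in range(matrix.n_features) if i not in used]
    unassigned = FeatureMatrix(
        feature_ids=[matrix.feature_ids[i] for i in left],
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[left] if left else np.empty((0, len(matrix.sample_ids))),
        groups=list(matrix.groups),
    )
    return summed, unassigned


def distributions_to_frame(
    distributions: Sequence[IsotopeDistribution],
    unassigned_bins: Sequence[PeakBin] = (),
) -> pd.DataFrame:
    """Tabular view of distributions (plus optionally unassigned bins)."""
    rows = [
        {
            "monoisotopic_mz": d.monoisotopic_mz,
            "n_members": d.n_members,
            "member_apexes": ";".join(f"{b.apex_mz:.4f}" for b in d.member_bins),
            "assigned": True,
        }
        for d in distributions
    ]
    rows += [
        {
            "monoisotopic_mz": b.apex_mz,
            "n_members": 1,
            "member_apexes": f"{b.apex_mz:.4f}",
            "assigned": False,
        }
        for b in unassigned_bins
    ]
    return pd.DataFrame(rows, columns=["monoisotopic_mz", "n_members", "member_apexes", "assigned"])
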