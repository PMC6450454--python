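"""Hospital catchment-area construction from patient counts by census tract.

The catchment area of a facility is the smallest set of its top census
tracts that together contain at least a threshold share (default 80%) of
the facility's distinct patients. Construction is greedy and
deterministic: tracts are accumulated in descending patient-count order,
ties broken by ascending tract id, until the cumulative share reaches the
threshold. Because any k tracts hold at most as many patients as the top
k tracts, the greedy prefix is also a minimum-cardinality covering set.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import pandas as pd

from .core import ConditionConfig, filter_encounters

__all__ = ["CatchmentArea", "compute_catchment", "patient_counts_by_tract"]


class CatchmentError(ValueError):
    """Catchment is undefined (e.g., no patients with positive tract counts)."""


@dataclasses.dataclass(frozen=True)
class CatchmentArea:
    """Selected tracts with their patient counts and achieved coverage.

    ``tract_ids`` are ordered by descending patient count (ties by ascending
    id); ``coverage`` is the share of the facility's distinct patients
    resident in the selected tracts, which is >= ``threshold`` unless every
    nonzero tract was needed (then coverage = 1).
    """

    facility_id: str
    tract_ids: tuple[str, ...]
    coverage: float
    threshold: float
    patient_counts: tuple[int, ...]
    cumulative_share: tuple[float, ...]

    def __contains__(self, tract_id: str) -> bool:
        return tract_id in set(self.tract_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "facility_id": self.facility_id,
                "tract_id": self.tract_ids,
                "rank": range(1, len(self.tract_ids) + 1),
                "patient_count": self.patient_counts,
                "cumulative_share": self.cumulative_share,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float) -> "CatchmentArea":
        df = df.sort_values("rank")
        return cls(
            facility_id=str(df["facility_id"].iloc[0]),
            tract_ids=tuple(df["tract_id"].astype(str)),
            coverage=float(df["cumulative_share"].iloc[-1]),
            threshold=threshold,
            patient_counts=tuple(int(c) for c in df["patient_count"]),
            cumulative_share=tuple(float(s) for s in df["cumulative_share"]),
        )


def compute_catchment(
    patient_counts: Mapping[str, int] | pd.Series,
    threshold: float,
    facility_id: str = "",
) -> CatchmentArea:
    """Greedily select top tracts until cumulative patient share >= ``threshold``.

    Raises :class:`CatchmentError` when all counts are zero (the catchment is
    undefined); when the threshold cannot be reached exactly the full set of
    nonzero tracts is returned with coverage 1.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("catchment threshold must lie in (0, 1]")
    counts = pd.Series(dict(patient_counts), dtype=float)
    if (counts < 0).any():
        raise ValueError("patient counts must be non-negative")
    counts = counts[counts > 0]
    if counts.empty:
        raise CatchmentError("catchment undefined: no tract has a positive patient count")

    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = counts.sum()
    selected: list[str] = []
    sel_counts: list[int] = []
    shares: list[float] = []
    cum = 0.0
    for tract, n in order:
        cum += n
        selected.append(str(tract))
        sel_counts.append(int(n))
        shares.append(cum / total)
        # tolerate float roundoff in threshold * total comparisons
        if cum >= threshold * total - 1e-9:
            break
    return CatchmentArea(
        facility_id=facility_id,
        tract_ids=tuple(selected),
        coverage=shares[-1],
        threshold=threshold,
        patient_counts=tuple(sel_counts),
        cumulative_share=tuple(shares),
    )


def patient_counts_by_tract(
    encounters: pd.DataFrame,
    config: ConditionConfig,
    basis: Optional[str] = None,
) -> pd.Series:
    """Distinct patients per residence tract for the facility and window.

    ``basis`` is ``"all-cause"`` (default: every patient of the facility, the
    natural reading of "the hospital's patient population") or
    ``"condition"`` (apply the diagnosis filter first). Falls back to
    ``config.catchment_basis`` when not given.
    """
    basis = basis or config.catchment_basis
    if basis not in ("all-cause", "condition"):
        raise ValueError(f"unknown catchment basis {basis!r}")
    df = filter_encounters(encounters, config, None, diagnosis=(basis == "condition"))
    return df.groupby("tract_id")["patient_id"].nunique().sort_index()
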