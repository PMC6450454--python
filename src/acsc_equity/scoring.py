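"""Health Equity Scores and the facility-level Health Equity Index.

The Health Equity Score of stratum g is the observed-to-expected ratio
``HES_g = O_g / E_g``; values above 1 mark strata with more encounters
than an equitable-utilization counterfactual predicts. The facility
index summarizes the magnitude of the excess: with X the set of valid
strata whose HES exceeds 1,

    index = 1 + sum_{g in X} w_g (HES_g - 1),   w_g = O_g / sum_{X} O_g

i.e., 1 plus the encounter-weighted mean excess over the excess strata.
The index is >= 1 by construction and equals 1 exactly when no stratum
shows excess. No reference group is involved: every stratum is compared
with the facility's own average utilization.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import catchment as _catchment
from . import expected as _expected
from .catchment import CatchmentArea
from .core import ConditionConfig, tabulate_observed

__all__ = [
    "compute_hes",
    "score_strata",
    "compute_index",
    "EquityResult",
    "score_facility",
    "StageError",
]

VALID, BENIGN, INVALID = "valid", "benign", "invalid"


class ScoringError(ValueError):
    """Index undefined (no valid strata)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


def compute_hes(observed: float, expected: float) -> tuple[float, str]:
    """Observed-to-expected ratio with a validity status.

    Returns ``(hes, status)`` where status is ``"valid"`` (E > 0),
    ``"benign"`` (O = E = 0: undefined but harmless, silently excluded) or
    ``"invalid"`` (O > 0 with E = 0: excluded from the index with a warning).
    """
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected counts must be non-negative")
    if expected > 0:
        return observed / expected, VALID
    if observed == 0:
        return float("nan"), BENIGN
    return float("inf"), INVALID


def score_strata(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``hes``, ``status`` and ``excess`` columns to a per-stratum table
    carrying ``observed`` and ``expected``."""
    out = table.copy()
    scored = [compute_hes(o, e) for o, e in zip(out["observed"], out["expected"])]
    out["hes"] = [h for h, _ in scored]
    out["status"] = [s for _, s in scored]
    out["excess"] = (out["status"] == VALID) & (out["hes"] > 1.0)
    return out


def compute_index(
    observed: np.ndarray | pd.Series,
    hes: np.ndarray | pd.Series,
    valid: np.ndarray | pd.Series,
    weighting: Literal["excess", "all"] = "excess",
) -> float:
    """Encounter-weighted average excess over strata with HES > 1, plus 1.

    ``weighting="excess"`` (default) renormalizes observed-encounter weights
    over the excess strata only. ``weighting="all"`` is a sensitivity
    variant averaging max(HES - 1, 0) with weights over all valid strata.
    Raises :class:`ScoringError` when no stratum is valid.
    """
    observed = np.asarray(observed, dtype=float)
    hes = np.asarray(hes, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ScoringError("index undefined: no stratum has a finite HES")
    if weighting == "excess":
        x = valid & (hes > 1.0)
        if not x.any():
            return 1.0
        w = observed[x]
        return 1.0 + float(np.sum(w * (hes[x] - 1.0)) / np.sum(w))
    if weighting == "all":
        w = observed[valid]
        if w.sum() == 0:
            return 1.0
        excess = np.maximum(hes[valid] - 1.0, 0.0)
        return 1.0 + float(np.sum(w * excess) / np.sum(w))
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclasses.dataclass
class EquityResult:
    """Full audit trail of one facility/condition/window scoring run."""

    facility_id: str
    condition: str
    window: tuple[dt.date, dt.date]
    strata: pd.DataFrame  # grid-indexed: observed, patients, population, prevalence, ..., hes, status, excess
    index: float
    rates: _expected.UtilizationRates
    catchment: CatchmentArea
    excess_weight_base: int
    quality: pd.DataFrame  # flagged rows (out-of-range ages, rejected inputs)
    config: ConditionConfig

    @property
    def total_observed(self) -> int:
        return int(self.strata["observed"].sum())

    @property
    def total_expected(self) -> float:
        return float(self.strata["expected"].sum())

    def summary_dict(self) -> dict:
        return {
            "facility_id": self.facility_id,
            "condition": self.condition,
            "window_start": self.window[0].isoformat(),
            "window_end": self.window[1].isoformat(),
            "index": self.index,
            "total_observed": self.total_observed,
            "total_expected": self.total_expected,
            "distinct_patients": int(self.strata.attrs.get("distinct_patients", 0)),
            "propensity": self.rates.propensity,
            "frequency": self.rates.frequency,
            "catchment_tracts": len(self.catchment.tract_ids),
            "catchment_coverage": self.catchment.coverage,
            "excess_weight_base": self.excess_weight_base,
            "n_valid_strata": int((self.strata["status"] == VALID).sum()),
            "n_invalid_strata": int((self.strata["status"] == INVALID).sum()),
        }


def score_facility(
    encounters: pd.DataFrame,
    population: pd.DataFrame,
    prevalence: pd.DataFrame,
    config: ConditionConfig,
    catchment: Optional[CatchmentArea] = None,
    quality: Optional[pd.DataFrame] = None,
) -> EquityResult:
    """Run the full pipeline: catchment -> observed counts -> condition
    population -> utilization rates -> expected counts -> HES -> index.

    ``catchment`` may be passed to freeze a precomputed catchment area
    (otherwise it is recomputed from the window's encounters). Stage
    failures are re-raised as :class:`StageError` naming the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, exc) from exc

    if catchment is None:
        counts = stage("catchment", _catchment.patient_counts_by_tract, encounters, config)
        catchment = stage(
            "catchment", _catchment.compute_catchment, counts, config.catchment_threshold, config.facility_id
        )

    observed = stage("tabulate_observed", tabulate_observed, encounters, catchment, config)
    cond_pop = stage(
        "condition_population", _expected.condition_population, population, prevalence, config, catchment
    )
    u_total = observed.attrs["distinct_patients"]
    c_total = int(observed["observed"].sum())
    rates = stage(
        "utilization_rates",
        _expected.utilization_rates,
        u_total,
        c_total,
        float(cond_pop["condition_population"].sum()),
    )
    expected = stage("expected_encounters", _expected.expected_encounters, cond_pop, rates)

    table = observed.join(expected)
    table = stage("scoring", score_strata, table)
    if config.min_expected > 0:
        table["low_expected"] = table["expected"] < config.min_expected
    index = stage(
        "scoring",
        compute_index,
        table["observed"],
        table["hes"],
        table["status"] == VALID,
        config.index_weighting,
    )
    table.attrs["distinct_patients"] = u_total

    out_of_range = observed.attrs.get("out_of_range_rows", pd.DataFrame())
    dq_frames = []
    if quality is not None and len(quality):
        dq_frames.append(quality.assign(flag="rejected_input_row"))
    if len(out_of_range):
        dq_frames.append(out_of_range.assign(flag="age_out_of_range"))
    dq = pd.concat(dq_frames, ignore_index=True) if dq_frames else pd.DataFrame(columns=["flag"])

    return EquityResult(
        facility_id=config.facility_id,
        condition=config.condition,
        window=(config.window_start, config.window_end),
        strata=table,
        index=index,
        rates=rates,
        catchment=catchment,
        excess_weight_base=int(table.loc[table["excess"], "observed"].sum()),
        quality=dq,
        config=config,
    )
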