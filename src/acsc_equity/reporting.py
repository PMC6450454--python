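"""Report bundles, monthly index series, stoplight summaries.

Outputs are deterministic: the same inputs and config produce
byte-identical CSV/JSON files (fixed column order, sorted JSON keys, no
wall-clock fields). The stratum CSV is written at full float precision so
the facility index can be recomputed from it alone; the JSON report
rounds display values to 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catchment import CatchmentArea
from .core import ConditionConfig, read_encounters, read_population, read_prevalence
from .scoring import VALID, EquityResult, StageError, compute_index, score_facility

__all__ = [
    "ReportBundle",
    "run_analysis",
    "score_system",
    "monthly_series",
    "calendar_months",
    "trailing_windows",
    "stoplight_summary",
    "recompute_index_from_strata_csv",
    "DEFAULT_STOPLIGHT_BANDS",
]

log = logging.getLogger("acsc_equity")

#: presentational band boundaries (lower edges beyond 1); configurable, not a
#: property of the metric itself
DEFAULT_STOPLIGHT_BANDS = (1.25, 1.5)
_BAND_LABELS = ("green", "yellow", "red")


def _round6(x: float) -> float:
    return float(f"{float(x):.6g}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclasses.dataclass
class ReportBundle:
    """One analysis run: the scored result plus the files written for it."""

    result: EquityResult
    out_dir: Path
    paths: dict[str, Path]
    metadata: dict


def strata_frame(result: EquityResult) -> pd.DataFrame:
    """Stratum table plus one summary row (the facility index in ``hes``)."""
    df = result.strata.reset_index()
    df.insert(0, "row_type", "stratum")
    summary = {c: "" for c in df.columns}
    summary.update(
        row_type="summary",
        age_band="ALL",
        race="ALL",
        gender="ALL",
        observed=result.total_observed,
        patients=result.strata.attrs.get("distinct_patients", ""),
        expected=result.total_expected,
        hes=result.index,
        status="",
        excess="",
    )
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def recompute_index_from_strata_csv(path: str | Path, weighting: str = "excess") -> float:
    """Audit helper: rebuild the facility index from the emitted stratum CSV."""
    df = pd.read_csv(path)
    rows = df[df["row_type"] == "stratum"]
    return compute_index(
        rows["observed"].to_numpy(float),
        rows["hes"].to_numpy(float),
        (rows["status"] == VALID).to_numpy(),
        weighting,
    )


def stoplight_summary(
    result: EquityResult,
    bands: Sequence[float] = DEFAULT_STOPLIGHT_BANDS,
    top_k: int = 3,
) -> dict:
    """Band label plus the top-k strata by HES with their observed counts."""
    idx = result.index
    label = _BAND_LABELS[int(np.searchsorted(np.asarray(bands), idx, side="right"))]
    valid = result.strata[result.strata["status"] == VALID]
    top = valid.sort_values("hes", ascending=False).head(top_k)
    return {
        "facility_id": result.facility_id,
        "condition": result.condition,
        "index": _round6(idx),
        "band": label,
        "band_boundaries": list(bands),
        "top_strata": [
            {
                "stratum": "|".join(ix),
                "hes": _round6(r.hes),
                "observed": int(r.observed),
            }
            for ix, r in top.iterrows()
        ],
    }


def run_analysis(
    config: ConditionConfig | str | Path,
    encounters_path: str | Path,
    population_path: str | Path,
    prevalence_path: str | Path,
    out_dir: str | Path,
    catchment: Optional[CatchmentArea] = None,
) -> ReportBundle:
    """Full pipeline from CSV inputs to an on-disk report bundle.

    Writes ``strata.csv`` (per-stratum table + summary row), ``index.json``
    (config, catchment, rates, index, stoplight), ``catchment.csv`` and
    ``quality.csv`` (rejected input rows and out-of-range ages). Invalid
    input rows are collected into the quality report rather than aborting
    the run; structural problems (missing files/columns) still raise.
    """
    if not isinstance(config, ConditionConfig):
        config = ConditionConfig.from_yaml(config)

    enc = read_encounters(encounters_path, config, strict=False)
    log.info("encounters: %d valid rows, %d rejected", len(enc.data), enc.n_rejected)
    pop = read_population(population_path, config, strict=False)
    log.info("population: %d valid rows, %d rejected", len(pop.data), pop.n_rejected)
    prev = read_prevalence(prevalence_path, config, strict=False)
    log.info("prevalence: %d valid rows, %d rejected", len(prev.data), prev.n_rejected)

    rejected = [
        df.assign(input=name)
        for name, df in (("encounters", enc.rejected), ("population", pop.rejected), ("prevalence", prev.rejected))
        if len(df)
    ]
    quality_in = pd.concat(rejected, ignore_index=True) if rejected else None

    result = score_facility(enc.data, pop.data, prev.data, config, catchment=catchment, quality=quality_in)
    log.info(
        "scored facility %s: index=%.4f over %d observed encounters",
        result.facility_id,
        result.index,
        result.total_observed,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "strata": out / "strata.csv",
        "index": out / "index.json",
        "catchment": out / "catchment.csv",
        "quality": out / "quality.csv",
    }
    strata_frame(result).to_csv(paths["strata"], index=False, float_format="%.17g")
    result.catchment.to_frame().to_csv(paths["catchment"], index=False, float_format="%.17g")
    qual = result.quality.copy()
    if "date" in qual.columns and np.issubdtype(qual["date"].dtype, np.datetime64):
        qual["date"] = qual["date"].dt.strftime("%Y-%m-%d")
    qual.to_csv(paths["quality"], index=False)

    metadata = {
        "software": {"name": "acsc-equity", "version": __version__},
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "summary": {k: (_round6(v) if isinstance(v, float) else v) for k, v in result.summary_dict().items()},
        "stoplight": stoplight_summary(result),
        "quality": {
            "rejected_input_rows": int(0 if quality_in is None else len(quality_in)),
            "out_of_range_ages": int((result.quality["flag"] == "age_out_of_range").sum()) if len(result.quality) else 0,
        },
    }
    with open(paths["index"], "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return ReportBundle(result=result, out_dir=out, paths=paths, metadata=metadata)


def score_system(results: Sequence[EquityResult]) -> dict:
    """Combine per-facility results into one system-wide summary.

    Observed and expected counts are pooled per stratum across facilities
    and the index is recomputed from the pooled table by the same
    definition, so the system value is itself encounter-weighted.
    """
    if not results:
        raise ValueError("need at least one facility result")
    pooled = None
    for r in results:
        part = r.strata[["observed", "expected"]]
        pooled = part if pooled is None else pooled.add(part, fill_value=0.0)
    from .scoring import score_strata

    scored = score_strata(pooled)
    index = compute_index(
        scored["observed"], scored["hes"], scored["status"] == VALID, results[0].config.index_weighting
    )
    return {
        "facilities": [r.facility_id for r in results],
        "condition": results[0].condition,
        "index": index,
        "total_observed": int(scored["observed"].sum()),
        "total_expected": float(scored["expected"].sum()),
        "strata": scored,
    }


def _add_months(d: dt.date, months: int) -> dt.date:
    y, m = divmod((d.year * 12 + d.month - 1) + months, 12)
    return dt.date(y, m + 1, 1)


def calendar_months(end: dt.date, n: int) -> list[tuple[dt.date, dt.date]]:
    """``n`` consecutive calendar months, the last one ending at ``end``
    (which must be the first day of a month)."""
    ends = [_add_months(end, -k) for k in range(n - 1, -1, -1)]
    return [(_add_months(e, -1), e) for e in ends]


def trailing_windows(end: dt.date, n: int, months: int = 12) -> list[tuple[dt.date, dt.date]]:
    """``n`` trailing-``months`` windows ending at successive month starts up to ``end``."""
    ends = [_add_months(end, -k) for k in range(n - 1, -1, -1)]
    return [(_add_months(e, -months), e) for e in ends]


def monthly_series(
    encounters: pd.DataFrame,
    population: pd.DataFrame,
    prevalence: pd.DataFrame,
    config: ConditionConfig,
    windows: Sequence[tuple[dt.date, dt.date]],
    catchment: Optional[CatchmentArea] = None,
) -> pd.DataFrame:
    """One index per analysis window with identical methodology throughout.

    Windows with no scorable encounters produce a flagged row (index NaN)
    rather than being dropped. The catchment is recomputed per window
    unless a frozen one is supplied.
    """
    rows = []
    for start, end in windows:
        wcfg = config.with_window(start, end)
        try:
            res = score_facility(encounters, population, prevalence, wcfg, catchment=catchment)
            rows.append(
                {
                    "period_start": start.isoformat(),
                    "period_end": end.isoformat(),
                    "index": res.index,
                    "n_valid_strata": int((res.strata["status"] == VALID).sum()),
                    "n_encounters": res.total_observed,
                    "flag": "",
                }
            )
        except StageError as err:
            rows.append(
                {
                    "period_start": start.isoformat(),
                    "period_end": end.isoformat(),
                    "index": float("nan"),
                    "n_valid_strata": 0,
                    "n_encounters": 0,
                    "flag": f"no index: stage '{err.stage}' ({err.cause})",
                }
            )
    return pd.DataFrame(rows)
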