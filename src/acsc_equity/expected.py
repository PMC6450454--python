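"""Expected encounter counts by indirect standardization.

The expected count for stratum g is the product

    E_g = Pop_g * prev_g * u * f

where ``Pop_g`` is the catchment population of the stratum, ``prev_g`` the
condition prevalence resolved for that stratum, ``u`` the average
utilization propensity (distinct observed condition patients divided by
the estimated condition population of the catchment) and ``f`` the average
encounter frequency (encounters per observed patient). ``u`` and ``f`` are
single catchment-wide averages, not stratum-specific rates: applying the
*average* utilization to every stratum's condition population is exactly
the counterfactual of equitable utilization, and it makes the expected
counts sum to the observed total by construction. Stratum-specific rates
would force every observed-to-expected ratio to 1 and destroy the metric.

Prevalence entries may come at mixed granularity (public sources publish
stratum, race-by-age, race-only, age-only or overall estimates); each
stratum resolves its prevalence by a most-specific-first fallback chain
and records the level used.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .catchment import CatchmentArea
from .core import ConditionConfig

__all__ = [
    "UtilizationRates",
    "PREVALENCE_LEVELS",
    "condition_population",
    "utilization_rates",
    "expected_encounters",
]

#: fallback chain, most specific first
PREVALENCE_LEVELS = ("stratum", "race_age", "race", "age", "overall")


class PrevalenceResolutionError(ValueError):
    """No prevalence entry resolvable for a stratum at any fallback level."""


class ExpectedModelError(ValueError):
    """Degenerate inputs to the expected-count model (e.g., zero condition population)."""


@dataclasses.dataclass(frozen=True)
class UtilizationRates:
    """Catchment-wide average utilization propensity and encounter frequency.

    ``propensity`` (u) is distinct observed patients / estimated condition
    population; ``frequency`` (f) is mean encounters per observed patient,
    >= 1 whenever any patient was observed. ``warning`` is set in the
    degenerate no-patients case, where both rates are defined as 0.
    """

    propensity: float
    frequency: float
    warning: bool = False


def _prevalence_lookups(prevalence: pd.DataFrame, condition: str) -> dict[str, dict]:
    rows = prevalence[prevalence["condition"] == condition]
    band = rows["age_band"].astype(str).str.strip()
    race = rows["race"].astype(str).str.strip()
    gender = rows["gender"].astype(str).str.strip()
    tables: dict[str, dict] = {level: {} for level in PREVALENCE_LEVELS}
    for i, r in rows.iterrows():
        b, rc, g = band[i], race[i], gender[i]
        p = float(r["prevalence"])
        if b and rc and g:
            tables["stratum"][(b, rc, g)] = p
        elif b and rc:
            tables["race_age"][(b, rc)] = p
        elif rc and not b and not g:
            tables["race"][rc] = p
        elif b and not rc and not g:
            tables["age"][b] = p
        elif not b and not rc and not g:
            tables["overall"][()] = p
        # other marginal shapes (e.g., gender-only) are not part of the chain
    return tables


def resolve_prevalence(band: str, race: str, gender: str, tables: dict[str, dict]) -> tuple[float, str]:
    """Resolve a stratum's prevalence via stratum -> race x age -> race -> age -> overall."""
    for level, key in (
        ("stratum", (band, race, gender)),
        ("race_age", (band, race)),
        ("race", race),
        ("age", band),
        ("overall", ()),
    ):
        if key in tables[level]:
            return tables[level][key], level
    raise PrevalenceResolutionError(
        f"no prevalence resolvable for stratum {band}|{race}|{gender} at any fallback level"
    )


def condition_population(
    population: pd.DataFrame,
    prevalence: pd.DataFrame,
    config: ConditionConfig,
    catchment: CatchmentArea | None = None,
) -> pd.DataFrame:
    """Estimated condition carriers per stratum within the catchment.

    Returns a frame indexed by the stratum grid with columns ``population``
    (Pop_g, summed over catchment tracts), ``prevalence`` (prev_g),
    ``prevalence_level`` (fallback level used) and ``condition_population``
    (P_g = Pop_g * prev_g).
    """
    pop = population
    if catchment is not None:
        tracts = set(getattr(catchment, "tract_ids", catchment))
        pop = pop[pop["tract_id"].isin(tracts)]
    pop_g = (
        pop.groupby(["age_band", "race", "gender"], observed=True)["population"]
        .sum()
        .reindex(config.grid_index(), fill_value=0.0)
    )
    tables = _prevalence_lookups(prevalence, config.condition)
    prevs, levels = [], []
    for band, race, gender in pop_g.index:
        p, level = resolve_prevalence(band, race, gender, tables)
        prevs.append(p)
        levels.append(level)
    out = pop_g.to_frame("population")
    out["prevalence"] = prevs
    out["prevalence_level"] = levels
    out["condition_population"] = out["population"] * out["prevalence"]
    return out


def utilization_rates(u_total: int, c_total: int, p_total: float) -> UtilizationRates:
    """Average propensity u = U/P_total and frequency f = C/U.

    ``u_total`` is the number of distinct observed condition patients,
    ``c_total`` the number of observed condition encounters and ``p_total``
    the estimated condition population of the catchment (must be > 0).
    """
    if p_total <= 0:
        raise ExpectedModelError("no condition population in catchment (P_total must be > 0)")
    if u_total < 0 or c_total < u_total:
        raise ValueError("need 0 <= distinct patients <= encounters")
    if u_total == 0:
        return UtilizationRates(0.0, 0.0, warning=True)
    return UtilizationRates(u_total / p_total, c_total / u_total)


def expected_encounters(cond_pop: pd.DataFrame, rates: UtilizationRates) -> pd.DataFrame:
    """Attach E_g = P_g * u * f; Sum E_g equals the observed encounter total
    by construction (u*f = C_total / P_total)."""
    out = cond_pop.copy()
    out["expected"] = out["condition_population"] * rates.propensity * rates.frequency
    return out
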