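"""Synthetic encounter/population/prevalence generator with planted disparities.

The generator emulates the three inputs of the equity pipeline — an
EHR-style encounter extract, ACS-style tract populations by stratum and a
prevalence table — under a fully known mechanism, so every stage has a
recovery oracle and no external data are needed:

* tract populations: each stratum's total is split over census tracts by
  a Dirichlet-drawn share vector (one "far" tract holds a configurable
  share so the 80% catchment rule excludes somebody);
* condition carriers per tract x stratum ~ Binomial(pop, prevalence);
* observed patients ~ Binomial(carriers, u0 * m_g), with m_g the planted
  disparity multiplier of the stratum;
* encounters per patient = 1 + Poisson(lambda0), so the mean frequency is
  1 + lambda0 >= 1.

Because the pipeline estimates the propensity-frequency product from the
pooled data, the expected Health Equity Score of stratum g has the closed
form HES*_g = m_g / m_bar with m_bar the condition-population-weighted
mean multiplier: the pooled average absorbs the overall excess, and each
stratum's score measures its multiplier relative to that average. The
same form holds when the multiplier acts on encounter frequency instead
of propensity, since u and f enter the expected counts only through
their product.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .core import ConditionConfig, ENCOUNTER_COLUMNS, Stratum

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "generate_scenario",
    "expected_hes_closed_form",
    "recovery_experiment",
    "RecoveryReport",
]


class ScenarioConfig(BaseModel):
    """Parameters of one synthetic scenario.

    ``multipliers`` plant group-level disparities: keys are either full
    stratum labels (``"20-44|AA|F"``) or race labels (applied to every
    stratum of that race); unlisted strata get multiplier 1. In
    ``multiplier_mode="propensity"`` the multiplier scales the chance a
    carrier becomes a patient (so ``u0 * m`` must stay <= 1); in
    ``"frequency"`` mode it scales the mean encounters per patient.
    ``tract_concentration`` is the Dirichlet concentration of the tract
    share vector: smaller values concentrate patients in fewer tracts.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    condition: str = "asthma"
    code_prefix: str = "J45"
    facility_id: str = "HOSP-A"
    window_start: dt.date = dt.date(2016, 1, 1)
    window_end: dt.date = dt.date(2017, 1, 1)
    n_tracts: int = 12
    population_per_stratum: float = 10_000.0
    stratum_weights: dict[str, float] = {}
    prevalence: float = 0.089
    race_prevalence: dict[str, float] = {}
    u0: float = 0.10
    lambda0: float = 0.35
    multipliers: dict[str, float] = {}
    multiplier_mode: Literal["propensity", "frequency"] = "propensity"
    tract_concentration: float = 1.0
    far_share: float = 0.05
    open_band_width: int = 25

    @model_validator(mode="after")
    def _check(self):
        if not (0.0 <= self.u0 <= 1.0):
            raise ValueError("baseline propensity u0 must lie in [0, 1]")
        if self.lambda0 < 0:
            raise ValueError("baseline mean extra encounters lambda0 must be >= 0")
        if self.n_tracts < 1:
            raise ValueError("need at least one tract")
        if not (0.0 <= self.far_share < 1.0):
            raise ValueError("far-tract share must lie in [0, 1)")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("planted multipliers must be > 0")
        if self.stratum_weights and (
            any(w < 0 for w in self.stratum_weights.values())
            or sum(self.stratum_weights.values()) <= 0
        ):
            raise ValueError("stratum weights must be >= 0 with positive sum")
        for p in [self.prevalence, *self.race_prevalence.values()]:
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalence must lie in [0, 1]")
        if self.multiplier_mode == "propensity":
            if self.u0 * max(self.multipliers.values(), default=1.0) > 1.0:
                raise ValueError("u0 * multiplier exceeds 1: not a valid propensity")
        else:
            lam_floor = (1.0 + self.lambda0) * min(self.multipliers.values(), default=1.0) - 1.0
            if lam_floor < 0:
                raise ValueError(
                    "frequency multiplier too small: mean encounters per patient would fall below 1"
                )
        return self

    def condition_config(self) -> ConditionConfig:
        return ConditionConfig(
            condition=self.condition,
            code_prefixes=(self.code_prefix,),
            window_start=self.window_start,
            window_end=self.window_end,
            facility_id=self.facility_id,
        )

    def multiplier_for(self, stratum: Stratum) -> float:
        if stratum.label in self.multipliers:
            return self.multipliers[stratum.label]
        return self.multipliers.get(stratum.race, 1.0)

    def prevalence_for(self, stratum: Stratum) -> float:
        return self.race_prevalence.get(stratum.race, self.prevalence)


@dataclasses.dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth they were drawn from."""

    encounters: pd.DataFrame
    population: pd.DataFrame
    prevalence: pd.DataFrame
    truth: dict
    config: ScenarioConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        enc = self.encounters.assign(date=self.encounters["date"].dt.strftime("%Y-%m-%d"))
        enc.to_csv(out / "encounters.csv", index=False)
        self.population.to_csv(out / "population.csv", index=False, float_format="%.17g")
        self.prevalence.to_csv(out / "prevalence.csv", index=False, float_format="%.17g")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def expected_hes_closed_form(
    multipliers: np.ndarray, condition_shares: np.ndarray
) -> np.ndarray:
    """Expected Health Equity Scores under the generator: HES*_g = m_g / m_bar.

    ``condition_shares`` are the strata's shares of the condition population
    (must sum to 1); ``m_bar`` is their weighted mean multiplier.
    """
    m = np.asarray(multipliers, dtype=float)
    pi = np.asarray(condition_shares, dtype=float)
    if m.shape != pi.shape:
        raise ValueError("multipliers and shares must have the same shape")
    if np.any(m <= 0):
        raise ValueError("multipliers must be > 0")
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("condition-population shares must sum to 1")
    return m / float(pi @ m)


def expected_index_closed_form(
    multipliers: np.ndarray, condition_shares: np.ndarray
) -> float:
    """Expected index: 1 + encounter-weighted mean excess of HES* over 1.

    Expected encounter weights are proportional to share x multiplier,
    restricted to strata with HES* > 1.
    """
    m = np.asarray(multipliers, dtype=float)
    pi = np.asarray(condition_shares, dtype=float)
    hes = expected_hes_closed_form(m, pi)
    x = hes > 1.0
    if not x.any():
        return 1.0
    w = pi[x] * m[x]
    return 1.0 + float(np.sum(w * (hes[x] - 1.0)) / np.sum(w))


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Draw one fully reproducible synthetic dataset from a scenario config."""
    rng = np.random.default_rng(config.seed)
    ccfg = config.condition_config()
    grid = ccfg.stratum_grid()

    tract_ids = [f"T{i:03d}" for i in range(1, config.n_tracts + 1)]
    shares = rng.dirichlet(np.full(config.n_tracts, config.tract_concentration))
    if config.far_share > 0:
        shares = np.append(shares * (1.0 - config.far_share), config.far_share)
        tract_ids.append("T-FAR")

    weights = np.array(
        [config.stratum_weights.get(s.label, 1.0) for s in grid], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("stratum weights sum to zero over the grid")
    weights = weights / weights.mean()
    totals = np.rint(config.population_per_stratum * weights).astype(int)

    n_days = (config.window_end - config.window_start).days
    window_start = pd.Timestamp(config.window_start)
    diagnosis = f"{config.code_prefix}.9"

    pop_rows: list[dict] = []
    enc: dict[str, list] = {c: [] for c in ENCOUNTER_COLUMNS}
    pid = 0
    eid = 0
    for s, total in zip(grid, totals):
        prev = config.prevalence_for(s)
        m = config.multiplier_for(s)
        if config.multiplier_mode == "propensity":
            p_patient, lam = config.u0 * m, config.lambda0
        else:
            p_patient, lam = config.u0, (1.0 + config.lambda0) * m - 1.0

        pop_t = rng.multinomial(total, shares)
        carriers_t = rng.binomial(pop_t, prev)
        patients_t = rng.binomial(carriers_t, p_patient)
        for tract, p in zip(tract_ids, pop_t):
            pop_rows.append(
                {
                    "tract_id": tract,
                    "age_band": s.age_band.label,
                    "race": s.race,
                    "gender": s.gender,
                    "population": int(p),
                }
            )

        n_pat = int(patients_t.sum())
        if n_pat == 0:
            continue
        tracts = np.repeat(tract_ids[: len(patients_t)], patients_t)
        hi = s.age_band.hi if s.age_band.hi is not None else s.age_band.lo + config.open_band_width
        ages = rng.integers(s.age_band.lo, hi, n_pat)
        n_enc = 1 + rng.poisson(lam, n_pat)
        total_enc = int(n_enc.sum())
        dates = window_start + pd.to_timedelta(rng.integers(0, n_days, total_enc), unit="D")

        pids = np.array([f"P{pid + i:06d}" for i in range(n_pat)])
        eids = [f"E{eid + i:07d}" for i in range(total_enc)]
        pid += n_pat
        eid += total_enc

        enc["patient_id"].extend(np.repeat(pids, n_enc))
        enc["encounter_id"].extend(eids)
        enc["date"].extend(dates)
        enc["facility_id"].extend([config.facility_id] * total_enc)
        enc["diagnosis_code"].extend([diagnosis] * total_enc)
        enc["tract_id"].extend(np.repeat(tracts, n_enc))
        enc["age"].extend(np.repeat(ages, n_enc))
        enc["gender"].extend([s.gender] * total_enc)
        enc["race_ethnicity"].extend([s.race] * total_enc)

    encounters = pd.DataFrame(enc, columns=list(ENCOUNTER_COLUMNS))
    encounters["date"] = pd.to_datetime(encounters["date"])
    encounters["age"] = encounters["age"].astype(int) if len(encounters) else encounters["age"]
    population = pd.DataFrame(pop_rows)

    prev_rows = [
        {
            "condition": config.condition,
            "age_band": "",
            "race": "",
            "gender": "",
            "prevalence": config.prevalence,
            "source": "synthetic ground truth",
        }
    ]
    for race, p in sorted(config.race_prevalence.items()):
        prev_rows.append(
            {
                "condition": config.condition,
                "age_band": "",
                "race": race,
                "gender": "",
                "prevalence": p,
                "source": "synthetic ground truth",
            }
        )
    prevalence = pd.DataFrame(prev_rows, columns=list(("condition", "age_band", "race", "gender", "prevalence", "source")))

    m_vec = np.array([config.multiplier_for(s) for s in grid])
    cond_pop = totals * np.array([config.prevalence_for(s) for s in grid])
    pi = cond_pop / cond_pop.sum() if cond_pop.sum() > 0 else np.full(len(grid), 1.0 / len(grid))
    hes_star = expected_hes_closed_form(m_vec, pi)
    truth = {
        "u0": config.u0,
        "lambda0": config.lambda0,
        "multiplier_mode": config.multiplier_mode,
        "multipliers": {s.label: float(m) for s, m in zip(grid, m_vec)},
        "condition_population_shares": {s.label: float(p) for s, p in zip(grid, pi)},
        "hes_star": {s.label: float(h) for s, h in zip(grid, hes_star)},
        "index_star": expected_index_closed_form(m_vec, pi),
        "seed": config.seed,
    }
    return SyntheticDataset(encounters, population, prevalence, truth, config)


@dataclasses.dataclass
class RecoveryReport:
    """Monte-Carlo comparison of pipeline scores against the closed form."""

    per_stratum: pd.DataFrame  # mean_hes, hes_star, abs_error per stratum label
    indices: np.ndarray
    index_star: float
    n_reps: int

    @property
    def max_abs_hes_error(self) -> float:
        return float(self.per_stratum["abs_error"].max())

    @property
    def mean_abs_hes_error(self) -> float:
        return float(self.per_stratum["abs_error"].mean())

    @property
    def index_bias(self) -> float:
        return float(np.mean(self.indices) - self.index_star)


def recovery_experiment(config: ScenarioConfig, n_reps: int) -> RecoveryReport:
    """Score ``n_reps`` independent scenarios and compare with the closed form.

    Replicate seeds are derived deterministically from the scenario's seed,
    so the whole report is reproducible from one master seed.
    """
    from .scoring import score_facility  # local import to avoid a cycle

    if n_reps < 1:
        raise ValueError("need at least one replicate")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    hes_rows = []
    indices = []
    truth = None
    for rep, seed in enumerate(child_seeds):
        ds = generate_scenario(config.model_copy(update={"seed": int(seed)}))
        truth = ds.truth
        result = score_facility(ds.encounters, ds.population, ds.prevalence, ds.config.condition_config())
        hes = result.strata["hes"]
        labels = ["|".join(ix) for ix in hes.index]
        hes_rows.append(pd.Series(hes.to_numpy(), index=labels, name=rep))
        indices.append(result.index)

    hes_df = pd.DataFrame(hes_rows)
    star = pd.Series(truth["hes_star"])
    per_stratum = pd.DataFrame(
        {
            "mean_hes": hes_df.mean(axis=0),
            "hes_star": star,
        }
    )
    per_stratum["abs_error"] = (per_stratum["mean_hes"] - per_stratum["hes_star"]).abs()
    return RecoveryReport(
        per_stratum=per_stratum,
        indices=np.asarray(indices, dtype=float),
        index_star=truth["index_star"],
        n_reps=n_reps,
    )
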