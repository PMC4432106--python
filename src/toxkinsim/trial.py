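"""Realize a full virtual toxicology study into a long-format dataset.

A trial simulation draws individual parameters for every animal,
schedules doses and samples from the cohort design, predicts noise-free
concentrations, applies proportional residual error, and stores the
result in a NONMEM-like long format (columns ID, TIME, AMT, DV, EVID,
MDV, DOSEGRP, COHORT, ROLE, plus a TRUE_DV truth column that the
estimator-facing view strips).

Seeding: a replicate seed spawns independent child streams for
parameter sampling, composite-slot allocation, and residual noise, so
replicates are reproducible and independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CohortDesign, Role, Scheme, allocate_composite_samples
from .errors import InputError
from .models import (
    DoseRegimen,
    IndividualParameters,
    ModelSpec,
    PopulationParameters,
    predict_concentration,
    sample_individual_params,
    simulate_observations,
)

log = logging.getLogger(__name__)

__all__ = ["TKDataset", "simulate_trial", "apply_bql_filter",
           "write_dataset", "read_dataset", "read_estimation_data",
           "ESTIMATION_COLUMNS"]

#: columns visible to estimators (truth never leaks through this view)
ESTIMATION_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV",
                      "DOSEGRP", "COHORT", "ROLE"]
_ALL_COLUMNS = ESTIMATION_COLUMNS + ["TRUE_DV"]


@dataclass
class TKDataset:
    """Long-format toxicokinetic dataset with truth sidecar columns.

    ``df`` holds dose records (EVID=1, MDV=1, AMT in mg/kg) and
    observation records (EVID=0, MDV=0, DV in mg/ml) sorted by animal
    and time.  ``individual_params`` maps animal id to the simulated
    parameters (truth-keeping; estimators must use
    :meth:`estimator_view` / :func:`read_estimation_data`).
    """

    df: pd.DataFrame
    individual_params: dict[int, IndividualParameters] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_bql_removed: int = 0

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def estimator_view(self) -> pd.DataFrame:
        """Copy of the data without any truth columns."""
        return self.df[ESTIMATION_COLUMNS].copy()

    def animals(self, dose: float | None = None, role: Role | None = None) -> list[int]:
        m = pd.Series(True, index=self.df.index)
        if dose is not None:
            m &= self.df["DOSEGRP"] == dose
        if role is not None:
            m &= self.df["ROLE"] == role.value
        return sorted(self.df.loc[m, "ID"].unique())


def simulate_trial(
    design: CohortDesign,
    spec: ModelSpec,
    pop: PopulationParameters,
    replicate_seed: int | np.random.SeedSequence,
    provenance: Mapping | None = None,
) -> TKDataset:
    """Simulate one replicate of a full cohort study.

    Every animal in every dose group (vehicle included) receives daily
    oral doses for the study duration and its scheduled samples, with
    its own individual parameters and proportional residual error.
    """
    ss = (replicate_seed if isinstance(replicate_seed, np.random.SeedSequence)
          else np.random.SeedSequence(replicate_seed))
    ss_params, ss_alloc, ss_noise = ss.spawn(3)
    rng_params = np.random.default_rng(ss_params)
    rng_alloc = np.random.default_rng(ss_alloc)
    rng_noise = np.random.default_rng(ss_noise)

    n_days = design.n_days
    rows: list[dict] = []
    ind_params: dict[int, IndividualParameters] = {}
    next_id = 1
    for dose in design.dose_groups:
        for role in (Role.TOXICITY, Role.SATELLITE):
            n = design.group_size(role)
            sch = design.scheme_for(role)
            animals = sample_individual_params(pop, n, rng_params, first_id=next_id)
            next_id += n
            ids = [a.animal_id for a in animals]
            # per-animal observation times (h since first dose)
            obs_times: dict[int, list[float]] = {i: [] for i in ids}
            for day in sch.sampling_days:
                day_start = (day - 1) * 24.0
                if sch.scheme is Scheme.COMPOSITE:
                    alloc = allocate_composite_samples(
                        n, sch.times_within_day, sch.replicates_per_timepoint,
                        rng_alloc, day=day, animal_ids=ids)
                    for aid, ts in alloc.assignments.items():
                        obs_times[aid].extend(day_start + t for t in ts)
                else:
                    for aid in ids:
                        obs_times[aid].extend(day_start + t for t in sch.times_within_day)
            regimen = DoseRegimen(dose=dose, n_doses=n_days, interval=24.0)
            for animal in animals:
                ind_params[animal.animal_id] = animal
                t_obs = np.array(sorted(obs_times[animal.animal_id]))
                true_c = predict_concentration(spec, animal, regimen, t_obs)
                obs_c = simulate_observations(true_c, pop.sigma_prop, rng_noise)
                obs_c = np.maximum(obs_c, 0.0)
                for td in regimen.dose_times():
                    rows.append({"ID": animal.animal_id, "TIME": td, "AMT": dose,
                                 "DV": np.nan, "EVID": 1, "MDV": 1,
                                 "DOSEGRP": dose, "COHORT": design.duration.value,
                                 "ROLE": role.value, "TRUE_DV": np.nan})
                for t, c, ct in zip(t_obs, obs_c, true_c):
                    rows.append({"ID": animal.animal_id, "TIME": t, "AMT": 0.0,
                                 "DV": c, "EVID": 0, "MDV": 0,
                                 "DOSEGRP": dose, "COHORT": design.duration.value,
                                 "ROLE": role.value, "TRUE_DV": ct})
    df = pd.DataFrame(rows, columns=_ALL_COLUMNS)
    # within (ID, TIME) a dose precedes an observation (EVID descending)
    df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                        kind="stable").reset_index(drop=True)
    prov = dict(provenance or {})
    prov.setdefault("model_id", spec.model_id.value)
    prov.setdefault("cohort", design.duration.value)
    return TKDataset(df=df, individual_params=ind_params, provenance=prov)


def apply_bql_filter(ds: TKDataset, lloq: float) -> TKDataset:
    """Drop observation records with DV below the lower limit of
    quantification; dose records are untouched."""
    if lloq < 0:
        raise InputError("lloq must be >= 0")
    drop = (ds.df["EVID"] == 0) & (ds.df["DV"] < lloq)
    n_removed = int(drop.sum())
    if n_removed:
        log.info("BQL filter removed %d observations below %g mg/ml",
                 n_removed, lloq)
    out = TKDataset(
        df=ds.df[~drop].reset_index(drop=True),
        individual_params=dict(ds.individual_params),
        provenance={**ds.provenance, "lloq": lloq},
        n_bql_removed=n_removed,
    )
    return out


# ---------------------------------------------------------------------------
# CSV round trip (NONMEM-like dialect; '.' marks missing values)
# ---------------------------------------------------------------------------

def write_dataset(ds: TKDataset, path: str | Path, with_truth: bool = True) -> None:
    cols = _ALL_COLUMNS if with_truth else ESTIMATION_COLUMNS
    ds.df[cols].to_csv(path, index=False, na_rep=".")


def read_dataset(path: str | Path) -> TKDataset:
    df = pd.read_csv(path, na_values=".", float_precision="round_trip")
    cols = [c for c in _ALL_COLUMNS if c in df.columns]
    return TKDataset(df=df[cols])


def read_estimation_data(path: str | Path) -> pd.DataFrame:
    """Estimator-facing reader: truth columns are never exposed."""
    df = pd.read_csv(path, na_values=".", float_precision="round_trip")
    return df[ESTIMATION_COLUMNS].copy()
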