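"""Replicate simulation–estimation studies and bias/precision metrics.

Each replicate of a scenario simulates a full virtual toxicology study,
estimates exposure by NCA (composite and serial arms, arithmetic and
geometric summaries) and by FOCE-I mixed-effects modelling (one
integrated fit over all active dose groups), and records relative
errors against the replicate's own simulated truth.  Across replicates
the study reports:

* SMRE  = 1/N * sum_i (estimated_i - true_i)/true_i * 100      (bias)
* CV    = 1/N * sqrt( sum_i ((estimated_i - mean)/mean)^2 ) * 100

The CV formula above divides the root-sum-of-squares by N (not
sqrt(N-1)); it therefore shrinks ~1/sqrt(N) with the number of
replicates.  It is the study's printed definition and the default;
``cv_convention="sample"`` switches to the conventional sample CV.
Failed fits are excluded from SMRE/CV and counted in the convergence
and covariance rates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import Duration, build_cohort_design
from .errors import ConfigurationError, InputError
from .exposure import ADVERSE_THRESHOLD, ALL_MEASURES, exposure_from_params
from .models import (
    DoseRegimen,
    ModelId,
    ModelSpec,
    PopulationParameters,
    population_for,
)
from .nca import SummaryKind, composite_nca_summary, serial_nca_summary
from .nlme import fit_population
from .trial import TKDataset, apply_bql_filter, simulate_trial

log = logging.getLogger(__name__)

__all__ = [
    "smre", "cv", "relative_error",
    "ScenarioConfig", "ComparisonTable", "run_study", "run_replicate",
    "summarize_to_tables", "NCA_METHODS", "MODEL_METHOD",
]

NCA_METHODS = ("NCA_COMPOSITE_MEAN", "NCA_COMPOSITE_GEOMEAN",
               "NCA_SERIAL_MEAN", "NCA_SERIAL_GEOMEAN")
MODEL_METHOD = "MODEL"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def relative_error(estimate: float, true_value: float) -> float:
    """(estimate - true)/true * 100 (percent)."""
    if true_value == 0:
        raise InputError("relative error undefined for true value 0")
    return (estimate - true_value) / true_value * 100.0


def smre(estimates: Sequence[float], true_value: float | Sequence[float]) -> float:
    """Scaled relative mean error (percent): mean of per-estimate
    relative errors.  ``true_value`` may be a scalar or per-estimate."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise InputError("smre needs at least one estimate")
    true = np.broadcast_to(np.asarray(true_value, dtype=float), estimates.shape)
    if np.any(true == 0):
        raise InputError("smre undefined for true value 0")
    return float(np.mean((estimates - true) / true) * 100.0)


def cv(estimates: Sequence[float], convention: str = "printed") -> float:
    """Coefficient of variation (percent) across estimates.

    ``printed``: 1/N * sqrt(sum(((x - mean)/mean)^2)) * 100 — note the
    1/N outside the square root.  ``sample``: conventional
    sd(x, ddof=1)/mean * 100.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size == 0:
        raise InputError("cv needs at least one estimate")
    m = x.mean()
    if m == 0:
        raise InputError("cv undefined for zero mean")
    if convention == "printed":
        return float(np.sqrt(np.sum(((x - m) / m) ** 2)) / x.size * 100.0)
    if convention == "sample":
        if x.size < 2:
            return 0.0
        return float(np.std(x, ddof=1) / m * 100.0)
    raise ConfigurationError(f"unknown cv convention {convention!r}")


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything needed to run one replicate study reproducibly."""

    model_id: ModelId = ModelId.ONE_CMT
    duration: Duration = Duration.THREE_MONTHS
    dose_group: float = 30.0
    n_replicates: int = 200
    master_seed: int = 20150414
    lloq: float = 0.001          # mg/ml; inert at the reference exposures
    threshold: float = ADVERSE_THRESHOLD
    truth_convention: str = "individual-mean"  # or "typical"
    methods: tuple[str, ...] = NCA_METHODS + (MODEL_METHOD,)
    measures: tuple[str, ...] = ALL_MEASURES
    cv_convention: str = "printed"
    sigma_prop: float = 0.15
    init_factor: float = 1.5     # initial estimates = truth * factor
    do_covariance: bool = True
    fit_options: dict = field(default_factory=dict)  # forwarded to fit_population
    design_overrides: dict = field(default_factory=dict)
    population_overrides: dict = field(default_factory=dict)
    scenario_id: str = ""

    def __post_init__(self) -> None:
        self.model_id = ModelId(self.model_id)
        self.duration = Duration(self.duration)
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not self.methods:
            raise ConfigurationError("method list is empty")
        bad = set(self.methods) - set(NCA_METHODS) - {MODEL_METHOD}
        if bad:
            raise ConfigurationError(f"unknown methods: {sorted(bad)}")
        if self.truth_convention not in ("individual-mean", "typical"):
            raise ConfigurationError("truth_convention must be "
                                     "'individual-mean' or 'typical'")
        if not self.scenario_id:
            self.scenario_id = (f"{self.model_id.value}_{self.duration.value}"
                                f"_{self.dose_group:g}mgkg")

    # -- derived pieces -----------------------------------------------------
    def design(self):
        return build_cohort_design(self.duration, self.design_overrides)

    def population(self) -> PopulationParameters:
        pop = population_for(self.model_id, sigma_prop=self.sigma_prop)
        ov = dict(self.population_overrides)
        theta = {**pop.theta, **ov.get("theta", {})}
        bsv = {**pop.bsv_cv, **ov.get("bsv_cv", {})}
        return PopulationParameters(theta=theta, bsv_cv=bsv,
                                    sigma_prop=ov.get("sigma_prop", pop.sigma_prop))

    def spec(self) -> ModelSpec:
        return ModelSpec(self.model_id)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_id"] = self.model_id.value
        d["duration"] = self.duration.value
        d["methods"] = list(self.methods)
        d["measures"] = list(self.measures)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d.pop("schema_version", None)
        for key in ("methods", "measures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# One replicate
# ---------------------------------------------------------------------------

def _truth_exposures(cfg: ScenarioConfig, ds: TKDataset, evaluation_day: int,
                     n_days: int, measures) -> dict[str, float]:
    """Replicate truth per measure.  'individual-mean' averages the
    exposures of the analyzed group's simulated animals; 'typical' uses
    the population typical values."""
    spec = cfg.spec()
    regimen = DoseRegimen(dose=cfg.dose_group, n_doses=n_days)
    if cfg.truth_convention == "typical":
        es = exposure_from_params(spec, cfg.population(), regimen,
                                  evaluation_day, cfg.threshold, measures)
        return {m: es.as_dict()[m] for m in measures}
    ids = ds.animals(dose=cfg.dose_group)
    per_animal = []
    for aid in ids:
        es = exposure_from_params(spec, ds.individual_params[aid], regimen,
                                  evaluation_day, cfg.threshold, measures)
        per_animal.append(es.as_dict())
    return {m: float(np.mean([pa[m] for pa in per_animal])) for m in measures}


def run_replicate(cfg: ScenarioConfig, replicate_index: int) -> list[dict]:
    """Simulate one replicate and estimate exposure with every method.

    Returns tidy rows: one per (method, measure) with the estimate, the
    replicate truth, the relative error, and fit bookkeeping.
    """
    ss = np.random.SeedSequence(entropy=cfg.master_seed,
                                spawn_key=(replicate_index,))
    design = cfg.design()
    spec = cfg.spec()
    pop = cfg.population()
    ds = simulate_trial(design, spec, pop, ss,
                        provenance={"scenario": cfg.scenario_id,
                                    "replicate": replicate_index,
                                    "master_seed": cfg.master_seed})
    ds = apply_bql_filter(ds, cfg.lloq)
    evaluation_day = design.last_serial_day
    measures = tuple(m for m in cfg.measures if m in ALL_MEASURES)
    truth = _truth_exposures(cfg, ds, evaluation_day, design.n_days, measures)

    rows: list[dict] = []

    def add(method, measure, estimate, converged=True, covariance_ok=True,
            error="", extra=None):
        t = truth.get(measure)
        rel = (relative_error(estimate, t)
               if (estimate is not None and t not in (None, 0)) else np.nan)
        rows.append({
            "scenario": cfg.scenario_id, "replicate": replicate_index,
            "method": method, "measure": measure,
            "estimate": estimate, "truth": t, "rel_err": rel,
            "converged": converged, "covariance_ok": covariance_ok,
            "error": error, **(extra or {}),
        })

    nca_kinds = {
        "NCA_COMPOSITE_MEAN": ("composite", SummaryKind.ARITHMETIC),
        "NCA_COMPOSITE_GEOMEAN": ("composite", SummaryKind.GEOMETRIC),
        "NCA_SERIAL_MEAN": ("serial", SummaryKind.ARITHMETIC),
        "NCA_SERIAL_GEOMEAN": ("serial", SummaryKind.GEOMETRIC),
    }
    nca_field = {"auc24": "auc24", "cmax24": "cmax24", "tat24": "tat24"}
    for method in cfg.methods:
        if method == MODEL_METHOD:
            continue
        arm, kind = nca_kinds[method]
        try:
            if arm == "composite":
                day = max(design.toxicity_scheme.sampling_days)
                res = composite_nca_summary(ds, cfg.dose_group, day, kind,
                                            cfg.threshold)
            else:
                res = serial_nca_summary(ds, cfg.dose_group, evaluation_day,
                                         kind, cfg.threshold)
            for m in measures:
                if m in nca_field:
                    add(method, m, getattr(res, nca_field[m]))
        except Exception as exc:  # per-replicate failures never abort a study
            log.warning("replicate %d %s failed: %s", replicate_index, method, exc)
            for m in measures:
                if m in nca_field:
                    add(method, m, None, error=str(exc))

    if MODEL_METHOD in cfg.methods:
        init = PopulationParameters(
            theta={k: v * cfg.init_factor for k, v in pop.theta.items()},
            bsv_cv={k: v * cfg.init_factor for k, v in pop.bsv_cv.items()},
            sigma_prop=pop.sigma_prop * cfg.init_factor,
        )
        try:
            fit = fit_population(ds, spec, init, do_covariance=cfg.do_covariance,
                                 **cfg.fit_options)
            regimen = DoseRegimen(dose=cfg.dose_group, n_doses=design.n_days)
            es = exposure_from_params(spec, fit.theta, regimen, evaluation_day,
                                      cfg.threshold, measures)
            fitted = {f"fit_{k}": v for k, v in fit.theta.items()}
            for m in measures:
                add(MODEL_METHOD, m, es.as_dict()[m],
                    converged=fit.converged,
                    covariance_ok=fit.covariance_ok, extra=fitted)
        except Exception as exc:
            log.warning("replicate %d model fit failed: %s", replicate_index, exc)
            for m in measures:
                add(MODEL_METHOD, m, None, converged=False,
                    covariance_ok=False, error=str(exc))
    return rows


# ---------------------------------------------------------------------------
# Study orchestration and summary
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-(scenario, method, measure) SMRE/CV/quantile summary plus the
    per-replicate records behind it."""

    summary: pd.DataFrame
    records: pd.DataFrame
    config: ScenarioConfig

    def row(self, method: str, measure: str) -> pd.Series:
        df = self.summary
        m = (df["method"] == method) & (df["measure"] == measure)
        if not m.any():
            raise KeyError((method, measure))
        return df[m].iloc[0]

    def rel_errors(self, method: str, measure: str) -> np.ndarray:
        r = self.records
        m = ((r["method"] == method) & (r["measure"] == measure)
             & r["rel_err"].notna())
        if method == MODEL_METHOD:
            m &= r["converged"]
        return r.loc[m, "rel_err"].to_numpy(dtype=float)


def run_study(cfg: ScenarioConfig, n_jobs: int = 1) -> ComparisonTable:
    """Run the full replicate study for one scenario.

    Replicates are seeded independently from the master seed, so the
    result is identical however the replicate loop is executed or
    parallelized (``n_jobs`` > 1 distributes replicates over joblib
    workers).  Per-replicate failures are recorded, never fatal.
    """
    if n_jobs == 1:
        per_replicate = [run_replicate(cfg, r) for r in range(cfg.n_replicates)]
    else:
        from joblib import Parallel, delayed

        per_replicate = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(cfg, r) for r in range(cfg.n_replicates))
    all_rows = [row for rows in per_replicate for row in rows]
    records = pd.DataFrame(all_rows)
    summary = _summarize(records, cfg)
    return ComparisonTable(summary=summary, records=records, config=cfg)


def _summarize(records: pd.DataFrame, cfg: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for (method, measure), grp in records.groupby(["method", "measure"]):
        usable = grp[grp["estimate"].notna()]
        if method == MODEL_METHOD:
            n_total = len(grp)
            conv_rate = 100.0 * grp["converged"].sum() / n_total
            cov_rate = 100.0 * grp["covariance_ok"].sum() / n_total
            usable = usable[usable["converged"]]
        else:
            conv_rate = cov_rate = np.nan
        est = usable["estimate"].to_numpy(dtype=float)
        true = usable["truth"].to_numpy(dtype=float)
        rel = usable["rel_err"].to_numpy(dtype=float)
        row = {
            "scenario": cfg.scenario_id, "method": method, "measure": measure,
            "n_used": len(usable),
            "smre": smre(est, true) if len(est) and np.all(true != 0) else np.nan,
            "cv": cv(est, cfg.cv_convention) if len(est) else np.nan,
            "cv_convention": cfg.cv_convention,
            "convergence_rate": conv_rate, "covariance_rate": cov_rate,
        }
        for q in (5, 25, 50, 75, 95):
            row[f"re_q{q:02d}"] = (float(np.percentile(rel, q))
                                   if len(rel) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_to_tables(table: ComparisonTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy summary, the per-replicate records, and a
    human-readable text table; returns the paths written."""
    if table.summary.empty:
        raise InputError("empty comparison table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = table.config.scenario_id
    paths = {
        "summary": out / f"{sid}_summary.csv",
        "records": out / f"{sid}_records.csv",
        "report": out / f"{sid}_report.txt",
        "config": out / f"{sid}_config.yaml",
    }
    table.summary.to_csv(paths["summary"], index=False)
    table.records.to_csv(paths["records"], index=False)
    with open(paths["report"], "w") as fh:
        fh.write(f"Scenario {sid}\n")
        fh.write(table.summary.to_string(index=False, float_format="%.4g"))
        fh.write("\n")
    table.config.to_yaml(paths["config"])
    return paths
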