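"""Replicate runner and aggregator for the four-scenario bias study.

One replicate simulates a full population, forms the four observation
samples, and applies every estimator.  An experiment repeats this (1000
replicates by default in the study design), then summarises each estimate by
its mean and standard deviation across replicates, records the fraction of
replicates in which each Kaplan-Meier median was defined, and computes bias.

Bias convention: ``true value - averaged estimate``, so positive bias means
underestimation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import complete_mean, complete_median, km_fit, km_median, sample_median
from .population import simulate_population
from .sampling import (
    SurvivalSample,
    assign_weights,
    cohort_sample,
    period_sample,
    prospective_sample,
    retrospective_sample,
)
from .scenarios import (
    ScenarioConfig,
    ScenarioSchedule,
    build_schedule,
    true_window_values,
)

__all__ = [
    "ReplicateResult",
    "SummaryStat",
    "ExperimentSummary",
    "run_replicate",
    "run_experiment",
    "compute_bias",
    "summarize_replicates",
    "replicates_to_frame",
    "frame_to_replicates",
    "make_tables",
    "make_boxplots",
]

logger = logging.getLogger(__name__)

#: Default weight for the fixed-weight censored Kaplan-Meier variant.
FIXED_CENSOR_WEIGHT = 0.1

#: Fraction of replicates in which a KM median must be defined for its
#: summary cell to be reported (otherwise the cell is NA).
NA_FRACTION_THRESHOLD = 0.5

#: Per-replicate estimate fields, in reporting order.
ESTIMATE_FIELDS = (
    "period_mean",
    "period_median",
    "cohort_mean",
    "cohort_median",
    "deaths_in_window",
    "deaths_since_start",
    "km_retro_nocensor",
    "km_retro_censored",
    "km_retro_w01",
    "km_retro_wpct",
    "prospective_deaths_in_window",
    "prospective_n",
    "km_prospective",
)

#: Fields that may be undefined (None) in a replicate.
_OPTIONAL_FIELDS = (
    "period_mean",
    "period_median",
    "cohort_mean",
    "cohort_median",
    "km_retro_nocensor",
    "km_retro_censored",
    "km_retro_w01",
    "km_retro_wpct",
    "km_prospective",
)


@dataclass(frozen=True)
class ReplicateResult:
    """All estimates from one simulated population."""

    scenario_id: int
    seed: int
    period_mean: Optional[float]
    period_median: Optional[float]
    cohort_mean: Optional[float]
    cohort_median: Optional[float]
    deaths_in_window: int
    deaths_since_start: int
    km_retro_nocensor: Optional[float]
    km_retro_censored: Optional[float]
    km_retro_w01: Optional[float]
    km_retro_wpct: Optional[float]
    prospective_deaths_in_window: int
    prospective_n: int
    km_prospective: Optional[float]

    def __post_init__(self) -> None:
        if self.deaths_in_window > self.deaths_since_start:
            raise ValueError("deaths_in_window cannot exceed deaths_since_start")


@dataclass(frozen=True)
class SummaryStat:
    """Across-replicate summary of one estimate."""

    mean: Optional[float]
    sd: Optional[float]
    frac_defined: float
    n_defined: int

    @property
    def is_na(self) -> bool:
        """True when the estimate was defined in too few replicates to report."""
        return self.frac_defined < NA_FRACTION_THRESHOLD or self.mean is None

    @property
    def reported(self) -> Optional[float]:
        """The reportable value: the across-replicate mean, or None for NA."""
        return None if self.is_na else self.mean


@dataclass
class ExperimentSummary:
    """Aggregated results of one scenario's replicates."""

    scenario_id: int
    n_reps: int
    base_seed: int
    true_mean: float
    true_median: float
    stats: dict[str, SummaryStat]
    bias: dict[str, Optional[float]] = field(default_factory=dict)
    replicates: list[ReplicateResult] = field(default_factory=list)


def _safe_km_median(sample: SurvivalSample) -> Optional[float]:
    try:
        return km_median(km_fit(sample))
    except ValueError:
        return None


def run_replicate(
    config: ScenarioConfig,
    seed: int,
    schedule: ScenarioSchedule | None = None,
) -> ReplicateResult:
    """Simulate one population and compute every estimate.

    Deterministic given ``(config, seed)``.  Passing a prebuilt ``schedule``
    skips re-solving the per-year Weibull parameters.  Undefined estimates
    (for example a Kaplan-Meier median that is never reached) are carried as
    ``None``; a replicate never aborts for that reason.
    """
    if schedule is None:
        schedule = build_schedule(config)
    rng = np.random.default_rng(seed)
    pop = simulate_population(schedule, config, rng)

    period = period_sample(pop, config)
    cohort = cohort_sample(pop, config)
    retro = retrospective_sample(pop, config)
    prosp = prospective_sample(pop, config)

    # No-censoring retrospective KM: the window deaths treated as all events.
    period_events = SurvivalSample(
        times=period,
        events=np.ones(period.size, dtype=bool),
        weights=np.ones(period.size),
    ) if period.size else None

    try:
        retro_wpct = assign_weights(retro, "uncensored_percentage")
    except ValueError:
        retro_wpct = None

    return ReplicateResult(
        scenario_id=config.scenario_id,
        seed=int(seed),
        period_mean=complete_mean(period),
        period_median=sample_median(period),
        cohort_mean=complete_mean(cohort),
        cohort_median=complete_median(cohort),
        deaths_in_window=int(period.size),
        deaths_since_start=len(retro),
        km_retro_nocensor=(
            _safe_km_median(period_events) if period_events is not None else None
        ),
        km_retro_censored=_safe_km_median(retro),
        km_retro_w01=_safe_km_median(
            assign_weights(retro, "fixed", w=FIXED_CENSOR_WEIGHT)
        ),
        km_retro_wpct=(
            _safe_km_median(retro_wpct) if retro_wpct is not None else None
        ),
        prospective_deaths_in_window=prosp.n_events,
        prospective_n=len(prosp),
        km_prospective=_safe_km_median(prosp),
    )


def replicate_seeds(config: ScenarioConfig, n_reps: int, base_seed: int) -> np.ndarray:
    """Derive one child seed per replicate from ``(base_seed, scenario_id)``.

    Uses a seed sequence so different scenarios and replicates get
    independent streams while staying reproducible from the single base seed.
    """
    ss = np.random.SeedSequence([int(base_seed), int(config.scenario_id)])
    return ss.generate_state(n_reps, dtype=np.uint32)


def compute_bias(
    true_value: Optional[float], estimate_mean: Optional[float]
) -> Optional[float]:
    """Bias as ``true value - averaged estimate`` (positive = underestimation)."""
    if true_value is None or estimate_mean is None:
        return None
    return true_value - estimate_mean


def summarize_replicates(
    config: ScenarioConfig,
    results: Sequence[ReplicateResult],
    base_seed: int = 0,
) -> ExperimentSummary:
    """Aggregate per-replicate results into an :class:`ExperimentSummary`.

    Means and standard deviations are computed over the replicates in which
    each estimate is defined; the fraction defined is recorded alongside.
    """
    if not results:
        raise ValueError("need at least one replicate")
    schedule = build_schedule(config)
    true = true_window_values(schedule, config)

    stats: dict[str, SummaryStat] = {}
    for name in ESTIMATE_FIELDS:
        values = [getattr(r, name) for r in results]
        defined = np.array([v for v in values if v is not None], dtype=float)
        frac = defined.size / len(values)
        if defined.size == 0:
            stats[name] = SummaryStat(None, None, 0.0, 0)
            continue
        sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
        stats[name] = SummaryStat(float(defined.mean()), sd, frac, int(defined.size))
        if name in _OPTIONAL_FIELDS and frac < 1.0:
            logger.info(
                "scenario %d: %s undefined in %d/%d replicates",
                config.scenario_id, name, len(values) - defined.size, len(values),
            )
        if name.startswith("km_") and frac < NA_FRACTION_THRESHOLD:
            logger.warning(
                "scenario %d: %s defined in only %.0f%% of replicates; cell is NA",
                config.scenario_id, name, 100 * frac,
            )

    bias = {
        "period_mean": compute_bias(true.mean, stats["period_mean"].mean),
        "cohort_mean": compute_bias(true.mean, stats["cohort_mean"].mean),
        "period_median": compute_bias(true.median, stats["period_median"].mean),
        "cohort_median": compute_bias(true.median, stats["cohort_median"].mean),
    }
    return ExperimentSummary(
        scenario_id=config.scenario_id,
        n_reps=len(results),
        base_seed=int(base_seed),
        true_mean=true.mean,
        true_median=true.median,
        stats=stats,
        bias=bias,
        replicates=list(results),
    )


def run_experiment(
    config: ScenarioConfig,
    n_reps: int,
    base_seed: int,
    progress: bool = False,
) -> ExperimentSummary:
    """Run ``n_reps`` replicates of one scenario and aggregate them."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    schedule = build_schedule(config)
    seeds = replicate_seeds(config, n_reps, base_seed)
    results = []
    for r, seed in enumerate(seeds):
        results.append(run_replicate(config, int(seed), schedule=schedule))
        if progress and (r + 1) % 200 == 0:
            logger.info(
                "scenario %d: %d/%d replicates done", config.scenario_id, r + 1, n_reps
            )
    return summarize_replicates(config, results, base_seed=base_seed)


# ---------------------------------------------------------------------------
# Replicate-level I/O


def replicates_to_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """One row per replicate; undefined estimates become NaN."""
    rows = []
    for r in results:
        row = {f.name: getattr(r, f.name) for f in fields(ReplicateResult)}
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_replicates(df: pd.DataFrame) -> list[ReplicateResult]:
    """Inverse of :func:`replicates_to_frame` (NaN back to None)."""
    results = []
    for row in df.to_dict(orient="records"):
        kwargs = {}
        for f in fields(ReplicateResult):
            v = row[f.name]
            if f.name in _OPTIONAL_FIELDS and (v is None or (isinstance(v, float) and math.isnan(v))):
                kwargs[f.name] = None
            elif f.name in ("scenario_id", "seed", "deaths_in_window",
                            "deaths_since_start", "prospective_deaths_in_window",
                            "prospective_n"):
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = float(v)
        results.append(ReplicateResult(**kwargs))
    return results


# ---------------------------------------------------------------------------
# Tables

_TABLE2_MEASURES = (
    "deaths_in_window",
    "deaths_since_start",
    "km_retro_nocensor",
    "km_retro_censored",
    "km_retro_w01",
    "km_retro_wpct",
    "prospective_deaths_in_window",
    "prospective_n",
    "km_prospective",
)


def _require_all_scenarios(
    summaries: Mapping[int, ExperimentSummary]
) -> list[ExperimentSummary]:
    missing = [s for s in (1, 2, 3, 4) if s not in summaries]
    if missing:
        raise ValueError(f"missing scenario summaries: {missing}")
    return [summaries[s] for s in (1, 2, 3, 4)]


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}"


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def make_tables(
    summaries: Mapping[int, ExperimentSummary], outdir: str | Path
) -> dict[str, Path]:
    """Write the two summary tables as CSV (2 decimals) and JSON (full precision).

    Table 1: true vs averaged period/cohort means and medians, with
    across-replicate standard deviations and biases.  Table 2: death counts
    and the Kaplan-Meier median variants, one column per scenario; cells
    whose estimate was defined in under half the replicates are NA.
    """
    ordered = _require_all_scenarios(summaries)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- Table 1 -----------------------------------------------------------
    t1_rows = []
    t1_json: dict[str, dict] = {}
    for s in ordered:
        row = {"scenario": s.scenario_id, "true_mean": s.true_mean}
        cell: dict[str, object] = {
            "true_mean": s.true_mean,
            "true_median": s.true_median,
            "n_reps": s.n_reps,
        }
        for est in ("period_mean", "cohort_mean", "period_median", "cohort_median"):
            st = s.stats[est]
            row[est] = st.reported
            row[f"{est}_sd"] = st.sd
            row[f"{est}_bias"] = s.bias[est]
            cell[est] = {
                "mean": st.mean,
                "sd": st.sd,
                "bias": s.bias[est],
                "frac_defined": st.frac_defined,
            }
        row["true_median"] = s.true_median
        t1_rows.append(row)
        t1_json[str(s.scenario_id)] = cell

    t1_cols = ["scenario", "true_mean", "period_mean", "period_mean_sd",
               "period_mean_bias", "cohort_mean", "cohort_mean_sd",
               "cohort_mean_bias", "true_median", "period_median",
               "period_median_sd", "period_median_bias", "cohort_median",
               "cohort_median_sd", "cohort_median_bias"]
    t1_csv = pd.DataFrame(t1_rows)[t1_cols]
    for c in t1_cols[1:]:
        t1_csv[c] = t1_csv[c].map(lambda v: _fmt(v) if v is not None else "NA")

    # --- Table 2 -----------------------------------------------------------
    t2_rows = []
    t2_json: dict[str, dict] = {m: {} for m in _TABLE2_MEASURES}
    for measure in _TABLE2_MEASURES:
        row: dict[str, object] = {"measure": measure}
        for s in ordered:
            st = s.stats[measure]
            row[f"scenario_{s.scenario_id}"] = _fmt(st.reported)
            t2_json[measure][str(s.scenario_id)] = {
                "mean": st.mean,
                "reported": st.reported,
                "frac_defined": st.frac_defined,
            }
        t2_rows.append(row)
    t2_csv = pd.DataFrame(t2_rows)

    paths = {
        "table1_csv": outdir / "table1.csv",
        "table1_json": outdir / "table1.json",
        "table2_csv": outdir / "table2.csv",
        "table2_json": outdir / "table2.json",
    }
    t1_csv.to_csv(paths["table1_csv"], index=False)
    _json_dump(t1_json, paths["table1_json"])
    t2_csv.to_csv(paths["table2_csv"], index=False)
    _json_dump(t2_json, paths["table2_json"])
    return paths


# ---------------------------------------------------------------------------
# Figures


def make_boxplots(
    summaries: Mapping[int, ExperimentSummary],
    outdir: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Boxplot-style panels of per-replicate period estimates, one per scenario.

    Grey points are single-replicate period mean/median estimates, the black
    point is their across-replicate average, and the dashed horizontal lines
    mark the true mean (blue) and true median (orange).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for scenario_id, s in sorted(summaries.items()):
        if not s.replicates:
            raise ValueError(
                f"scenario {scenario_id}: no replicate-level results retained"
            )
        means = np.array(
            [r.period_mean for r in s.replicates if r.period_mean is not None]
        )
        medians = np.array(
            [r.period_median for r in s.replicates if r.period_median is not None]
        )
        rng = np.random.default_rng(0)  # jitter only, cosmetic
        fig, ax = plt.subplots(figsize=(5, 5))
        for x0, vals in ((1.0, means), (2.0, medians)):
            x = x0 + rng.uniform(-0.12, 0.12, size=vals.size)
            ax.scatter(x, vals, s=6, color="0.6", alpha=0.4, linewidths=0)
            ax.scatter([x0], [vals.mean()], s=45, color="black", zorder=3)
        ax.axhline(s.true_mean, color="tab:blue", linestyle="--", label="true mean")
        ax.axhline(s.true_median, color="tab:orange", linestyle="--", label="true median")
        ax.set_xticks([1.0, 2.0], ["period mean", "period median"])
        ax.set_ylabel("estimated survival (years)")
        ax.set_title(f"Scenario {scenario_id}")
        ax.legend(loc="upper right", fontsize=8)
        path = outdir / f"fig1_scenario{scenario_id}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
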