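"""Patient-clustered bootstrap, weekly drift, and report assembly.

Confidence intervals resample at the patient level: each bootstrap draw
takes all encounters of each sampled patient, which respects within-patient
correlation that naive encounter resampling would ignore.  Intervals are
percentile intervals over the replicate statistics — reproducible and
assumption-light, since no distributional form is asserted for the
resampled metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from .model import UndefinedMetricError, logger
from .metrics import auprc, auroc


class BootstrapConfig(BaseModel):
    n_boot: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    method: str = "percentile"

    @field_validator("n_boot")
    @classmethod
    def _enough(cls, v: int) -> int:
        if v < 100:
            raise ValueError("n_boot must be >= 100 for reported CIs")
        return v

    @field_validator("ci_level")
    @classmethod
    def _level(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("ci_level must be in (0, 1)")
        return v


@dataclass
class MetricEstimate:
    name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_failed_replicates: int = 0
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failed_replicates": self.n_failed_replicates,
            "flagged": self.flagged,
        }


def clustered_bootstrap(
    instances: pd.DataFrame,
    statistic,
    config: BootstrapConfig | None = None,
    name: str = "statistic",
) -> MetricEstimate:
    """Percentile bootstrap CI with patient-level cluster resampling.

    ``statistic(scores, labels) -> float`` is evaluated on the full sample
    for the point estimate and on each replicate formed by drawing patients
    with replacement (all encounters of each drawn patient included).
    Replicates on which the statistic is undefined (e.g. single-class
    resamples) are dropped; if more than 20% fail the estimate is flagged.
    Deterministic given the config seed.
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    inst = instances.dropna(subset=["max_score_pre_t0"])
    s = inst["max_score_pre_t0"].to_numpy(dtype=float)
    y = inst["label"].to_numpy(dtype=bool)
    point = float(statistic(s, y))

    patients, inverse = np.unique(inst["patient_id"].to_numpy(), return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    starts = np.searchsorted(sorted_inv, np.arange(len(patients)))
    ends = np.searchsorted(sorted_inv, np.arange(len(patients)), side="right")
    cluster_idx = [order[a:b] for a, b in zip(starts, ends)]

    reps = np.empty(config.n_boot)
    reps.fill(np.nan)
    n_pat = len(patients)
    for b in range(config.n_boot):
        draw = rng.integers(0, n_pat, size=n_pat)
        idx = np.concatenate([cluster_idx[j] for j in draw])
        try:
            reps[b] = statistic(s[idx], y[idx])
        except UndefinedMetricError:
            continue
    ok = reps[~np.isnan(reps)]
    n_failed = config.n_boot - ok.size
    flagged = n_failed > 0.2 * config.n_boot
    if flagged:
        logger.warning("bootstrap: %d/%d replicates undefined", n_failed, config.n_boot)
    alpha = 1 - config.ci_level
    lo, hi = np.quantile(ok, [alpha / 2, 1 - alpha / 2]) if ok.size else (np.nan, np.nan)
    est = MetricEstimate(
        name, point, float(lo), float(hi), config.n_boot, config.seed, n_failed, flagged
    )
    if not (est.ci_low <= est.point <= est.ci_high):
        logger.warning("bootstrap point estimate outside percentile CI for %s", name)
    return est


def weekly_drift(instances: pd.DataFrame) -> pd.DataFrame:
    """AUROC and AUPRC per ISO week of encounter arrival.

    Weeks with a single class are reported with NaN metrics; output sorted
    by week.
    """
    inst = instances.dropna(subset=["max_score_pre_t0"]).copy()
    iso = pd.to_datetime(inst["arrival_time"]).dt.isocalendar()
    inst["week"] = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    rows = []
    for week, g in inst.groupby("week"):
        s = g["max_score_pre_t0"].to_numpy(dtype=float)
        y = g["label"].to_numpy(dtype=bool)
        try:
            a = auroc(s, y)
            p = auprc(s, y)
        except UndefinedMetricError:
            a, p = np.nan, np.nan
        rows.append((week, len(g), int(y.sum()), a, p))
    return (
        pd.DataFrame(rows, columns=["week", "n_encounters", "n_cases", "auroc", "auprc"])
        .sort_values("week")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, MetricEstimate):
        return _jsonable(x.as_dict())
    if isinstance(x, pd.DataFrame):
        return _jsonable(x.to_dict(orient="records"))
    if isinstance(x, pd.Series):
        return _jsonable(x.to_dict())
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, pd.Timestamp):
        return x.isoformat()
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


def assemble_report(
    cohort: dict | None = None,
    per_definition: dict | None = None,
    censoring: dict | None = None,
    drift: pd.DataFrame | None = None,
) -> dict:
    """Assemble the machine-readable evaluation report.

    ``per_definition`` maps definition → blocks such as incidence,
    case-mortality, discrimination estimates, operating points and lead-time
    summaries.  Missing blocks are listed under ``missing_sections`` and the
    report is still emitted.
    """
    report: dict = {"sections_present": [], "missing_sections": []}
    for key, block in (
        ("cohort", cohort),
        ("per_definition", per_definition),
        ("censoring_sensitivity", censoring),
        ("weekly_drift", drift),
    ):
        if block is None or (isinstance(block, pd.DataFrame) and block.empty):
            report["missing_sections"].append(key)
            report[key] = None
        else:
            report["sections_present"].append(key)
            report[key] = _jsonable(block)
    return report


def case_mortality_pct(deaths: int, cases: int) -> float:
    """In-hospital mortality among cases, percent to 1 decimal (half-up)."""
    from .model import percentage

    return percentage(deaths, cases)


def report_to_text(report: dict) -> str:
    """Human-readable rendering of :func:`assemble_report` output."""
    lines = ["sepseval evaluation report", "=" * 28]
    cohort = report.get("cohort")
    if cohort:
        lines.append("Cohort:")
        for k, v in cohort.items():
            lines.append(f"  {k}: {v}")
    per_def = report.get("per_definition")
    if per_def:
        for d, block in per_def.items():
            lines.append(f"Definition {d}:")
            for k, v in block.items():
                lines.append(f"  {k}: {v}")
    if report.get("missing_sections"):
        lines.append(f"Missing sections: {report['missing_sections']}")
    return "\n".join(lines)
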