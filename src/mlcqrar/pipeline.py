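"""End-to-end replication pipeline.

Fits the lipophilicity calibration (log k_m on log K_AM), the ten
four-descriptor QSAR models (five endpoints x two lipophilicity
descriptors), their applicability domains, the univariate
retention-activity suite, the group-wise lipophilicity calibrations and
the property screen — and, when run on the embedded dataset, compares
every replicated statistic side-by-side against the published values.

Published statistics ship as a second embedded fixture with their printed
precision preserved, so replication is machine-checked rather than a
documentation claim.  The default comparison tolerance for each statistic
is the larger of two units in its last printed digit and a small relative
slack that absorbs rounding of the two-decimal chromatographic inputs
(1% for coefficients, 2% for sd, 3% for F/PRESS/MSE, 0.002 absolute for
the R family).  Printed standard errors are displayed for inspection but
not gated (one published value appears to carry a transcription slip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .data import CompoundTable, load_fixture, read_compound_table
from .domain import ADAssessment, assess_domain
from .regression import QSARModel, QSARResults, RegressionSpec
from .screens import ScreenReport, groupwise_linear, qrar_suite, \
    rule_of_five_screen, QRARFit

__all__ = [
    "PipelineConfig",
    "ToleranceSettings",
    "ReplicationReport",
    "run_pipeline",
    "load_reported_stats",
    "DEFAULT_ENDPOINTS",
    "CALIBRATION_KEY",
]

DEFAULT_ENDPOINTS = ("log_Kp", "log_Kwcell", "log_KHSA", "log_BB", "LD50")
CALIBRATION_KEY = "log_km~log_KAM"
_COUNT_DESCRIPTORS = ("HBD", "HBA", "NRB")


@dataclass(frozen=True)
class PrintedValue:
    """A published number kept with its printed precision."""

    text: str

    @property
    def value(self) -> float:
        return float(self.text)

    @property
    def ulp(self) -> float:
        """One unit in the last printed digit."""
        if "." in self.text:
            return 10.0 ** -(len(self.text.split(".")[1]))
        return 1.0


@dataclass(frozen=True)
class ReportedModel:
    """Published statistic block for one model."""

    key: str
    response: str
    predictors: tuple[str, ...]
    coefficients: tuple[PrintedValue, ...]
    standard_errors: tuple[PrintedValue, ...]
    n: int
    R: PrintedValue
    R_adj: PrintedValue
    sd: PrintedValue
    F: PrintedValue
    PRESS: PrintedValue | None
    MSE: PrintedValue | None
    vif_max: PrintedValue | None


def load_reported_stats() -> dict[str, ReportedModel]:
    """Load the embedded published-statistics fixture."""
    text = resources.files("mlcqrar").joinpath(
        "assets/reported_stats.json").read_text()
    raw = json.loads(text)
    out = {}
    for key, d in raw.items():
        opt = {name: (PrintedValue(d[name]) if d[name] is not None else None)
               for name in ("PRESS", "MSE", "vif_max")}
        out[key] = ReportedModel(
            key=key,
            response=d["response"],
            predictors=tuple(d["predictors"]),
            coefficients=tuple(PrintedValue(s) for s in d["coefficients"]),
            standard_errors=tuple(PrintedValue(s)
                                  for s in d["standard_errors"]),
            n=int(d["n"]),
            R=PrintedValue(d["R"]),
            R_adj=PrintedValue(d["R_adj"]),
            sd=PrintedValue(d["sd"]),
            F=PrintedValue(d["F"]),
            **opt,
        )
    return out


@dataclass(frozen=True)
class ToleranceSettings:
    """Per-statistic comparison slack (see module docstring)."""

    ulp_units: float = 2.0
    coef_rel: float = 0.01
    r_abs: float = 0.002
    sd_rel: float = 0.02
    f_rel: float = 0.03
    press_rel: float = 0.03
    mse_rel: float = 0.03

    def __post_init__(self) -> None:
        for name in ("ulp_units", "coef_rel", "r_abs", "sd_rel", "f_rel",
                     "press_rel", "mse_rel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def tolerance(self, kind: str, printed: PrintedValue) -> float:
        rel = {"coef": self.coef_rel, "sd": self.sd_rel, "F": self.f_rel,
               "PRESS": self.press_rel, "MSE": self.mse_rel}.get(kind)
        base = self.ulp_units * printed.ulp
        if kind == "R":
            return max(base, self.r_abs)
        return max(base, rel * abs(printed.value))


@dataclass(frozen=True)
class StatComparison:
    """One published-vs-replicated number."""

    statistic: str
    printed: float
    computed: float
    tolerance: float
    bound: bool = False  # printed value is an upper bound, not a target

    @property
    def ok(self) -> bool:
        if self.bound:
            return self.computed <= self.printed + 1e-9
        return abs(self.computed - self.printed) <= self.tolerance


@dataclass
class ModelReplication:
    """Replicated model, its domain assessment, and the comparison rows."""

    key: str
    results: QSARResults
    assessment: ADAssessment
    comparisons: list[StatComparison] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.comparisons)


@dataclass
class ReplicationReport:
    """Everything the pipeline produced in one run."""

    table: CompoundTable
    calibration: ModelReplication | None
    models: dict[str, ModelReplication]
    qrar: dict[str, list[QRARFit]]
    groupwise: dict[str, dict[str, QSARResults]]
    screen: ScreenReport

    @property
    def all_passed(self) -> bool:
        items = list(self.models.values())
        if self.calibration is not None:
            items.append(self.calibration)
        return all(m.passed for m in items)

    def to_text(self) -> str:
        lines: list[str] = []
        for repl in ([self.calibration] if self.calibration else []) + \
                list(self.models.values()):
            lines.append(f"== {repl.key} ==")
            lines.append(repl.results.summary())
            lines.append(repl.assessment.summary())
            for c in repl.comparisons:
                mark = "ok " if c.ok else "FAIL"
                rel = "<=" if c.bound else "vs"
                lines.append(
                    f"  [{mark}] {c.statistic}: computed {c.computed:.6g} "
                    f"{rel} printed {c.printed:.6g} "
                    f"(tol {c.tolerance:.2g})"
                )
            lines.append("")
        for desc, fits in self.qrar.items():
            lines.append(f"== retention-activity suite ({desc}) ==")
            for f in fits:
                lines.append(f"  {f.endpoint:<10s} {f.form:<9s} "
                             f"R = {f.R:.4f}")
            lines.append("")
        for desc, groups in self.groupwise.items():
            lines.append(f"== group-wise log_P vs {desc} ==")
            for label, res in groups.items():
                lines.append(f"  group {label}: R = {res.R:.4f}  "
                             f"slope = {res.slopes[0]:.3f}")
            lines.append("")
        lines.append("== property screen (passing counts) ==")
        for flag, count in self.screen.summary_counts.items():
            lines.append(f"  {flag:<14s} {int(count)}/{len(self.table)}")
        lines.append("")
        lines.append(f"overall replication: "
                     f"{'PASS' if self.all_passed else 'FAIL'}")
        return "\n".join(lines)

    def to_json(self) -> str:
        def model_block(repl: ModelReplication) -> dict:
            return {
                "model": repl.results.to_dict(),
                "applicability_domain": {
                    "h_star": repl.assessment.h_star,
                    "leverage_outliers": repl.assessment.leverage_outliers,
                    "residual_outliers": repl.assessment.residual_outliers,
                },
                "comparisons": [
                    {"statistic": c.statistic, "printed": c.printed,
                     "computed": c.computed, "tolerance": c.tolerance,
                     "bound": c.bound, "ok": c.ok}
                    for c in repl.comparisons
                ],
                "passed": repl.passed,
            }

        payload = {
            "calibration": (model_block(self.calibration)
                            if self.calibration else None),
            "models": {k: model_block(v) for k, v in self.models.items()},
            "qrar": {
                desc: [{"endpoint": f.endpoint, "form": f.form, "R": f.R}
                       for f in fits]
                for desc, fits in self.qrar.items()
            },
            "groupwise": {
                desc: {label: {"R": res.R,
                               "slope": float(res.slopes[0]),
                               "intercept": res.intercept}
                       for label, res in groups.items()}
                for desc, groups in self.groupwise.items()
            },
            "screen": {
                flag: {"passing": int(count),
                       "failing_ids": self.screen.failing(flag)}
                for flag, count in self.screen.summary_counts.items()
            },
            "all_passed": self.all_passed,
        }
        return json.dumps(payload, indent=2)


@dataclass
class PipelineConfig:
    """What to run and against what tolerances.

    ``source`` is "fixture" for the embedded dataset or a CSV path;
    comparisons against published values are made only for the fixture
    (user data has nothing to compare against).
    """

    source: str = "fixture"
    descriptor: str = "both"  # log_km | log_KAM | both
    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS
    tolerances: ToleranceSettings = field(default_factory=ToleranceSettings)
    compare: bool | None = None  # default: compare iff source == "fixture"

    def __post_init__(self) -> None:
        if self.descriptor not in ("log_km", "log_KAM", "both"):
            raise ValueError("descriptor must be log_km, log_KAM or both")

    @property
    def descriptors(self) -> tuple[str, ...]:
        if self.descriptor == "both":
            return ("log_km", "log_KAM")
        return (self.descriptor,)


def _compare_model(key: str, results: QSARResults,
                   reported: Mapping[str, ReportedModel],
                   tol: ToleranceSettings) -> list[StatComparison]:
    if key not in reported:
        return []
    ref = reported[key]
    rows: list[StatComparison] = []
    names = ("intercept",) + ref.predictors
    for name, printed, computed in zip(names, ref.coefficients,
                                       results.coefficients):
        rows.append(StatComparison(f"coef[{name}]", printed.value,
                                   float(computed),
                                   tol.tolerance("coef", printed)))
    for stat, kind in (("R", "R"), ("R_adj", "R"), ("sd", "sd"),
                       ("F", "F")):
        printed = getattr(ref, stat)
        rows.append(StatComparison(stat, printed.value,
                                   float(getattr(results, stat)),
                                   tol.tolerance(kind, printed)))
    for stat in ("PRESS", "MSE"):
        printed = getattr(ref, stat)
        if printed is not None:
            rows.append(StatComparison(stat, printed.value,
                                       float(getattr(results, stat)),
                                       tol.tolerance(stat, printed)))
    if ref.vif_max is not None:
        rows.append(StatComparison("max VIF", ref.vif_max.value,
                                   float(np.max(results.vif)), 0.0,
                                   bound=True))
    return rows


def run_pipeline(config: PipelineConfig | None = None) -> ReplicationReport:
    """Run the full replication pipeline and return the report."""
    config = config or PipelineConfig()
    if config.source == "fixture":
        table = load_fixture()
    else:
        table = read_compound_table(config.source)
    compare = (config.compare if config.compare is not None
               else config.source == "fixture")
    reported = load_reported_stats() if compare else {}
    ids = table.column("compound_id").astype(int)

    def replicate(key: str, spec: RegressionSpec) -> ModelReplication:
        results = QSARModel(table, spec).fit()
        assessment = assess_domain(results, compound_ids=ids)
        comparisons = _compare_model(key, results, reported,
                                     config.tolerances)
        return ModelReplication(key, results, assessment, comparisons)

    calibration = replicate(CALIBRATION_KEY,
                            RegressionSpec("log_km", ("log_KAM",)))

    models: dict[str, ModelReplication] = {}
    for endpoint in config.endpoints:
        for descriptor in config.descriptors:
            key = f"{endpoint}~{descriptor}"
            spec = RegressionSpec(endpoint,
                                  (descriptor,) + _COUNT_DESCRIPTORS)
            models[key] = replicate(key, spec)

    qrar = {d: qrar_suite(table, d) for d in config.descriptors}
    groupwise = {d: groupwise_linear(table, x=d, y="log_P")
                 for d in config.descriptors}
    screen = rule_of_five_screen(table)

    return ReplicationReport(table=table, calibration=calibration,
                             models=models, qrar=qrar,
                             groupwise=groupwise, screen=screen)
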