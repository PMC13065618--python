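"""End-to-end orchestration: simulate/ingest -> descriptors -> statistics -> LDA.

The default model roster mirrors the comparisons of the study design: six
binary discriminant models, ternary Healthy/T1D/T2D models at 6/5/4/3
variables, the TNF-activated ternary model, and the full six-condition
model.  Each roster entry runs either in ``discover`` mode (fresh stepwise
selection) or ``reproduce`` mode (fixed variable list).

Everything is a pure function of (config, seed): identical configuration
yields byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import BinScheme, CLASSICAL_COLUMNS, FEATURE_COLUMNS, extract_all, \
    feature_dictionary_frame
from .discriminant import CVResult, DiscriminantModel, fit_classifier, loo_cv, \
    pca_varimax, stepwise_select
from .groupstats import anova_tukey, correlations
from .synthetic import CONDITIONS, SimulationConfig, simulate_cohort
from .trackio import CalibrationSpec, parse_tracker_export

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


class PipelineDataError(ValueError):
    pass


def condition_tag(group: str, tnf: bool) -> str:
    return f"{group}+TNF" if tnf else group


#: fixed variable lists of the published binary/ternary models (reproduce mode)
REPRODUCE_VARIABLES: dict[str, list[str]] = {
    "healthy_vs_healthy_tnf": ["prod_v_500_1000_x_1000_1500"],
    "healthy_vs_t1d": ["prod_v_a_med", "prod_a_minf_m5000_x_0_5000", "N_v_500_1000"],
    "healthy_tnf_vs_t1d": ["v_med", "prod_v_500_1000_x_1000_1500"],
    "healthy_vs_t2d": ["R_ratio", "prod_v_0_500_x_1000_1500", "prod_a_m5000_0_x_5000_inf"],
    "healthy_tnf_vs_t2d": ["a_m5000_0", "prod_v_500_1000_x_1000_1500"],
    "t1d_vs_t2d": ["prod_v_0_500_x_500_1000", "R_ratio", "v_ave"],
    "ternary_6var": ["N_v_500_1000", "N_v_1000_1500", "prod_v_0_500_x_500_1000",
                     "R_ratio", "v_ave", "a_minf_m5000"],
    "ternary_5var": ["N_v_500_1000", "N_v_1000_1500", "prod_v_0_500_x_500_1000",
                     "R_ratio", "v_ave"],
    "ternary_4var": ["N_v_500_1000", "N_v_1000_1500", "prod_v_0_500_x_500_1000", "R_ratio"],
    "ternary_3var": ["N_v_500_1000", "N_v_1000_1500", "R_ratio"],
    "ternary_tnf": ["v_500_1000", "v_1500_inf", "N_a_5000_inf"],
    "six_group": ["N_v_500_1000", "R_ratio", "v_ave"],
}


@dataclass(frozen=True)
class ModelSpec:
    """One roster entry: which conditions to compare and how to pick variables."""

    name: str
    conditions: tuple[str, ...]        # condition tags, e.g. ("T1D", "T2D")
    mode: str = "discover"             # "discover" | "reproduce"
    variables: tuple[str, ...] = ()    # fixed list for reproduce mode


def default_roster(mode: str = "discover") -> list[ModelSpec]:
    """The study's comparisons: 6 binary, 4 ternary, TNF ternary, 6-group."""
    all_tags = tuple(condition_tag(g, t) for g, t in CONDITIONS)
    plain = ("Healthy", "T1D", "T2D")
    tnf = ("Healthy+TNF", "T1D+TNF", "T2D+TNF")
    specs = [
        ModelSpec("healthy_vs_healthy_tnf", ("Healthy", "Healthy+TNF")),
        ModelSpec("healthy_vs_t1d", ("Healthy", "T1D")),
        ModelSpec("healthy_tnf_vs_t1d", ("Healthy+TNF", "T1D")),
        ModelSpec("healthy_vs_t2d", ("Healthy", "T2D")),
        ModelSpec("healthy_tnf_vs_t2d", ("Healthy+TNF", "T2D")),
        ModelSpec("t1d_vs_t2d", ("T1D", "T2D")),
        ModelSpec("ternary_6var", plain), ModelSpec("ternary_5var", plain),
        ModelSpec("ternary_4var", plain), ModelSpec("ternary_3var", plain),
        ModelSpec("ternary_tnf", tnf),
        ModelSpec("six_group", all_tags),
    ]
    out = []
    for s in specs:
        if mode == "reproduce":
            out.append(ModelSpec(s.name, s.conditions, "reproduce",
                                 tuple(REPRODUCE_VARIABLES[s.name])))
        else:
            out.append(s)
    return out


@dataclass
class PipelineConfig:
    """Full pipeline configuration; exactly one input mode."""

    input_mode: str = "simulate"               # simulate | tracker-files | cohort-csv
    input_path: str | None = None              # for tracker-files / cohort-csv
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    bins: BinScheme = field(default_factory=BinScheme)
    epsilon_um_s: float = 0.0
    roster: list[ModelSpec] = field(default_factory=default_roster)
    f_in: float = 3.84
    f_out: float = 2.71
    priors: str = "equal"
    seed: int = 0
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "tracker-files", "cohort-csv"):
            raise PipelineConfigError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode != "simulate" and not self.input_path:
            raise PipelineConfigError(f"input mode {self.input_mode!r} needs input_path")
        if not self.roster:
            raise PipelineConfigError("model roster is empty")

    def digest(self) -> str:
        payload = _jsonify(self)
        payload.pop("outdir", None)  # output location is not analytic config
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonify(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


@dataclass
class ModelReport:
    spec: ModelSpec
    model: DiscriminantModel
    original: CVResult
    loo: CVResult
    n_imputed: int
    trace: pd.DataFrame | None = None


@dataclass
class RunReport:
    cohort: pd.DataFrame
    models: dict[str, ModelReport]
    anova: "pd.DataFrame"
    correlations: dict[str, pd.DataFrame]
    pca_summary: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------------------


def load_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Produce the individuals x features table for the configured input mode."""
    if config.input_mode == "simulate":
        return simulate_cohort(config.simulation)
    if config.input_mode == "cohort-csv":
        table = pd.read_csv(config.input_path, na_values=["NA"])
        missing = {"individual_id", "group", "tnf"} - set(table.columns)
        if missing:
            raise PipelineDataError(f"cohort CSV lacks columns: {sorted(missing)}")
        table["tnf"] = table["tnf"].astype(bool)
        return table
    # tracker-files: one export per individual/condition, named
    # <individual>__<group>__<tnf>.tsv (tnf in {0,1})
    rows = []
    files = sorted(Path(config.input_path).glob("*.tsv"))
    if not files:
        raise PipelineDataError(f"no .tsv exports under {config.input_path}")
    for f in files:
        parts = f.stem.split("__")
        if len(parts) != 3:
            raise PipelineDataError(f"{f.name}: expected <id>__<group>__<tnf>.tsv")
        iid, group, tnf_s = parts
        rec = parse_tracker_export(f, config.calibration, individual_id=iid,
                                   group=group, tnf=tnf_s == "1")
        feats = extract_all(rec, bins=config.bins, epsilon_um_s=config.epsilon_um_s,
                            seed=config.seed)
        row = {"individual_id": iid, "group": group, "tnf": tnf_s == "1"}
        row.update(feats.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def prepare_design(table: pd.DataFrame, variables: list[str]) -> tuple[pd.DataFrame, int]:
    """Design matrix with missing feature values imputed as 0 (logged count)."""
    X = table[variables].copy()
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d missing feature value(s) as 0", n_missing)
        X = X.fillna(0.0)
    return X, n_missing


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and return the consolidated report."""
    t0 = time.perf_counter()
    stage = "ingest"
    try:
        cohort = load_cohort(config)
        logger.info("stage %s done in %.2fs (%d rows)", stage,
                    time.perf_counter() - t0, len(cohort))

        cohort = cohort.copy()
        cohort["condition"] = [condition_tag(g, t)
                               for g, t in zip(cohort["group"], cohort["tnf"])]
        feature_cols = [c for c in FEATURE_COLUMNS if c in cohort.columns]
        classical_cols = [c for c in CLASSICAL_COLUMNS if c in cohort.columns]
        meta = {"individual_id", "group", "tnf", "condition"}
        biomarker_cols = [c for c in cohort.columns
                          if c not in meta and c not in feature_cols
                          and c not in classical_cols]

        stage = "groupstats"
        t1 = time.perf_counter()
        stats_res = anova_tukey(cohort, feature_cols + classical_cols,
                                group_col="condition")
        corr: dict[str, pd.DataFrame] = {}
        if biomarker_cols:
            for method in ("pearson", "spearman"):
                c, p = correlations(cohort, biomarker_cols,
                                    feature_cols + classical_cols, method=method)
                corr[f"{method}_r"] = c
                corr[f"{method}_p"] = p
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t1)

        stage = "pca"
        t1 = time.perf_counter()
        Xp, _ = prepare_design(cohort, feature_cols)
        pca = pca_varimax(Xp)
        pca_summary = pd.DataFrame({
            "component": [f"PC{k+1}" for k in range(len(pca.eigenvalues))],
            "eigenvalue": pca.eigenvalues,
            "percent_variance": pca.percent_variance,
            "retained": pca.retained,
        })
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t1)

        stage = "discriminant"
        t1 = time.perf_counter()
        models: dict[str, ModelReport] = {}
        for spec in config.roster:
            sub = cohort[cohort["condition"].isin(spec.conditions)]
            labels = sub["condition"].to_numpy()
            X, n_imp = prepare_design(sub, feature_cols)
            trace = None
            if spec.mode == "reproduce":
                variables = list(spec.variables)
                # a fixed list may be degenerate on a given cohort (a bin
                # never populated); drop constant columns with a warning
                const = [v for v in variables if X[v].nunique() <= 1]
                if const:
                    logger.warning("model %s: dropping constant variable(s) %s",
                                   spec.name, const)
                    variables = [v for v in variables if v not in const]
                if not variables:
                    lams = {v: _safe_lambda(X[[v]], labels) for v in feature_cols}
                    variables = [min(lams, key=lams.get)]
            else:
                variables, trace = stepwise_select(X, labels, f_in=config.f_in,
                                                   f_out=config.f_out)
                if not variables:
                    logger.warning("model %s: stepwise admitted no variable; "
                                   "falling back to best single variable", spec.name)
                    lams = {v: _safe_lambda(X[[v]], labels) for v in feature_cols}
                    variables = [min(lams, key=lams.get)]
            from .discriminant import MulticollinearityError
            while True:
                try:
                    model = fit_classifier(X, labels, variables, priors=config.priors)
                    break
                except MulticollinearityError as err:
                    aliased = [v for v in variables if v in str(err)]
                    if spec.mode != "reproduce" or not aliased:
                        raise
                    logger.warning("model %s: dropping aliased variable(s) %s",
                                   spec.name, aliased)
                    variables = [v for v in variables if v not in aliased]
                    if not variables:
                        raise
            preds = model.classify(X)
            from .discriminant import _confusion
            original = _confusion(labels.astype(str), preds, model.groups)
            loo = loo_cv(X, labels, variables, priors=config.priors)
            models[spec.name] = ModelReport(spec=spec, model=model, original=original,
                                            loo=loo, n_imputed=n_imp, trace=trace)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t1)
    except (PipelineConfigError, PipelineDataError):
        raise
    except Exception as exc:
        raise PipelineDataError(f"stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "n_rows": int(len(cohort)),
        "models": [s.name for s in config.roster],
    }
    return RunReport(cohort=cohort, models=models, anova=stats_res.tidy(),
                     correlations=corr, pca_summary=pca_summary, provenance=provenance)


def _safe_lambda(X, labels) -> float:
    from .discriminant import wilks_lambda
    try:
        return wilks_lambda(X, labels)
    except Exception:
        return 1.0


# ---------------------------------------------------------------------------


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write summary text, per-model CSV/JSON, and tidy stats tables.

    File names are deterministic and contents are a pure function of the
    report, so re-running on the same report reproduces identical bytes.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineDataError(f"output directory not writable: {exc}") from exc

    written: list[Path] = []

    def _w(path: Path, text: str) -> None:
        path.write_text(text, encoding="utf-8")
        written.append(path)

    lines = ["leukoflow pipeline report",
             f"config {report.provenance['config_hash']}  seed {report.provenance['seed']}",
             ""]
    for name, mr in report.models.items():
        lines.append(f"model {name} [{mr.spec.mode}]  conditions: "
                     f"{', '.join(mr.spec.conditions)}")
        lines.append(f"  Wilks lambda = {mr.model.wilks_lambda:.3f}")
        for v in mr.model.selected_variables:
            coefs = ", ".join(f"{c:.3f}" for c in mr.model.standardized_coefficients.loc[v])
            lines.append(f"  {v}: std coef ({coefs}); VIF {mr.model.vif[v]:.2f}")
        orig = "  ".join(f"{g}: {a:.0f}%" for g, a in mr.original.per_class_accuracy.items())
        loo = "  ".join(f"{g}: {a:.0f}%" for g, a in mr.loo.per_class_accuracy.items())
        lines.append(f"  original  {orig}")
        lines.append(f"  LOO       {loo}")
        if mr.n_imputed:
            lines.append(f"  ({mr.n_imputed} missing feature values imputed as 0)")
        lines.append("")
    _w(outdir / "summary.txt", "\n".join(lines) + "\n")

    for name, mr in report.models.items():
        df = mr.model.standardized_coefficients.copy()
        df["VIF"] = mr.model.vif
        df.index.name = "variable"
        _w(outdir / f"model_{name}.csv", df.to_csv(na_rep="NA"))
        payload = {
            "name": name,
            "mode": mr.spec.mode,
            "conditions": list(mr.spec.conditions),
            "variables": mr.model.selected_variables,
            "wilks_lambda": mr.model.wilks_lambda,
            "vif": mr.model.vif.round(6).to_dict(),
            "original_accuracy_pct": mr.original.per_class_accuracy.round(3).to_dict(),
            "loo_accuracy_pct": mr.loo.per_class_accuracy.round(3).to_dict(),
            "loo_confusion": mr.loo.confusion.to_dict(),
        }
        _w(outdir / f"model_{name}.json", json.dumps(payload, indent=2, sort_keys=True))

    _w(outdir / "anova_tukey.csv", report.anova.to_csv(index=False, na_rep="NA"))
    for key, mat in report.correlations.items():
        _w(outdir / f"correlations_{key}.csv", mat.to_csv(na_rep="NA"))
    _w(outdir / "pca_summary.csv", report.pca_summary.to_csv(index=False, na_rep="NA"))
    _w(outdir / "cohort.csv", report.cohort.to_csv(index=False, na_rep="NA"))
    _w(outdir / "feature_dictionary.csv",
       feature_dictionary_frame().to_csv(index=False))
    _w(outdir / "provenance.json",
       json.dumps(report.provenance, indent=2, sort_keys=True))
    return written
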