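"""End-to-end orchestration: simulate → preprocess → features → select →
classify / quantify → report.

Two entry points:

* :func:`run_analysis` — in-memory: returns an :class:`AnalysisResult` with
  the feature matrix, selection, classification and quantification reports.
* :func:`run_pipeline` — disk: runs the same stages but writes every
  artifact (trace CSVs, cycle matrices, feature CSV, selection JSON,
  reports, a Markdown summary and a provenance manifest with the config
  hash) into a run directory.

All randomness derives from the master seed via a seed sequence, so a run
is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import models, preprocess, selection
from .sensor_sim import (
    GasResponseModel,
    SensorTrace,
    Study,
    StudyConfig,
    TemperatureProgram,
    make_study,
)

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_pipeline", "make_fixtures"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run (serializable, hashable)."""

    study: StudyConfig = field(default_factory=StudyConfig)
    preprocess: preprocess.PreprocessParams = field(default_factory=preprocess.PreprocessParams)
    seed: int = 0
    n_selected: int = 8
    sfs_folds: int = 10
    kernel: str = "quadratic"
    clf_folds: int = 10
    conc_clf_folds: int = 10
    plsr_folds: int = 10
    plsr_max_components: int = 10
    test_size: float = 0.2
    carrier_per_trace: int | None = None
    reselect_per_task: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "study" in d:
            s = dict(d["study"])
            if "program" in s:
                p = dict(s["program"])
                p["plateau_temps_c"] = tuple(p.get("plateau_temps_c", ()))
                s["program"] = TemperatureProgram(**p)
            if "model" in s:
                m = dict(s["model"])
                for key in ("temps_c",):
                    if key in m:
                        m[key] = tuple(m[key])
                if "amplitudes_pct" in m:
                    m["amplitudes_pct"] = {g: tuple(a) for g, a in m["amplitudes_pct"].items()}
                s["model"] = GasResponseModel(**m)
            for key in ("gases", "concentrations_ppb"):
                if key in s:
                    s[key] = tuple(s[key])
            d["study"] = StudyConfig(**s)
        if "preprocess" in d:
            d["preprocess"] = preprocess.PreprocessParams(**d["preprocess"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.n_selected < 1:
            raise ConfigError("n_selected must be >= 1")
        if self.kernel not in ("linear", "quadratic"):
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        if not 0 < self.test_size < 1:
            raise ConfigError("test_size must be in (0, 1)")
        # StudyConfig validates itself on construction


def _derived_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class AnalysisResult:
    """Everything a run computes, in memory."""

    config: RunConfig
    study: Study
    catalog: feat.FeatureCatalog
    feature_table: pd.DataFrame           # 299 feature cols + gas, conc_ppb, exposure
    identity_selection: selection.SelectionResult
    identity_report: models.ClassificationReport
    lda_scores: models.LDAScores
    conc_reports: dict[str, models.ClassificationReport]
    conc_selections: dict[str, selection.SelectionResult]
    plsr_reports: dict[str, models.QuantificationReport]
    plsr_selections: dict[str, selection.SelectionResult]

    @property
    def n_observations(self) -> int:
        return len(self.feature_table)


def build_feature_table(config: RunConfig, study: Study) -> tuple[pd.DataFrame, feat.FeatureCatalog]:
    """Standardized observation cycles → labeled feature matrix."""
    program = config.study.program
    catalog = feat.FeatureCatalog.for_program(program)
    frames = []
    for exposure_id, trace in enumerate(study.traces):
        cycles = preprocess.observation_cycles(
            [trace], program, config.preprocess,
            include_carrier=True, carrier_per_trace=config.carrier_per_trace,
        )
        if not cycles:
            continue
        df = feat.extract_features(cycles, catalog)
        df["exposure"] = exposure_id
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table, catalog


def _xy(table: pd.DataFrame, catalog: feat.FeatureCatalog):
    return table[catalog.names].to_numpy(float), table


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run the whole virtual-e-nose analysis in memory."""
    config.validate()
    seeds = _derived_seeds(config.seed, 5)
    study = make_study(replace(config.study, seed=seeds[0]))
    table, catalog = build_feature_table(config, study)
    X, _ = _xy(table, catalog)
    gas_labels = table["gas"].to_numpy()

    t0 = time.perf_counter()
    identity_sel = selection.sfs_select(
        X, gas_labels, k=config.n_selected, task="classification",
        folds=config.sfs_folds, seed=seeds[1], feature_names=catalog.names,
        kernel=config.kernel,
    )
    log.info("gas-identity SFS: %s (%.1fs)", identity_sel.selected_names,
             time.perf_counter() - t0)
    X_sel = X[:, identity_sel.selected]
    identity_report = models.svm_crossval(
        X_sel, gas_labels, kernel=config.kernel, folds=config.clf_folds, seed=seeds[2]
    )
    lda_scores = models.lda_fit_project(X_sel, gas_labels)

    conc_reports, conc_sels, plsr_reports, plsr_sels = {}, {}, {}, {}
    for gas in config.study.gases:
        mask = (table["gas"] == gas).to_numpy()
        Xg, cg = X[mask], table.loc[mask, "conc_ppb"].to_numpy(float)
        if config.reselect_per_task:
            sel_c = selection.sfs_select(
                Xg, np.array([f"{c:g}" for c in cg]), k=config.n_selected,
                task="classification", folds=config.conc_clf_folds, seed=seeds[3],
                feature_names=catalog.names, kernel=config.kernel,
            )
            sel_q = selection.sfs_select(
                Xg, cg, k=config.n_selected, task="regression",
                folds=config.plsr_folds, seed=seeds[3], feature_names=catalog.names,
            )
        else:
            sel_c = sel_q = identity_sel
        conc_sels[gas], plsr_sels[gas] = sel_c, sel_q
        conc_reports[gas] = models.per_gas_concentration_classifier(
            Xg[:, sel_c.selected], cg, kernel=config.kernel,
            folds=config.conc_clf_folds, seed=seeds[4],
        )
        plsr_reports[gas] = models.plsr_quantify(
            Xg[:, sel_q.selected], cg, folds=config.plsr_folds,
            split_seed=seeds[4], test_size=config.test_size,
            max_components=config.plsr_max_components, gas=gas,
        )
    return AnalysisResult(
        config=config, study=study, catalog=catalog, feature_table=table,
        identity_selection=identity_sel, identity_report=identity_report,
        lda_scores=lda_scores, conc_reports=conc_reports, conc_selections=conc_sels,
        plsr_reports=plsr_reports, plsr_selections=plsr_sels,
    )


# ---------------------------------------------------------------- disk stages


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def stage_simulate(config: RunConfig, out: Path) -> Study:
    """Simulate the study and write trace CSVs + the exposure label table."""
    seeds = _derived_seeds(config.seed, 5)
    study = make_study(replace(config.study, seed=seeds[0]))
    tdir = out / "traces"
    tdir.mkdir(parents=True, exist_ok=True)
    for i, trace in enumerate(study.traces):
        trace.to_csv(tdir / f"exposure_{i:03d}.csv")
    study.labels.to_csv(out / "labels.csv", index=False)
    log.info("simulate: %d exposures, %d samples each",
             len(study.traces), len(study.traces[0]))
    return study


def load_study(config: RunConfig, out: Path) -> Study:
    labels = pd.read_csv(out / "labels.csv")
    traces = [
        SensorTrace.from_csv(out / "traces" / f"exposure_{i:03d}.csv")
        for i in range(len(labels))
    ]
    return Study(traces, labels, config.study)


def stage_preprocess(config: RunConfig, out: Path, study: Study | None = None) -> pd.DataFrame:
    """Standardize observation cycles; write the cycle matrix + metadata CSVs."""
    study = study or load_study(config, out)
    program = config.study.program
    all_cycles, meta_rows = [], []
    dropped = 0
    for exposure_id, trace in enumerate(study.traces):
        dropped += len(trace) % program.cycle_length_samples
        cycles = preprocess.observation_cycles(
            [trace], program, config.preprocess,
            include_carrier=True, carrier_per_trace=config.carrier_per_trace,
        )
        for c in cycles:
            all_cycles.append(c)
            meta_rows.append(
                {"exposure": exposure_id, "cycle_idx": c.cycle_index,
                 "gas": c.gas, "conc_ppb": c.conc_ppb, "phase": c.phase}
            )
    if dropped:
        log.warning("preprocess: discarded %d trailing samples in partial cycles", dropped)
    mat, _ = preprocess.cycles_to_frame(all_cycles)
    mat.to_csv(out / "cycles.csv", index=False)
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "cycle_meta.csv", index=False)
    log.info("preprocess: %d observation cycles", len(all_cycles))
    return meta


def stage_features(config: RunConfig, out: Path) -> pd.DataFrame:
    """Feature matrix CSV + catalog JSON from the stored cycle matrix."""
    program = config.study.program
    catalog = feat.FeatureCatalog.for_program(program)
    mat = pd.read_csv(out / "cycles.csv").to_numpy(float)
    meta = pd.read_csv(out / "cycle_meta.csv")
    cycles = [
        preprocess.Cycle(values=row, cycle_index=int(m.cycle_idx), raw_mean=0.0,
                         gas=str(m.gas), conc_ppb=float(m.conc_ppb),
                         phase=str(m.phase), standardized=True)
        for row, m in zip(mat, meta.itertuples())
    ]
    table = feat.extract_features(cycles, catalog)
    table["exposure"] = meta["exposure"].to_numpy()
    table.to_csv(out / "features.csv", index=False)
    _write_json({n: list(w) for n, w in catalog.windows().items()}, out / "catalog.json")
    log.info("features: %d x %d matrix", len(table), catalog.n_features)
    return table


def stage_select(config: RunConfig, out: Path) -> selection.SelectionResult:
    """Gas-identity SFS on the stored feature matrix; writes selection JSON."""
    seeds = _derived_seeds(config.seed, 5)
    table = pd.read_csv(out / "features.csv")
    catalog = feat.FeatureCatalog.for_program(config.study.program)
    X, _ = _xy(table, catalog)
    sel = selection.sfs_select(
        X, table["gas"].to_numpy(), k=config.n_selected, task="classification",
        folds=config.sfs_folds, seed=seeds[1], feature_names=catalog.names,
        kernel=config.kernel,
    )
    _write_json(sel.to_dict(), out / "selection.json")
    return sel


def stage_classify(config: RunConfig, out: Path) -> dict:
    """Gas-identity SVM + LDA scores + per-gas concentration classification."""
    seeds = _derived_seeds(config.seed, 5)
    table = pd.read_csv(out / "features.csv")
    catalog = feat.FeatureCatalog.for_program(config.study.program)
    X, _ = _xy(table, catalog)
    sel = selection.SelectionResult(**_load_selection(out / "selection.json", catalog))
    X_sel = X[:, sel.selected]
    y = table["gas"].to_numpy()

    report = models.svm_crossval(X_sel, y, kernel=config.kernel,
                                 folds=config.clf_folds, seed=seeds[2])
    _write_json(report.to_dict(), out / "classification_gas.json")
    report.counts_frame().to_csv(out / "confusion_gas.csv")
    lda = models.lda_fit_project(X_sel, y)
    lda.scores.to_csv(out / "lda_scores.csv", index_label="obs_id")

    conc_out = {}
    for gas in config.study.gases:
        mask = (table["gas"] == gas).to_numpy()
        Xg, cg = X[mask], table.loc[mask, "conc_ppb"].to_numpy(float)
        if config.reselect_per_task:
            sel_c = selection.sfs_select(
                Xg, np.array([f"{c:g}" for c in cg]), k=config.n_selected,
                task="classification", folds=config.conc_clf_folds, seed=seeds[3],
                feature_names=catalog.names, kernel=config.kernel,
            )
        else:
            sel_c = sel
        rep = models.per_gas_concentration_classifier(
            Xg[:, sel_c.selected], cg, kernel=config.kernel,
            folds=config.conc_clf_folds, seed=seeds[4],
        )
        _write_json(rep.to_dict(), out / f"classification_conc_{gas}.json")
        rep.counts_frame().to_csv(out / f"confusion_conc_{gas}.csv")
        conc_out[gas] = rep
    return {"gas": report, "conc": conc_out, "lda": lda}


def stage_quantify(config: RunConfig, out: Path) -> dict:
    """Per-gas PLSR calibration; writes report JSON + predicted-vs-true CSVs."""
    seeds = _derived_seeds(config.seed, 5)
    table = pd.read_csv(out / "features.csv")
    catalog = feat.FeatureCatalog.for_program(config.study.program)
    X, _ = _xy(table, catalog)
    sel = selection.SelectionResult(**_load_selection(out / "selection.json", catalog))
    reports = {}
    for gas in config.study.gases:
        mask = (table["gas"] == gas).to_numpy()
        Xg, cg = X[mask], table.loc[mask, "conc_ppb"].to_numpy(float)
        if config.reselect_per_task:
            sel_q = selection.sfs_select(
                Xg, cg, k=config.n_selected, task="regression",
                folds=config.plsr_folds, seed=seeds[3], feature_names=catalog.names,
            )
        else:
            sel_q = sel
        rep = models.plsr_quantify(
            Xg[:, sel_q.selected], cg, folds=config.plsr_folds,
            split_seed=seeds[4], test_size=config.test_size,
            max_components=config.plsr_max_components, gas=gas,
        )
        _write_json(rep.to_dict(), out / f"quantification_{gas}.json")
        rep.pairs_frame().to_csv(out / f"predicted_vs_true_{gas}.csv", index=False)
        reports[gas] = rep
    return reports


def _load_selection(path: Path, catalog: feat.FeatureCatalog) -> dict:
    d = json.loads(Path(path).read_text())
    return {
        "selected": d["selected_indices"],
        "scores": d["scores"],
        "criterion": d["criterion"],
        "seed": d["seed"],
        "feature_names": catalog.names,
    }


def _summary_markdown(config: RunConfig, out: Path) -> str:
    lines = [f"# Virtual e-nose run `{config.hash()}` (seed {config.seed})", ""]
    gas_rep = json.loads((out / "classification_gas.json").read_text())
    lines += ["## Gas-identity classification",
              f"- kernel: {gas_rep['kernel']}, folds: {gas_rep['folds']}",
              f"- validation accuracy: {gas_rep['accuracy_pct']:.1f}%",
              "- per-class rates: "
              + ", ".join(f"{k} {v:.1f}%" for k, v in gas_rep["per_class_rate_pct"].items()),
              "", "### Confusion matrix (counts)", "",
              (out / "confusion_gas.csv").read_text(), ""]
    lines += ["## Per-gas concentration classification"]
    for gas in config.study.gases:
        rep = json.loads((out / f"classification_conc_{gas}.json").read_text())
        lines.append(f"- {gas}: accuracy {rep['accuracy_pct']:.1f}% over {len(rep['classes'])} levels")
    lines += ["", "## PLSR quantification"]
    for gas in config.study.gases:
        rep = json.loads((out / f"quantification_{gas}.json").read_text())
        lines.append(
            f"- {gas}: R^2 = {rep['r2']:.3f}, RMSE = {rep['rmse_ppb']:.0f} ppb "
            f"({rep['n_components']} components, {rep['n_train']}/{rep['n_test']} train/test)"
        )
    lines += ["", "LDA scores: `lda_scores.csv`; selected features: `selection.json`.", ""]
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage, writing all artifacts and a provenance manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    timings = {}
    for name, fn in (
        ("simulate", stage_simulate), ("preprocess", stage_preprocess),
        ("features", stage_features), ("select", stage_select),
        ("classify", stage_classify), ("quantify", stage_quantify),
    ):
        t0 = time.perf_counter()
        fn(config, out)
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: %.2fs", name, timings[name])
    (out / "report.md").write_text(_summary_markdown(config, out))
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "timings_s": timings,
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files
        },
    }
    _write_json(manifest, out / "manifest.json")
    return out


def noise_sweep_accuracy(
    noise_sds,
    seeds,
    study: StudyConfig | None = None,
    folds: int = 5,
    kernel: str = "quadratic",
    params: preprocess.PreprocessParams | None = None,
) -> pd.DataFrame:
    """Gas-identity CV accuracy of a small study across simulator noise levels.

    For each (noise sd, seed) a fresh study is simulated, featurized, and
    scored with a stratified CV SVM on the full feature catalog (no
    selection, to keep the sweep cheap).  Returns a tidy frame with columns
    ``noise_sd``, ``seed``, ``accuracy_pct`` — the raw material for checking
    that more measurement noise never helps classification.
    """
    study = study or StudyConfig(
        gases=("CH2O", "CH2O2", "CH3COOH"), concentrations_ppb=(500.0, 2000.0),
        repetitions=1, baseline_cycles=3, exposure_cycles=5, recovery_cycles=0,
    )
    params = params or preprocess.PreprocessParams()
    rows = []
    for sd in noise_sds:
        for seed in seeds:
            cfg = RunConfig(
                study=replace(study, model=replace(study.model, noise_sd=float(sd)),
                              seed=int(seed)),
                preprocess=params, seed=int(seed),
            )
            s = make_study(cfg.study)
            table, catalog = build_feature_table(cfg, s)
            rep = models.svm_crossval(
                table[catalog.names].to_numpy(float), table["gas"].to_numpy(),
                kernel=kernel, folds=folds, seed=int(seed),
            )
            rows.append({"noise_sd": float(sd), "seed": int(seed),
                         "accuracy_pct": rep.accuracy_pct})
    return pd.DataFrame(rows)


def make_fixtures(size: str = "demo", seed: int = 0) -> RunConfig:
    """Canned study configurations.

    ``tiny``: 2 gases × 2 levels, a few cycles each — smoke-test scale.
    ``demo``: the full study shape — 3 VOCs + carrier air, 7 concentration
    levels from 250 to 3000 ppb, ~42 observations per gas and ~168 total.
    """
    if size == "tiny":
        study = StudyConfig(
            gases=("CH2O", "CH2O2"), concentrations_ppb=(500.0, 2000.0),
            repetitions=1, baseline_cycles=3, exposure_cycles=4,
            recovery_cycles=1, seed=seed,
        )
        return RunConfig(
            study=study, seed=seed,
            preprocess=preprocess.PreprocessParams(settle_cycles=1),
            n_selected=3, sfs_folds=3, clf_folds=3, conc_clf_folds=3,
            plsr_folds=3, plsr_max_components=3, test_size=0.34,
        )
    if size == "demo":
        study = StudyConfig(
            gases=("CH2O", "CH2O2", "CH3COOH"),
            concentrations_ppb=(250.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0),
            repetitions=1, baseline_cycles=4, exposure_cycles=8,
            recovery_cycles=3, seed=seed,
        )
        return RunConfig(study=study, seed=seed, conc_clf_folds=6)
    raise ValueError(f"unknown fixture size {size!r}; use 'tiny' or 'demo'")
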