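"""End-to-end orchestration: staged runs, config files, run manifests.

A run lives in one output directory with a fixed layout::

    cohort/        simulated (or ingested) time series, motion, phenotype
    cleaned/       preprocessed time series + per-subject QC JSON
    connectivity/  per-subject correlation matrices (TSV)
    metrics/       per-subject AUC tables, long-format metric TSV
    stats/         demographics, group comparison, hub tables
    classify/      classification reports (JSON + TSV)
    manifest.jsonl one line per completed stage with output hashes

Stages are re-runnable in isolation: each reads only upstream artifacts from
the run directory, and identical seeds reproduce identical files (manifest
hashes match; timestamps differ).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import roi_labels
from .classify import (CVConfig, assemble_features, circular_cv_classify,
                       metrics_from_confusion, nested_cv_classify)
from .cohort import SimulationConfig, read_cohort, simulate_cohort
from .connectome import (SparsitySweep, default_densities,
                         pearson_connectivity, threshold_by_density)
from .metrics import (GLOBAL_METRICS, NODAL_METRICS, MetricTable,
                      compute_metric_table)
from .preprocess import PreprocessConfig, preprocess_subject
from .stats import chi_square_2x2, compare_groups, detect_hubs, two_sample_t

STAGES = ("simulate", "preprocess", "connectome", "metrics", "stats",
          "classify")

COVARIATE_COLS = ("age", "gender", "mean_fd", "verbal_iq", "performance_iq",
                  "full_iq")


@dataclass
class PipelineConfig:
    out_dir: str = "braingraph_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    densities: list = field(default_factory=lambda: default_densities().tolist())
    use_absolute: bool = False
    n_random: int = 100
    cv: CVConfig = field(default_factory=CVConfig)
    classifiers: tuple = ("GB", "RF", "SVM")
    cv_modes: tuple = ("nested", "circular")
    hub_criterion: str = "betweenness"
    global_metrics: tuple = GLOBAL_METRICS
    nodal_metrics: tuple = NODAL_METRICS
    verbose: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file with per-stage blocks; kwargs win over file
        values, file values win over defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for block, target in (("simulation", cfg.simulation),
                              ("preprocess", cfg.preprocess),
                              ("cv", cfg.cv)):
            for k, v in (raw.pop(block, {}) or {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown key {block}.{k}")
                setattr(target, k, v)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k}")
            setattr(cfg, k, v)
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        cfg.simulation.seed = cfg.seed
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"].pop("covariate_params", None)
        return d


def _log(config: PipelineConfig, **fields) -> None:
    if config.verbose:
        print(json.dumps(fields), file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_append(out: Path, stage: str, config: PipelineConfig,
                     outputs: list[Path], t0: float) -> dict:
    entry = {
        "stage": stage,
        "seed": config.seed,
        "duration_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        "config": config.snapshot(),
    }
    with open(out / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")
    return entry


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path} -- run stage '{stage}' first")
    return path


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    config.simulation.seed = config.seed
    simulate_cohort(config.simulation, out_dir=out / "cohort")
    outputs = sorted((out / "cohort").rglob("*.*"))
    _log(config, stage="simulate", n_subjects=2 * config.simulation.n_per_group)
    return _manifest_append(out, "simulate", config, outputs, t0)


def stage_preprocess(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    _require(out / "cohort" / "phenotype.csv", "simulate", "preprocess")
    subjects = read_cohort(out / "cohort")
    cleaned_dir = out / "cleaned"
    qc_dir = out / "qc"
    cleaned_dir.mkdir(parents=True, exist_ok=True)
    qc_dir.mkdir(parents=True, exist_ok=True)
    excluded = []
    outputs = []
    for s in subjects:
        res = preprocess_subject(s.timeseries, s.motion, config.preprocess)
        qc = {"subject_id": s.subject_id, "mean_fd": res["mean_fd"],
              "censored_volumes": res["censored"], "exclude": res["exclude"],
              "stages": res["stages"]}
        qc_path = qc_dir / f"{s.subject_id}.json"
        qc_path.write_text(json.dumps(qc))
        outputs.append(qc_path)
        if res["exclude"]:
            excluded.append((s.subject_id, res["mean_fd"]))
            continue
        df = pd.DataFrame(res["timeseries"],
                          columns=roi_labels(s.timeseries.shape[1]))
        p = cleaned_dir / f"{s.subject_id}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs.append(p)
        _log(config, stage="preprocess", subject=s.subject_id,
             mean_fd=round(res["mean_fd"], 4))
    excl_path = out / "exclusions.tsv"
    pd.DataFrame(excluded, columns=["subject_id", "mean_fd"]).to_csv(
        excl_path, sep="\t", index=False)
    outputs.append(excl_path)
    return _manifest_append(out, "preprocess", config, outputs, t0)


def stage_connectome(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    cleaned = sorted(_require(out / "cleaned", "preprocess",
                              "connectome").glob("*.tsv"))
    conn_dir = out / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for p in cleaned:
        df = pd.read_csv(p, sep="\t")
        R = pearson_connectivity(df.values, list(df.columns))
        rp = conn_dir / p.name
        pd.DataFrame(R.values, columns=R.roi_labels).to_csv(
            rp, sep="\t", index=False, float_format="%.6f")
        outputs.append(rp)
    return _manifest_append(out, "connectome", config, outputs, t0)


def _load_connectivity(out: Path):
    from .connectome import ConnectivityMatrix
    for p in sorted(_require(out / "connectivity", "connectome",
                             "metrics").glob("*.tsv")):
        df = pd.read_csv(p, sep="\t")
        yield p.stem, ConnectivityMatrix(df.values, list(df.columns))


def stage_metrics(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    sweep = SparsitySweep(np.asarray(config.densities, dtype=float))
    met_dir = out / "metrics"
    met_dir.mkdir(parents=True, exist_ok=True)
    auc_g_rows, auc_n = {}, {m: {} for m in config.nodal_metrics}
    outputs = []
    long_path = met_dir / "metrics_long.tsv"
    first = True
    for sid, R in _load_connectivity(out):
        # per-subject substream (stable CRC key) so single subjects are
        # reproducible in isolation
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(STAGES.index("metrics"),
                       zlib.crc32(sid.encode()) % (2 ** 31))))
        nets = [threshold_by_density(R, d, config.use_absolute)
                for d in sweep.densities]
        mt = compute_metric_table(nets, sweep.densities, sid,
                                  n_random=config.n_random, rng=rng,
                                  roi_labels=R.roi_labels,
                                  global_metrics=config.global_metrics,
                                  nodal_metrics=config.nodal_metrics)
        mt.to_long().to_csv(long_path, sep="\t", index=False, mode="w" if first
                            else "a", header=first)
        first = False
        auc_g_rows[sid] = mt.auc_global
        for m in config.nodal_metrics:
            auc_n[m][sid] = mt.auc_nodal.loc[m]
        _log(config, stage="metrics", subject=sid,
             duration=round(time.time() - t0, 1))
    gpath = met_dir / "auc_global.tsv"
    pd.DataFrame(auc_g_rows).T.to_csv(gpath, sep="\t")
    outputs.extend([long_path, gpath])
    for m, rows in auc_n.items():
        p = met_dir / f"auc_nodal_{m}.tsv"
        pd.DataFrame(rows).T.to_csv(p, sep="\t")
        outputs.append(p)
    mpath = met_dir / "settings.json"
    mpath.write_text(json.dumps({
        "densities": list(map(float, sweep.densities)),
        "n_random": config.n_random, "seed": config.seed}))
    outputs.append(mpath)
    return _manifest_append(out, "metrics", config, outputs, t0)


def _phenotype(out: Path) -> pd.DataFrame:
    pheno = pd.read_csv(_require(out / "cohort" / "phenotype.csv",
                                 "simulate", "stats"))
    return pheno.set_index("subject_id")


def stage_stats(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    met_dir = _require(out / "metrics", "metrics", "stats")
    auc_g = pd.read_csv(met_dir / "auc_global.tsv", sep="\t", index_col=0)
    pheno = _phenotype(out).loc[auc_g.index]
    groups = ["ADHD" if d == 1 else "TD" for d in pheno["dx"]]
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    outputs = []

    # demographics: t-tests on continuous covariates, chi-square on gender
    demo_rows = []
    td = pheno[pheno.dx == 0]
    ad = pheno[pheno.dx == 1]
    for covar in ("age", "full_iq", "performance_iq", "verbal_iq", "mean_fd"):
        t, p = two_sample_t(td[covar], ad[covar])
        demo_rows.append({"variable": covar, "statistic": t, "p": p,
                          "TD_mean": td[covar].mean(), "TD_sd": td[covar].std(),
                          "ADHD_mean": ad[covar].mean(),
                          "ADHD_sd": ad[covar].std(), "test": "t"})
    chi2 = chi_square_2x2(int((td.gender == 1).sum()),
                          int((td.gender == 0).sum()),
                          int((ad.gender == 1).sum()),
                          int((ad.gender == 0).sum()))
    demo_rows.append({"variable": "gender", "statistic": chi2, "p": np.nan,
                      "TD_mean": td.gender.mean(), "TD_sd": np.nan,
                      "ADHD_mean": ad.gender.mean(), "ADHD_sd": np.nan,
                      "test": "chi2"})
    dpath = stats_dir / "demographics.tsv"
    pd.DataFrame(demo_rows).to_csv(dpath, sep="\t", index=False)
    outputs.append(dpath)

    cov = pheno[list(COVARIATE_COLS)]
    comparison = compare_groups(auc_g, groups, cov)
    cpath = stats_dir / "group_comparison.tsv"
    comparison.to_csv(cpath, sep="\t", index=False)
    outputs.append(cpath)

    crit = config.hub_criterion
    nodal_path = met_dir / f"auc_nodal_{crit}.tsv"
    if nodal_path.exists():
        nodal = pd.read_csv(nodal_path, sep="\t", index_col=0)
        for gname in ("TD", "ADHD"):
            sel = [s for s, g in zip(auc_g.index, groups) if g == gname]
            report = detect_hubs(nodal.loc[sel].values, gname, crit)
            p = stats_dir / f"hubs_{gname}.tsv"
            report.to_frame().to_csv(p, sep="\t", index=False)
            outputs.append(p)
            _log(config, stage="stats", group=gname,
                 hubs=len(report.hub_indices))
    return _manifest_append(out, "stats", config, outputs, t0)


def stage_classify(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    t0 = time.time()
    met_dir = _require(out / "metrics", "metrics", "classify")
    auc_g = pd.read_csv(met_dir / "auc_global.tsv", sep="\t", index_col=0)
    blocks = [auc_g[[m for m in config.global_metrics]]]
    for m in config.nodal_metrics:
        p = met_dir / f"auc_nodal_{m}.tsv"
        if p.exists():
            nodal = pd.read_csv(p, sep="\t", index_col=0)
            nodal.columns = [f"{m}__{c}" for c in nodal.columns]
            blocks.append(nodal)
    X = pd.concat(blocks, axis=1)
    pheno = _phenotype(out).loc[X.index]
    y = pheno["dx"].values.astype(int)
    from .classify import FeatureMatrix
    fm = FeatureMatrix(X, y, list(X.index))
    config.cv.seed = config.seed
    cls_dir = out / "classify"
    cls_dir.mkdir(parents=True, exist_ok=True)
    results, rows = {}, []
    for model in config.classifiers:
        for mode in config.cv_modes:
            fn = nested_cv_classify if mode == "nested" else circular_cv_classify
            report = fn(fm, config.cv, model)
            results[f"{model}_{mode}"] = {
                "pooled": report.pooled, "metrics": report.metrics,
                "fold_confusions": report.fold_confusions,
                "selected_features": report.selected_features,
                "seed": report.seed,
            }
            rows.append({"classifier": model, "mode": mode, **report.metrics})
            _log(config, stage="classify", model=model, mode=mode,
                 accuracy=report.metrics["accuracy"])
    jpath = cls_dir / "reports.json"
    jpath.write_text(json.dumps(results, default=float, indent=1))
    tpath = cls_dir / "performance.tsv"
    pd.DataFrame(rows).to_csv(tpath, sep="\t", index=False,
                              float_format="%.1f")
    return _manifest_append(out, "classify", config, [jpath, tpath], t0)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connectome": stage_connectome,
    "metrics": stage_metrics,
    "stats": stage_stats,
    "classify": stage_classify,
}


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one named stage; returns its manifest entry."""
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    return _STAGE_FN[name](config)


def run_all(config: PipelineConfig) -> dict:
    """Execute simulate -> preprocess -> connectome -> metrics -> stats ->
    classify and return {stage: manifest entry}."""
    return {name: run_stage(name, config) for name in STAGES}
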