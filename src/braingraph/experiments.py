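"""Scaled-down simulation studies: recovery, calibration, and audits.

These are the package's canonical self-checks, sized to run on a single CPU
in minutes.  Each takes an explicit seed and returns plain dictionaries of
measured quantities; nothing here is fitted to a desired outcome.

Scaling choices (documented in the methods note): the recovery and type-I
experiments use a reduced density grid (10-50% in 10% steps) and the reduced
global metric set {Cp, Lp, global efficiency}, which omits the
null-normalized coefficients so no rewired ensembles are needed per subject;
the small-world study uses 20-network null ensembles per replicate; the
classification audits use a reduced feature set (3 global + 2 nodal metric
blocks, 235 features).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (CVConfig, FeatureMatrix, assemble_features,
                       circular_cv_classify, nested_cv_classify)
from .cohort import SimulationConfig, make_group_graph, simulate_cohort
from .connectome import pearson_connectivity, threshold_by_density
from .metrics import (compute_metric_table, degree_centrality,
                      rewire_degree_preserving, small_world_coefficients)
from .stats import compare_groups, detect_hubs

__all__ = [
    "REDUCED_DENSITIES",
    "REDUCED_GLOBALS",
    "cohort_global_aucs",
    "lp_recovery_experiment",
    "null_fdr_experiment",
    "smallworld_replicates",
    "degree_preservation_check",
    "cohort_feature_matrix",
    "permutation_audit",
    "classification_recovery",
    "hub_analysis",
]

REDUCED_DENSITIES = (0.10, 0.20, 0.30, 0.40, 0.50)
REDUCED_GLOBALS = ("Cp", "Lp", "global_efficiency")
COVARIATE_COLS = ("age", "gender", "mean_fd", "verbal_iq", "performance_iq",
                  "full_iq")


def _covariate_frame(subjects) -> pd.DataFrame:
    return pd.DataFrame([{k: s.covariates[k] for k in COVARIATE_COLS}
                         for s in subjects])


def cohort_global_aucs(config: SimulationConfig,
                       densities=REDUCED_DENSITIES,
                       global_metrics=REDUCED_GLOBALS):
    """Simulate a cohort and compute per-subject global AUC summaries.

    Returns ``(metric_frame, covariates, groups)``.  Preprocessing is skipped:
    the simulator emits stationary, trend-free series, so cleaning would only
    discard degrees of freedom here.
    """
    subjects, _ = simulate_cohort(config)
    rows = []
    for s in subjects:
        R = pearson_connectivity(s.timeseries)
        nets = [threshold_by_density(R, d) for d in densities]
        mt = compute_metric_table(nets, densities, s.subject_id, n_random=0,
                                  global_metrics=global_metrics,
                                  nodal_metrics=())
        rows.append(mt.auc_global)
    return pd.DataFrame(rows), _covariate_frame(subjects), \
        [s.group for s in subjects]


def lp_recovery_experiment(n_replicates: int = 20, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Power of the ANCOVA + FDR pipeline for the injected Lp group gap.

    Each replicate simulates an effect cohort (TD-like rewiring 0.2 vs
    ADHD-like 0.02, 56 + 56 subjects) and asks whether the characteristic
    path length survives FDR at ``alpha`` with the ADHD-like group longer.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    hits = 0
    for s in seeds:
        cfg = SimulationConfig(seed=int(s))
        M, cov, groups = cohort_global_aucs(cfg)
        tab = compare_groups(M, groups, cov, alpha=alpha)
        row = tab[tab.metric == "Lp"].iloc[0]
        hits += bool(row.p_fdr < alpha and row.direction == "ADHD>TD")
    return {"n_replicates": n_replicates, "detections": hits,
            "detection_rate": hits / n_replicates}


def null_fdr_experiment(n_replicates: int = 200, seed: int = 0,
                        alpha: float = 0.05) -> dict:
    """Type-I error of the group pipeline on exchangeable-group cohorts.

    Both groups use the same rewiring probability, so any FDR-significant
    metric is a false discovery; reports the fraction of cohorts with at
    least one.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    false_cohorts = 0
    for s in seeds:
        cfg = SimulationConfig(seed=int(s), ws_rewire_adhd=0.2,
                               ws_rewire_td=0.2)
        M, cov, groups = cohort_global_aucs(cfg)
        tab = compare_groups(M, groups, cov, alpha=alpha)
        false_cohorts += bool(tab.significant.any())
    return {"n_replicates": n_replicates, "false_cohorts": false_cohorts,
            "false_rate": false_cohorts / n_replicates}


def smallworld_replicates(n_replicates: int = 100, n_random: int = 20,
                          seed: int = 0, n_roi: int = 116, k: int = 10,
                          p_rewire: float = 0.1) -> dict:
    """Small-world coefficients of seeded Watts-Strogatz graphs.

    Reports how often gamma > 1, sigma > 1 and lambda falls in [0.9, 1.2]
    across replicates, plus ensemble means.
    """
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    gammas, lams, sigmas = [], [], []
    for child in ss:
        rng = np.random.default_rng(child)
        a = make_group_graph(n_roi, k, p_rewire, rng)
        sw = small_world_coefficients(a, n_random=n_random, rng=rng)
        gammas.append(sw["gamma"])
        lams.append(sw["lambda"])
        sigmas.append(sw["sigma"])
    gammas, lams, sigmas = map(np.asarray, (gammas, lams, sigmas))
    return {
        "n_replicates": n_replicates, "n_random": n_random,
        "frac_gamma_gt_1": float((gammas > 1).mean()),
        "frac_sigma_gt_1": float((sigmas > 1).mean()),
        "frac_lambda_in_band": float(((lams >= 0.9) & (lams <= 1.2)).mean()),
        "mean_gamma": float(gammas.mean()),
        "mean_lambda": float(lams.mean()),
        "mean_sigma": float(sigmas.mean()),
    }


def degree_preservation_check(n_random: int = 100, seed: int = 0) -> dict:
    """Degree sequences of rewired null networks vs their source."""
    rng = np.random.default_rng(seed)
    a = make_group_graph(116, 10, 0.1, rng)
    k0 = degree_centrality(a)
    m = int(a.sum()) // 2
    preserved = 0
    for _ in range(n_random):
        null = rewire_degree_preserving(a, 10 * m, rng)
        preserved += bool((degree_centrality(null) == k0).all())
    return {"n_random": n_random, "preserved": preserved}


def cohort_feature_matrix(config: SimulationConfig,
                          densities=REDUCED_DENSITIES) -> FeatureMatrix:
    """Reduced feature matrix (235 features) for classification studies:
    global {Cp, Lp, Eglob} plus nodal degree and nodal efficiency AUCs."""
    subjects, _ = simulate_cohort(config)
    tables = []
    for s in subjects:
        R = pearson_connectivity(s.timeseries)
        nets = [threshold_by_density(R, d) for d in densities]
        tables.append(compute_metric_table(
            nets, densities, s.subject_id, n_random=0,
            global_metrics=REDUCED_GLOBALS,
            nodal_metrics=("degree", "nodal_efficiency")))
    return assemble_features(tables, [s.group for s in subjects],
                             global_metrics=REDUCED_GLOBALS,
                             nodal_metrics=("degree", "nodal_efficiency"))


def permutation_audit(n_permutations: int = 50, seed: int = 0,
                      model_name: str = "SVM",
                      features: FeatureMatrix | None = None) -> dict:
    """Nested vs circular cross-validation on label-permuted cohorts.

    With permuted labels there is nothing to learn: nested CV should hover
    at chance, while selecting features on all subjects first (circular
    analysis) overfits the permuted labels and inflates accuracy.  Reports
    mean pooled accuracy of both modes over the same permutations.
    """
    if features is None:
        features = cohort_feature_matrix(SimulationConfig(seed=seed))
    rng = np.random.default_rng(seed)
    nested_acc, circular_acc = [], []
    for p in range(n_permutations):
        y_perm = rng.permutation(features.y)
        fm = FeatureMatrix(features.X, y_perm, features.subject_ids)
        cv = CVConfig(seed=p)
        nested_acc.append(
            nested_cv_classify(fm, cv, model_name).metrics["accuracy"])
        circular_acc.append(
            circular_cv_classify(fm, cv, model_name).metrics["accuracy"])
    nested_acc, circular_acc = np.asarray(nested_acc), np.asarray(circular_acc)
    return {
        "n_permutations": n_permutations, "model": model_name,
        "nested_mean_accuracy": float(nested_acc.mean()),
        "circular_mean_accuracy": float(circular_acc.mean()),
        "inflation": float(circular_acc.mean() - nested_acc.mean()),
    }


def classification_recovery(seed: int = 0, model_name: str = "GB",
                            features: FeatureMatrix | None = None,
                            rfe_step: float = 0.5) -> dict:
    """Nested-CV accuracy on an effect cohort with the injected topology gap.

    ``rfe_step`` defaults to 0.5 (halving) for the tree models, whose refits
    dominate the runtime of a fine elimination schedule.
    """
    if features is None:
        features = cohort_feature_matrix(SimulationConfig(seed=seed))
    cv = CVConfig(seed=seed, rfe_step=rfe_step)
    report = nested_cv_classify(features, cv, model_name)
    return {"model": model_name, "accuracy": report.metrics["accuracy"],
            "report": report}


def hub_analysis(seed: int = 0, densities=(0.10, 0.20, 0.30),
                 criterion: str = "betweenness") -> dict:
    """Hub detection per group on an effect cohort.

    Uses group-mean nodal betweenness (AUC over a low-density grid, where
    the injected topology difference is strongest).
    """
    if criterion not in ("betweenness", "degree"):
        raise ValueError("hub criterion must be 'betweenness' or 'degree'")
    subjects, _ = simulate_cohort(SimulationConfig(seed=seed))
    auc_by_group: dict[str, list[np.ndarray]] = {"TD": [], "ADHD": []}
    for s in subjects:
        R = pearson_connectivity(s.timeseries)
        nets = [threshold_by_density(R, d) for d in densities]
        mt = compute_metric_table(nets, densities, s.subject_id, n_random=0,
                                  global_metrics=(),
                                  nodal_metrics=(criterion,))
        auc_by_group[s.group].append(mt.auc_nodal.loc[criterion].values)
    reports = {g: detect_hubs(np.vstack(v), group=g, criterion=criterion)
               for g, v in auc_by_group.items()}
    return {"reports": reports,
            "hub_counts": {g: len(r.hub_indices) for g, r in reports.items()}}
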