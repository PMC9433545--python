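"""Group statistics: demographics, covariate-adjusted comparisons, hubs.

Group effects on graph measures are tested by ANCOVA -- an ordinary
least-squares model ``metric ~ group + age + gender + FD + verbal IQ +
performance IQ + full IQ`` -- with Benjamini-Hochberg FDR control across
metrics.  The reported direction is ADHD minus TD.  Hub nodes are those whose
group-mean centrality exceeds the across-node mean by more than two standard
deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import load_atlas

__all__ = [
    "StatResult",
    "HubReport",
    "two_sample_t",
    "two_sample_t_summary",
    "chi_square_2x2",
    "ancova_group_effect",
    "fdr_bh",
    "compare_groups",
    "detect_hubs",
]

DEFAULT_COVARIATES = ("age", "gender", "mean_fd", "verbal_iq",
                      "performance_iq", "full_iq")


@dataclass
class StatResult:
    metric: str
    statistic: float               # group-effect t (or chi2 for counts)
    p_value: float
    p_fdr: float | None
    group_means: dict              # group -> (mean, sd)
    covariates: tuple = ()
    direction: str = ""            # "ADHD>TD" / "ADHD<TD"

    def summary(self) -> str:
        g = ", ".join(f"{k}: {m:.4g} +/- {s:.4g}"
                      for k, (m, s) in self.group_means.items())
        fdr = f", p_FDR={self.p_fdr:.4g}" if self.p_fdr is not None else ""
        return (f"{self.metric}: t={self.statistic:.3f}, p={self.p_value:.4g}"
                f"{fdr} ({self.direction}; {g})")


def two_sample_t_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> float:
    """Pooled-variance Student t for group2 - group1 from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("zero variance in both groups; t undefined")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    return float((mean2 - mean1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def two_sample_t(x1, x2) -> tuple[float, float]:
    """Pooled t and two-sided p for group2 - group1 on raw vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    t = two_sample_t_summary(x1.mean(), x1.std(ddof=1), x1.size,
                             x2.mean(), x2.std(ddof=1), x2.size)
    from scipy import stats as sps
    p = 2 * sps.t.sf(abs(t), x1.size + x2.size - 2)
    return t, float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]], no continuity
    correction (matches SPSS's default Pearson value)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin; chi-square undefined")
    num = n * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return float(num / den)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ancova_group_effect(values, groups, covariates: pd.DataFrame | None = None,
                        metric: str = "") -> StatResult:
    """Group effect on one metric, adjusted for demographic covariates.

    ``groups`` holds "TD"/"ADHD" (or 0/1) labels; the model is OLS of the
    metric on group plus the covariate columns.  Zero-variance covariates are
    pruned (with a warning), so with no informative covariates the group test
    degrades to a two-sample t-test.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray([1 if str(x) in ("ADHD", "1") else 0 for x in groups])
    if y.size != g.size:
        raise ValueError("values and group labels differ in length")
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    X = pd.DataFrame({"group": g.astype(float)})
    used = []
    if covariates is not None:
        for col in covariates.columns:
            v = np.asarray(covariates[col], dtype=float)
            if np.std(v) == 0:
                warnings.warn(f"covariate {col!r} has zero variance; dropped",
                              RuntimeWarning)
                continue
            X[col] = v
            used.append(col)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues["group"])
    p = float(fit.pvalues["group"])
    means = {
        "TD": (float(y[g == 0].mean()), float(y[g == 0].std(ddof=1))),
        "ADHD": (float(y[g == 1].mean()), float(y[g == 1].std(ddof=1))),
    }
    direction = "ADHD>TD" if fit.params["group"] > 0 else "ADHD<TD"
    return StatResult(metric, t, p, None, means, tuple(used), direction)


def compare_groups(metric_frame: pd.DataFrame, groups,
                   covariates: pd.DataFrame | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """ANCOVA on every metric column with joint FDR correction.

    Returns a table with one row per metric: t, raw p, FDR-adjusted p,
    group means +/- SD and significance at ``alpha``.  Metric columns that
    are constant or contain NaNs are skipped.
    """
    results: list[StatResult] = []
    for col in metric_frame.columns:
        v = np.asarray(metric_frame[col], dtype=float)
        if np.isnan(v).any() or np.std(v) == 0:
            continue
        results.append(ancova_group_effect(v, groups, covariates, metric=col))
    if not results:
        raise ValueError("no testable metric columns")
    adj = fdr_bh([r.p_value for r in results])
    rows = []
    for r, pa in zip(results, adj):
        r.p_fdr = float(pa)
        rows.append({
            "metric": r.metric, "t": r.statistic, "p": r.p_value,
            "p_fdr": r.p_fdr, "direction": r.direction,
            "mean_TD": r.group_means["TD"][0], "sd_TD": r.group_means["TD"][1],
            "mean_ADHD": r.group_means["ADHD"][0],
            "sd_ADHD": r.group_means["ADHD"][1],
            "significant": r.p_fdr < alpha,
        })
    return pd.DataFrame(rows)


@dataclass
class HubReport:
    group: str
    criterion: str                      # "betweenness" or "degree"
    hub_indices: list = field(default_factory=list)   # 0-based node indices
    threshold: float = 0.0
    node_values: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Hub table with ROI number, AAL label and network tag."""
        atlas = load_atlas()
        rows = []
        for i in self.hub_indices:
            rec = atlas.iloc[i] if i < len(atlas) else None
            rows.append({
                "roi_number": i + 1,
                "label": rec["label"] if rec is not None else f"ROI_{i + 1}",
                "network": rec["network"] if rec is not None else "",
                "value": float(self.node_values[i]),
                "group": self.group,
                "criterion": self.criterion,
            })
        return pd.DataFrame(rows,
                            columns=["roi_number", "label", "network",
                                     "value", "group", "criterion"])


def detect_hubs(nodal_values: np.ndarray, group: str = "",
                criterion: str = "betweenness") -> HubReport:
    """Hub nodes of a group: value > across-node mean + 2 SD.

    ``nodal_values`` is subjects x nodes (typically AUC-over-sparsity values
    of betweenness or degree); it is averaged over subjects first, then the
    mean and SD are taken across nodes.
    """
    v = np.atleast_2d(np.asarray(nodal_values, dtype=float))
    node_mean = v.mean(axis=0)
    mu, sd = node_mean.mean(), node_mean.std(ddof=0)
    if sd == 0:
        warnings.warn("across-node SD is zero; no hubs detectable",
                      RuntimeWarning)
        return HubReport(group, criterion, [], float(mu), node_mean)
    thr = mu + 2.0 * sd
    hubs = np.flatnonzero(node_mean > thr).tolist()
    return HubReport(group, criterion, hubs, float(thr), node_mean)
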