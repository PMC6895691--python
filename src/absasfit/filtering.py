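"""Ensemble filter cascade and cluster classification.

The goodness-of-fit cutoff is data-driven: two duplicate experimental
curves of the same sample give two R factors per model, and the cutoff is
the point at which restricting to ever-better fits destroys the agreement
of the two rankings (both Pearson r and Spearman r_s drop below 0.5).
Models are then filtered by R factor, by disulphide C-alpha proximity, and
by the joint X-ray + neutron intersection, and the survivors are classified
into alpha/beta clusters by their inter-region distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .structures import DistanceSummary

# Canonical EnsembleTable column names
TABLE_COLUMNS = ["model_id", "R_xray", "eta_xray", "R_neutron", "eta_neutron",
                 "d1", "d2", "d3", "abs_d23", "ss_dist_1", "ss_dist_2",
                 "cluster"]

D1_THRESHOLD_NM = 7.0       # alpha/beta boundary on the Fab-Fab separation
ASYM_THRESHOLD_NM = 1.5     # beta1/beta2 boundary on abs(d2 - d3)
SS_MAX_NM = 0.75
CORR_THRESHOLD = 0.5


@dataclass
class CutoffResult:
    """Chosen R-factor cutoff (%) plus the full correlation trace."""

    cutoff: float | None
    trace: pd.DataFrame          # columns: cutoff, pearson_r, spearman_r, n

    @property
    def found(self) -> bool:
        return self.cutoff is not None


def determine_cutoff(r_a: np.ndarray, r_b: np.ndarray,
                     threshold: float = CORR_THRESHOLD, min_n: int = 50,
                     n_grid: int = 200, min_retained: int = 5,
                     sustain: int = 3, rule: str = "max") -> CutoffResult:
    """Scan candidate R-factor cutoffs against duplicate-curve R factors.

    Candidates run over ``n_grid`` evenly spaced values between the 1st and
    99th percentile of the pooled R factors, scanned descending.  At each
    candidate c the models with combined R (max, mean or either per-curve,
    per ``rule``) <= c are retained and Pearson/Spearman correlations of
    (r_a, r_b) computed (skipped once fewer than ``min_retained`` models
    remain).  The cutoff is the largest c at which both coefficients fall
    below ``threshold``; if that never happens the result carries a ``None``
    cutoff with the full trace.  ``min_n`` is the minimum population for the
    procedure to be attempted at all.

    With small ensembles the correlation trace is noisy, so a candidate only
    counts as the crossing point when both coefficients stay below the
    threshold for ``sustain`` consecutive candidates.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if len(r_a) != len(r_b):
        raise ValueError("R-factor vectors must describe the same model set")
    if len(r_a) < min_n:
        raise ValueError(f"need at least min_n={min_n} models")
    if rule == "max":
        combined = np.maximum(r_a, r_b)
    elif rule == "mean":
        combined = 0.5 * (r_a + r_b)
    elif rule == "a":
        combined = r_a
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    pooled = np.concatenate([r_a, r_b])
    lo, hi = np.percentile(pooled, [1, 99])
    candidates = np.linspace(lo, hi, n_grid)[::-1]
    rows = []
    for c in candidates:
        keep = combined <= c
        n = int(keep.sum())
        if n < max(min_retained, 3):
            rows.append((c, np.nan, np.nan, n))
            continue
        a, b = r_a[keep], r_b[keep]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            pr = sr = 1.0      # degenerate: identical values, perfectly consistent
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pr = float(pearsonr(a, b)[0])
                sr = float(spearmanr(a, b)[0])
        rows.append((c, pr, sr, n))
    trace = pd.DataFrame(rows, columns=["cutoff", "pearson_r", "spearman_r", "n"])
    below = ((trace["pearson_r"] < threshold)
             & (trace["spearman_r"] < threshold)).to_numpy()
    cutoff = None
    for k in range(len(below)):
        window = below[k:k + sustain]
        if len(window) > 0 and window.all():
            cutoff = float(trace["cutoff"].iloc[k])
            break
    _warn_if_sparse_minimum(combined)
    return CutoffResult(cutoff=cutoff, trace=trace)


def _warn_if_sparse_minimum(combined: np.ndarray) -> None:
    # The procedure assumes the best fits are the most densely sampled; warn
    # when the lower half of the R range holds fewer models than the upper.
    mid = 0.5 * (combined.min() + combined.max())
    if (combined <= mid).sum() < (combined > mid).sum():
        warnings.warn(
            "R factors are not denser near the minimum; the duplicate-curve "
            "cutoff procedure may be unreliable", stacklevel=3)


# ---------------------------------------------------------------------------
# EnsembleTable construction and filters
# ---------------------------------------------------------------------------

def make_table(model_ids: list[str],
               r_factors: dict[str, np.ndarray],
               etas: dict[str, np.ndarray] | None = None,
               distances: list[DistanceSummary] | None = None,
               ss_distances: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble an ensemble table; one row per model.

    ``r_factors`` maps curve labels (e.g. 'xray', 'neutron') to per-model R
    factor vectors; ``ss_distances`` is (n_models, n_pairs).
    """
    df = pd.DataFrame({"model_id": model_ids})
    for label, r in r_factors.items():
        df[f"R_{label}"] = np.asarray(r, dtype=float)
    if etas:
        for label, e in etas.items():
            df[f"eta_{label}"] = np.asarray(e, dtype=float)
    if distances is not None:
        df["d1"] = [d.d1 for d in distances]
        df["d2"] = [d.d2 for d in distances]
        df["d3"] = [d.d3 for d in distances]
        df["abs_d23"] = [d.abs_diff for d in distances]
    if ss_distances is not None:
        ss = np.atleast_2d(np.asarray(ss_distances, dtype=float))
        for k in range(ss.shape[1]):
            df[f"ss_dist_{k + 1}"] = ss[:, k]
    return df


def filter_rfactor(table: pd.DataFrame, label: str,
                   cutoff: float) -> pd.DataFrame:
    """Retain rows with R factor for ``label`` at or below the cutoff."""
    col = f"R_{label}"
    if col not in table.columns:
        raise KeyError(f"no R-factor column for curve label {label!r}")
    out = table[table[col] <= cutoff].copy()
    out.attrs["stages"] = table.attrs.get("stages", []) + \
        [f"R_{label} <= {cutoff:g}%"]
    return out


def filter_disulphide(table: pd.DataFrame,
                      max_distance: float = SS_MAX_NM) -> pd.DataFrame:
    """Retain rows where every constrained cysteine pair is close enough."""
    ss_cols = [c for c in table.columns if c.startswith("ss_dist_")]
    if not ss_cols:
        raise KeyError("table has no disulphide distance columns")
    keep = np.ones(len(table), dtype=bool)
    for c in ss_cols:
        keep &= table[c].to_numpy() <= max_distance
    out = table[keep].copy()
    out.attrs["stages"] = table.attrs.get("stages", []) + \
        [f"disulphide <= {max_distance:g} nm"]
    return out


def joint_filter(table: pd.DataFrame, xray_label: str, xray_cutoff: float,
                 neutron_label: str, neutron_cutoff: float,
                 ss_max: float = SS_MAX_NM) -> pd.DataFrame:
    """Intersection of the X-ray, neutron and disulphide filters.

    The result is identical regardless of application order.
    """
    out = filter_rfactor(table, xray_label, xray_cutoff)
    out = filter_rfactor(out, neutron_label, neutron_cutoff)
    return filter_disulphide(out, ss_max)


# ---------------------------------------------------------------------------
# Cluster classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterLabel:
    cluster: str                 # alpha | beta1 | beta2
    d1_threshold: float
    asym_threshold: float


def classify_clusters(summary: DistanceSummary,
                      d1_threshold: float = D1_THRESHOLD_NM,
                      asym_threshold: float = ASYM_THRESHOLD_NM) -> ClusterLabel:
    """alpha if d1 < threshold; else beta1 (asymmetric) or beta2 (symmetric).

    d1 exactly at the boundary is assigned to beta.
    """
    if summary.d1 < d1_threshold:
        cluster = "alpha"
    elif summary.abs_diff >= asym_threshold:
        cluster = "beta1"
    else:
        cluster = "beta2"
    return ClusterLabel(cluster=cluster, d1_threshold=d1_threshold,
                        asym_threshold=asym_threshold)


def classify_table(table: pd.DataFrame,
                   d1_threshold: float = D1_THRESHOLD_NM,
                   asym_threshold: float = ASYM_THRESHOLD_NM) -> pd.DataFrame:
    """Add a 'cluster' column from the d1 / abs(d2-d3) columns."""
    out = table.copy()
    labels = []
    for d1, abs_d23 in zip(out["d1"], out["abs_d23"]):
        if d1 < d1_threshold:
            labels.append("alpha")
        elif abs_d23 >= asym_threshold:
            labels.append("beta1")
        else:
            labels.append("beta2")
    out["cluster"] = labels
    return out


# ---------------------------------------------------------------------------
# Stage-by-stage reporting
# ---------------------------------------------------------------------------

def filter_report(stages: list[pd.DataFrame],
                  stage_names: list[str] | None = None) -> pd.DataFrame:
    """Per-stage counts and mean +/- SD of the headline observables.

    Mirrors the layout of an ensemble-modelling summary table: one row per
    filter stage with the retained count and statistics of R factors, d1 and
    the larger/smaller Fab-Fc distances over the retained rows.
    """
    if not stages:
        raise ValueError("no stages to report")
    rows = []
    for k, df in enumerate(stages):
        name = (stage_names[k] if stage_names else
                "; ".join(df.attrs.get("stages", [])) or f"stage{k}")
        row: dict[str, float | int | str] = {"stage": name, "n_models": len(df)}
        for col in df.columns:
            if col == "model_id" or df[col].dtype == object:
                continue
            vals = df[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{col}_sd"] = float(np.std(vals, ddof=0)) if len(vals) else np.nan
        if {"d2", "d3"} <= set(df.columns) and len(df):
            mx = np.maximum(df["d2"].to_numpy(), df["d3"].to_numpy())
            mn = np.minimum(df["d2"].to_numpy(), df["d3"].to_numpy())
            row["max_d23_mean"] = float(mx.mean())
            row["max_d23_sd"] = float(mx.std(ddof=0))
            row["min_d23_mean"] = float(mn.mean())
            row["min_d23_sd"] = float(mn.std(ddof=0))
        rows.append(row)
    report = pd.DataFrame(rows)
    counts = report["n_models"].to_numpy()
    if np.any(np.diff(counts) > 0):
        warnings.warn("stage counts increase; stages are not ordered filters",
                      stacklevel=2)
    return report
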