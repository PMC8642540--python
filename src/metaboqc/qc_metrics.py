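"""Dataset-level quality metrics for untargeted LC-MS feature tables.

Five scores, each on a 0-100 scale (100 = highest quality), summarize a
dataset after signal-drift correction (and before the pooled-QC CV feature
filter):

* **Drift Spearman** — ``(1 - p_correlated / p_total) x 100``: the proportion
  of features *not* significantly rank-correlated with the injection order
  (Benjamini-Hochberg at 5% FDR).
* **Drift PCA** — ``(1 - cos^2(alpha)) x 100`` where ``alpha`` is the angle
  between the injection-order direction and its projection onto the hyperplane
  of the first 3 principal-component score vectors.
* **QC spread** — ``(1 - max(d_QC) / max(d_sample)) x 100`` with ``d`` the
  Mahalanobis distance to the centroid in the 3-D PCA score space.
* **QC CV** — percentage of features with a pooled-QC coefficient of variation
  of at most 30%.
* **QC ICC** — 100x the intraclass correlation coefficient ICC(A,1) (two-way
  random effects, absolute agreement, single rater) of the pooled-QC
  intensities in the most populated log2-intensity bin.

A spiked-standard screen (:func:`flag_standard_outliers`) flags samples with a
|z-score| above 3 for any standard compound.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .dataset import MSDataset

#: sample types entering the metric computations (dilution series excluded:
#: their intensities vary by design and would confound drift detection)
DEFAULT_INCLUDE = ("sample", "pool")


# ---------------------------------------------------------------------------
# small numerical building blocks

@lru_cache(maxsize=8)
def _spearman_null(n: int) -> np.ndarray:
    """Exact null distribution of |rho| for untied ranks of length n (n <= 8)."""
    base = np.arange(n, dtype=float)
    base -= base.mean()
    denom = (base ** 2).sum()
    rhos = np.empty(math.factorial(n))
    for k, perm in enumerate(itertools.permutations(range(n))):
        p = base[list(perm)]
        rhos[k] = (base * p).sum() / denom
    return np.abs(rhos)


def spearman_pvalue(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Exact permutation null for n <= 8 without ties; the t-approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho, p_t = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        return np.nan, np.nan
    if n <= 8 and np.unique(x).size == n and np.unique(y).size == n:
        null = _spearman_null(n)
        p = float((null >= abs(rho) - 1e-12).mean())
        return float(rho), p
    return float(rho), float(p_t)


def mahalanobis_distances(points: np.ndarray, center: np.ndarray | None = None,
                          cov: np.ndarray | None = None) -> np.ndarray:
    """Mahalanobis distance of each row of ``points`` to ``center``.

    Defaults: centroid and covariance (ddof=1) of ``points`` themselves.
    Raises on a singular covariance.
    """
    points = np.asarray(points, dtype=float)
    if center is None:
        center = points.mean(axis=0)
    if cov is None:
        cov = np.cov(points, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score covariance; Mahalanobis distances undefined") from exc
    diff = points - center
    z = np.linalg.solve(chol, diff.T)
    return np.sqrt((z ** 2).sum(axis=0))


def icc_a1(mat: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``mat`` is an n x k matrix (n subjects/features, k raters/injections).
    Computed from the two-way ANOVA decomposition::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Raises on missing values or when the denominator vanishes (no variance
    anywhere).
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("ICC needs an n x k matrix with n >= 2 and k >= 2")
    if not np.isfinite(mat).all():
        raise ValueError("ICC requires a complete matrix (no missing values)")
    n, k = mat.shape
    grand = mat.mean()
    row = mat.mean(axis=1)
    col = mat.mean(axis=0)
    ss_r = k * ((row - grand) ** 2).sum()
    ss_c = n * ((col - grand) ** 2).sum()
    ss_t = ((mat - grand) ** 2).sum()
    ss_e = ss_t - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < 1e-300 or (ms_r == 0 and ms_c == 0 and ms_e == 0):
        raise ValueError("ICC undefined: no variance in the matrix")
    return float((ms_r - ms_e) / denom)


def projection_cos2(T: np.ndarray, o: np.ndarray) -> float:
    """cos^2 of the angle between vector ``o`` and the span of the columns of T."""
    o = np.asarray(o, dtype=float)
    o = o - o.mean()
    denom = (o ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate injection-order vector (all equal)")
    beta, *_ = np.linalg.lstsq(T, o, rcond=None)
    proj = T @ beta
    return float((proj ** 2).sum() / denom)


# ---------------------------------------------------------------------------
# shared PCA preparation

def _metric_matrix(dataset: MSDataset, include) -> tuple[np.ndarray, list[str]]:
    """Samples x features matrix for the included sample types, mean-imputed,
    zero-variance features dropped (the imputation is never written back)."""
    ids = dataset.sample_ids_of_type(*include)
    mat = dataset.intensities[ids].to_numpy().T  # samples x features
    keep = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2:
            continue
        m = col[ok].mean()
        col[~ok] = m
        if col.std() > 0:
            keep.append(j)
    return mat[:, keep], ids


def _pca_scores(mat: np.ndarray, n_components: int, scale: bool) -> np.ndarray:
    X = mat - mat.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    if k < 1:
        raise ValueError("not enough samples/features for PCA")
    return PCA(n_components=k, svd_solver="full").fit_transform(X)


# ---------------------------------------------------------------------------
# the five metrics

def drift_spearman(dataset: MSDataset, fdr: float = 0.05,
                   include=DEFAULT_INCLUDE) -> tuple[float, dict]:
    """Proportion of features not significantly correlated with injection order.

    Per feature, a Spearman rank-correlation test of intensity against
    injection order over the included (non-blank, non-dilution) injections;
    Benjamini-Hochberg correction at ``fdr``.  Features with fewer than 4
    observed values are excluded from the total.
    """
    ids = dataset.sample_ids_of_type(*include)
    if len(ids) < 4:
        raise ValueError("drift_spearman needs >= 4 included injections")
    orders = dataset.injection_orders(ids)
    mat = dataset.intensities[ids].to_numpy()
    pvals, tested = [], []
    for i in range(mat.shape[0]):
        y = mat[i]
        ok = np.isfinite(y)
        if ok.sum() < 4:
            continue
        _, p = spearman_pvalue(orders[ok], y[ok])
        if np.isfinite(p):
            pvals.append(p)
            tested.append(dataset.feature_ids[i])
    if not pvals:
        raise ValueError("no testable features (p_total == 0)")
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    p_total = len(pvals)
    p_corr = int(reject.sum())
    score = (1.0 - p_corr / p_total) * 100.0
    return score, {"p_correlated": p_corr, "p_total": p_total, "fdr": fdr,
                   "correlated_ids": [t for t, r in zip(tested, reject) if r]}


def drift_pca(dataset: MSDataset, n_components: int = 3, scale: bool = True,
              include=DEFAULT_INCLUDE) -> tuple[float, dict]:
    """Proportion of injection-order variance unexplained by the first 3 PCs.

    ``(1 - cos^2 alpha) x 100`` with ``alpha`` the angle between the centered
    injection-order vector and its projection on the span of the first
    ``n_components`` PCA score vectors (features centered and unit-variance
    scaled, missing values mean-imputed for the PCA only).
    """
    mat, ids = _metric_matrix(dataset, include)
    if mat.shape[0] < n_components + 2:
        raise ValueError(f"drift_pca needs >= {n_components + 2} included injections")
    o = dataset.injection_orders(ids)
    if np.unique(o).size < 2:
        raise ValueError("degenerate injection-order vector (all equal)")
    T = _pca_scores(mat, n_components, scale)
    cos2 = projection_cos2(T, o)
    score = (1.0 - cos2) * 100.0
    return score, {"cos2_alpha": cos2, "n_components": T.shape[1], "n_samples": len(ids)}


def qc_spread(dataset: MSDataset, n_components: int = 3,
              scale: bool = True) -> tuple[float, dict]:
    """Spread of the pooled QCs relative to the biological samples in PCA space.

    ``(1 - max(d_QC) / max(d_sample)) x 100`` (clamped below at 0), with
    Mahalanobis distances of the 3-D PCA scores to the common centroid, under
    the covariance of all included samples' scores.
    """
    pools = dataset.sample_ids_of_type("pool")
    bios = dataset.sample_ids_of_type("sample")
    if len(pools) < 2 or len(bios) < 2:
        raise ValueError("qc_spread needs >= 2 'pool' and >= 2 'sample' injections")
    mat, ids = _metric_matrix(dataset, ("pool", "sample"))
    T = _pca_scores(mat, n_components, scale)
    d = mahalanobis_distances(T)
    is_pool = np.array([i in set(pools) for i in ids])
    max_d_qc = float(d[is_pool].max())
    max_d_sample = float(d[~is_pool].max())
    if max_d_sample == 0:
        raise ValueError("degenerate PCA scores: farthest biological sample at distance 0")
    score = max(0.0, (1.0 - max_d_qc / max_d_sample) * 100.0)
    return score, {"max_d_qc": max_d_qc, "max_d_sample": max_d_sample,
                   "n_components": T.shape[1]}


def qc_cv(dataset: MSDataset, cv_threshold: float = 0.30) -> tuple[float, dict]:
    """Percentage of features with pooled-QC CV at or below the threshold.

    Only features with at least 3 observed pool values count toward the total.
    Also returns the cumulative %-features-below-CV curve.
    """
    pools = dataset.sample_ids_of_type("pool")
    if len(pools) < 3:
        raise ValueError("qc_cv needs >= 3 'pool' injections")
    mat = dataset.intensities[pools].to_numpy()
    cvs = []
    for i in range(mat.shape[0]):
        v = mat[i][np.isfinite(mat[i])]
        if v.size >= 3 and v.mean() != 0:
            cvs.append(v.std(ddof=1) / v.mean())
    if not cvs:
        raise ValueError("no features with >= 3 observed pool values")
    cvs = np.sort(np.asarray(cvs))
    p_total = cvs.size
    p_le = int((cvs <= cv_threshold).sum())
    curve = pd.DataFrame({"cv": cvs, "cum_pct_features": 100.0 * np.arange(1, p_total + 1) / p_total})
    return 100.0 * p_le / p_total, {"p_cv_le_030": p_le, "p_total": p_total,
                                    "cv_threshold": cv_threshold, "curve": curve}


def qc_icc(dataset: MSDataset, n_bins: int = 10) -> tuple[float, dict]:
    """ICC(A,1) of the pooled-QC intensities at the most probable abundance.

    Features with complete pool values are binned into ``n_bins`` equal-width
    bins of log2 median pool intensity; the metric is 100x the ICC of the most
    populated (modal) bin's features x pool-injections matrix, clamped to
    [0, 100].  The per-bin ICC curve is returned for the abundance profile.
    """
    pools = dataset.sample_ids_of_type("pool")
    if len(pools) < 3:
        raise ValueError("qc_icc needs >= 3 'pool' injections")
    mat = dataset.intensities[pools].to_numpy()
    complete = np.isfinite(mat).all(axis=1) & (np.nan_to_num(mat, nan=1.0) > 0).all(axis=1)
    if complete.sum() < n_bins:
        raise ValueError(f"qc_icc needs >= n_bins={n_bins} features with complete positive "
                         "pool values")
    sub = mat[complete]
    med = np.log2(np.median(sub, axis=1))
    lo, hi = med.min(), med.max()
    if hi == lo:
        bins = np.zeros(sub.shape[0], dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(med, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    modal = int(counts.argmax())
    if counts[modal] < 3:
        raise ValueError("modal intensity bin has fewer than 3 features")
    icc_by_bin = {}
    for b in range(n_bins):
        if counts[b] >= 3:
            try:
                icc_by_bin[b] = icc_a1(sub[bins == b])
            except ValueError:
                icc_by_bin[b] = np.nan
    icc_modal = icc_by_bin[modal]
    score = float(np.clip(icc_modal * 100.0, 0.0, 100.0))
    return score, {"icc_by_bin": icc_by_bin, "modal_bin": modal,
                   "bin_counts": counts.tolist(), "icc_modal": icc_modal,
                   "n_bins": n_bins}


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class QualityReport:
    """The five quality scores plus their intermediate quantities."""

    drift_spearman: float
    drift_pca: float
    qc_spread: float
    qc_cv: float
    qc_icc: float
    detail: dict = field(default_factory=dict)

    @property
    def scores(self) -> dict:
        return {"drift_spearman": self.drift_spearman, "drift_pca": self.drift_pca,
                "qc_spread": self.qc_spread, "qc_cv": self.qc_cv, "qc_icc": self.qc_icc}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"metric": list(self.scores), "score": list(self.scores.values())})

    def to_json(self) -> str:
        detail = {}
        for k, v in self.detail.items():
            detail[k] = {kk: vv for kk, vv in v.items() if not isinstance(vv, pd.DataFrame)}
        return json.dumps({"scores": self.scores, "detail": detail}, default=_jsonable, indent=2)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return str(v)


def quality_report(dataset: MSDataset, fdr: float = 0.05, n_components: int = 3,
                   cv_threshold: float = 0.30, n_bins: int = 10, scale: bool = True,
                   include=DEFAULT_INCLUDE) -> QualityReport:
    """Assemble all five quality metrics of a drift-corrected dataset.

    Expects the dataset in the paper-trail state "post-processed through
    signal-drift correction but before the pooled-QC CV feature filter"; on
    the raw (pre-log2) intensity scale for the CV- and ICC-based metrics.
    """
    if not dataset.sample_ids_of_type("pool"):
        raise ValueError("quality_report requires samples of sample_type 'pool'")
    if not dataset.sample_ids_of_type("sample"):
        raise ValueError("quality_report requires samples of sample_type 'sample'")
    ds_score, ds_detail = drift_spearman(dataset, fdr=fdr, include=include)
    dp_score, dp_detail = drift_pca(dataset, n_components=n_components, scale=scale,
                                    include=include)
    sp_score, sp_detail = qc_spread(dataset, n_components=n_components, scale=scale)
    cv_score, cv_detail = qc_cv(dataset, cv_threshold=cv_threshold)
    icc_score, icc_detail = qc_icc(dataset, n_bins=n_bins)
    return QualityReport(ds_score, dp_score, sp_score, cv_score, icc_score,
                         detail={"drift_spearman": ds_detail, "drift_pca": dp_detail,
                                 "qc_spread": sp_detail, "qc_cv": cv_detail,
                                 "qc_icc": icc_detail})


def plot_radar(report: QualityReport, path=None, label: str = "dataset"):
    """Radar plot of the five scores (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    names = list(report.scores)
    vals = list(report.scores.values())
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False).tolist()
    vals_c = vals + vals[:1]
    angles_c = angles + angles[:1]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles_c, vals_c, "o-", label=label)
    ax.fill(angles_c, vals_c, alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(names)
    ax.set_ylim(0, 100)
    ax.legend(loc="lower right")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# spiked-standard screening

@dataclass
class StandardPanel:
    """Identifiers of spiked internal/external standard features."""

    standard_ids: list

    def __post_init__(self):
        self.standard_ids = list(self.standard_ids)


def flag_standard_outliers(dataset: MSDataset, panel: StandardPanel | list,
                           z_threshold: float = 3.0, sample_types=("sample",)):
    """Flag (sample, standard) pairs with |z-score| above the threshold.

    Per standard feature, z-scores of its intensities across the selected
    samples; returns the flagged pairs and a per-standard CV summary.
    """
    ids = panel.standard_ids if isinstance(panel, StandardPanel) else list(panel)
    missing = [i for i in ids if i not in set(dataset.feature_ids)]
    if missing:
        raise ValueError(f"standards absent from the dataset: {missing}")
    sample_ids = dataset.sample_ids_of_type(*sample_types)
    flagged = []
    summary = []
    for sid in ids:
        row = dataset.intensities.loc[sid, sample_ids].to_numpy(dtype=float)
        ok = np.isfinite(row)
        if ok.sum() < 3:
            raise ValueError(f"standard '{sid}' has fewer than 3 observed values")
        m, s = row[ok].mean(), row[ok].std(ddof=1)
        cv = s / m if m != 0 else np.nan
        summary.append({"standard": sid, "n": int(ok.sum()), "mean": m, "sd": s, "cv": cv})
        if s == 0:
            continue
        z = (row - m) / s
        for j, samp in enumerate(sample_ids):
            if np.isfinite(z[j]) and abs(z[j]) > z_threshold:
                flagged.append({"sample": samp, "standard": sid, "z": float(z[j])})
    summary_df = pd.DataFrame(summary)
    summary_df.attrs["mean_cv"] = float(np.nanmean(summary_df["cv"])) if len(summary_df) else np.nan
    return flagged, summary_df
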