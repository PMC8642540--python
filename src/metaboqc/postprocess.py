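"""Statistical post-processing of untargeted LC-MS feature tables.

The chain applies, in fixed order:

1. **blank filter** — discard features whose mean intensity in the biological
   samples is less than 3x the mean in the solvent blanks;
2. **dilution filter** — discard features whose Pearson correlation between
   intensity and the inverse pooled-QC dilution factor is below 0.7;
3. **signal-drift correction** — per-feature loess of intensity against
   injection order on a reference sample set (pooled QCs or biological
   samples), multiplicative correction renormalized to the reference median;
4. **CV filter** — discard features whose pooled-QC coefficient of variation
   exceeds 30% or the biological-sample CV;
5. **redundancy filter** — collapse groups of features that are correlated
   (r > 0.9), co-eluting (|delta RT| < 6 s) and separated by a known
   isotope/adduct/fragment m/z offset (0.005 Da tolerance), keeping one
   representative per group;
6. **log2 transform** (final step; zeros become missing).

All filters operate on raw-scale intensities and keep full bookkeeping of the
discarded features in :class:`FilterReport` objects, so the feature-count
cascade of a run can be reconstructed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MSDataset
from .mzref import MzDiffTable
from .smooth import loess

PIPELINE_STEPS = ("blank", "dilution", "drift", "cv", "redundancy", "log2")


@dataclass
class FilterReport:
    """Bookkeeping of one post-processing step."""

    step: str
    n_features_in: int
    n_features_out: int
    discarded: dict = field(default_factory=dict)  # feature id -> reason
    params: dict = field(default_factory=dict)
    skipped: bool = False
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_features_out != self.n_features_in - len(self.discarded):
            raise ValueError("inconsistent report: n_out != n_in - |discarded|")

    def to_dict(self) -> dict:
        return {"step": self.step, "n_features_in": self.n_features_in,
                "n_features_out": self.n_features_out, "skipped": self.skipped,
                "params": self.params, "n_discarded": len(self.discarded),
                "discarded": self.discarded, "notes": self.notes}


def _skip_report(step, dataset, reason, **params) -> FilterReport:
    warnings.warn(f"{step} filter skipped: {reason}")
    return FilterReport(step=step, n_features_in=dataset.n_features,
                        n_features_out=dataset.n_features, params=params,
                        skipped=True, notes=[reason])


def _nanmean_or_zero(a: np.ndarray) -> np.ndarray:
    """Row means ignoring NaN; all-missing rows give 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(a, axis=1)
    return np.nan_to_num(m, nan=0.0)


def blank_filter(dataset: MSDataset, ratio_threshold: float = 3.0):
    """Discard features dominated by the solvent-blank background.

    A feature is kept iff its mean over biological samples is at least
    ``ratio_threshold`` times its mean over blanks (equality passes; only
    strictly *less than* is discarded).  Missing values are ignored in the
    means; an all-missing blank mean counts as 0.
    """
    if dataset.log_transformed:
        raise ValueError("blank filter requires raw-scale intensities")
    blanks = dataset.sample_ids_of_type("blank")
    bios = dataset.sample_ids_of_type("sample")
    if not blanks or not bios:
        return dataset.copy(), _skip_report("blank", dataset,
                                            "requires at least one blank and one biological sample",
                                            ratio_threshold=ratio_threshold)
    bio_mean = _nanmean_or_zero(dataset.intensities[bios].to_numpy())
    blank_mean = _nanmean_or_zero(dataset.intensities[blanks].to_numpy())
    discarded = {}
    keep = []
    for i, f in enumerate(dataset.features):
        if bio_mean[i] < ratio_threshold * blank_mean[i]:
            f.flags.add("blank_fail")
            discarded[f.id] = (f"mean(bio)={bio_mean[i]:.6g} < "
                               f"{ratio_threshold:g} x mean(blank)={blank_mean[i]:.6g}")
        else:
            keep.append(f.id)
    out = dataset.subset_features(keep)
    return out, FilterReport("blank", dataset.n_features, out.n_features, discarded,
                             {"ratio_threshold": ratio_threshold})


def dilution_filter(dataset: MSDataset, r_threshold: float = 0.7):
    """Discard features not tracking the pooled-QC dilution series.

    Keeps a feature iff the Pearson correlation between its intensity and
    1/dilution_factor over the ``pool_dilution`` injections is at least
    ``r_threshold``.  A zero-variance intensity vector has undefined
    correlation and is discarded (a feature blind to the dilution series is
    not quantitative).  Skipped (with a warning) when fewer than 3 dilution
    points with distinct factors exist.
    """
    if dataset.log_transformed:
        raise ValueError("dilution filter requires raw-scale intensities")
    dil = dataset.samples_of_type("pool_dilution")
    dil = [s for s in dil if s.dilution_factor is not None]
    factors = [s.dilution_factor for s in dil]
    if len(dil) < 3 or len(set(factors)) < 3:
        return dataset.copy(), _skip_report(
            "dilution", dataset,
            "requires >= 3 pool_dilution samples with distinct dilution factors",
            r_threshold=r_threshold)
    ids = [s.id for s in dil]
    inv = 1.0 / np.asarray(factors, dtype=float)
    mat = dataset.intensities[ids].to_numpy()
    discarded, keep = {}, []
    for i, f in enumerate(dataset.features):
        y = mat[i]
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.unique(inv[ok]).size < 3:
            f.flags.add("dilution_fail")
            discarded[f.id] = "fewer than 3 observed dilution points"
            continue
        yv, xv = y[ok], inv[ok]
        if np.std(yv) == 0:
            f.flags.add("dilution_fail")
            discarded[f.id] = "zero-variance intensity over the dilution series"
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        if not np.isfinite(r) or r < r_threshold:
            f.flags.add("dilution_fail")
            discarded[f.id] = f"r={r:.4f} < {r_threshold:g}"
        else:
            keep.append(f.id)
    out = dataset.subset_features(keep)
    return out, FilterReport("dilution", dataset.n_features, out.n_features, discarded,
                             {"r_threshold": r_threshold})


def drift_correct(dataset: MSDataset, reference: str = "pool", span: float = 1.0,
                  degree: int = 2, min_reference: int = 5):
    """Correct per-feature signal drift along the injection order by loess.

    For each feature a loess curve of intensity against injection order is
    fitted on the reference injections (``reference='pool'`` for pooled QCs or
    ``'sample'`` for biological samples); every intensity is then multiplied by
    ``median(reference) / fitted(order)``.  Outside the reference injection
    range the fit is extrapolated as the nearest fitted value; the fitted curve
    is floored at ``1e-6 x median(reference)`` before division.  Corrected
    features are flagged ``drift_corrected``; features with fewer than
    ``min_reference`` observed reference values are left uncorrected (noted in
    the report).
    """
    if reference not in ("pool", "sample"):
        raise ValueError("reference must be 'pool' or 'sample'")
    if not (0 < span <= 1):
        raise ValueError(f"loess span must be in (0, 1], got {span}")
    ref_samples = dataset.samples_of_type(reference)
    out = dataset.copy()
    report = FilterReport("drift", dataset.n_features, dataset.n_features,
                          params={"reference": reference, "span": span, "degree": degree,
                                  "min_reference": min_reference})
    if len(ref_samples) < min_reference:
        report.skipped = True
        report.notes.append(f"fewer than {min_reference} '{reference}' injections; no correction")
        warnings.warn(report.notes[-1])
        return out, report

    ref_ids = [s.id for s in ref_samples]
    ref_orders = dataset.injection_orders(ref_ids)
    all_orders = dataset.injection_orders()

    ref_mat = out.intensities[ref_ids].to_numpy()
    sample_pos = {sid: k for k, sid in enumerate(dataset.sample_ids)}
    ref_cols = [sample_pos[r] for r in ref_ids]
    uncorrected = []
    for i, f in enumerate(out.features):
        y = ref_mat[i]
        ok = np.isfinite(y)
        if ok.sum() < min_reference:
            uncorrected.append(f.id)
            continue
        m_ref = float(np.median(y[ok]))
        # nearest-fitted-value extrapolation outside this feature's reference range
        eval_orders = np.clip(all_orders, ref_orders[ok].min(), ref_orders[ok].max())
        fitted = loess(ref_orders[ok], y[ok], eval_orders, span=span, degree=degree)
        fitted = np.maximum(fitted, 1e-6 * abs(m_ref) if m_ref != 0 else 1e-6)
        ratio = out.intensities.iloc[i, :].to_numpy() / fitted
        # renormalize so the reference-sample median is preserved exactly
        ref_ratio = np.array([ratio[ref_cols[j]] for j in np.where(ok)[0]])
        scale = m_ref / np.median(ref_ratio)
        out.intensities.iloc[i, :] = ratio * scale
        f.flags.add("drift_corrected")
    if uncorrected:
        report.notes.append(f"uncorrected (fewer than {min_reference} reference values): "
                            f"{uncorrected}")
    return out, report


def _cv(mat: np.ndarray, min_obs: int = 2) -> np.ndarray:
    """Row-wise coefficient of variation sd/mean over observed values."""
    out = np.full(mat.shape[0], np.nan)
    for i in range(mat.shape[0]):
        v = mat[i][np.isfinite(mat[i])]
        if v.size >= min_obs and v.mean() != 0:
            out[i] = v.std(ddof=1) / v.mean()
    return out


def cv_filter(dataset: MSDataset, cv_threshold: float = 0.30):
    """Discard features unreliable in the pooled QCs.

    A feature is discarded iff its pooled-QC CV exceeds ``cv_threshold`` or
    exceeds its biological-sample CV (both computed as sd/mean on the raw
    scale over observed values), or fewer than 3 pool values are observed.
    The computed CVs are stored on the feature records.
    """
    if dataset.log_transformed:
        raise ValueError("CV filter requires raw-scale intensities")
    pools = dataset.sample_ids_of_type("pool")
    if len(pools) < 3:
        return dataset.copy(), _skip_report("cv", dataset, "requires >= 3 pool samples",
                                            cv_threshold=cv_threshold)
    bios = dataset.sample_ids_of_type("sample")
    pool_mat = dataset.intensities[pools].to_numpy()
    bio_mat = dataset.intensities[bios].to_numpy() if bios else np.empty((dataset.n_features, 0))
    n_pool_obs = np.isfinite(pool_mat).sum(axis=1)
    cv_pool = _cv(pool_mat)
    cv_bio = _cv(bio_mat)
    discarded, keep = {}, []
    for i, f in enumerate(dataset.features):
        f.qc_cv = None if np.isnan(cv_pool[i]) else float(cv_pool[i])
        f.sample_cv = None if np.isnan(cv_bio[i]) else float(cv_bio[i])
        if n_pool_obs[i] < 3:
            f.flags.add("cv_fail")
            discarded[f.id] = "fewer than 3 observed pool values"
        elif np.isnan(cv_pool[i]):
            f.flags.add("cv_fail")
            discarded[f.id] = "pool CV undefined (zero mean)"
        elif cv_pool[i] > cv_threshold:
            f.flags.add("cv_fail")
            discarded[f.id] = f"CV_pool={cv_pool[i]:.4f} > {cv_threshold:g}"
        elif not np.isnan(cv_bio[i]) and cv_pool[i] > cv_bio[i]:
            f.flags.add("cv_fail")
            discarded[f.id] = f"CV_pool={cv_pool[i]:.4f} > CV_bio={cv_bio[i]:.4f}"
        else:
            keep.append(f.id)
    out = dataset.subset_features(keep)
    # carry the CVs over to the surviving records
    by_id = {f.id: f for f in dataset.features}
    for f in out.features:
        f.qc_cv, f.sample_cv = by_id[f.id].qc_cv, by_id[f.id].sample_cv
    return out, FilterReport("cv", dataset.n_features, out.n_features, discarded,
                             {"cv_threshold": cv_threshold})


def redundancy_filter(dataset: MSDataset, mzdiff: MzDiffTable | None = None,
                      r_min: float = 0.9, rt_tol_s: float = 6.0):
    """Collapse isotope/adduct/fragment feature groups to one representative.

    Two features are linked iff all three criteria hold: Pearson correlation of
    their biological-sample profiles above ``r_min``, retention-time difference
    below ``rt_tol_s`` seconds, and m/z difference matching a reference-list
    entry within the table's tolerance.  Connected components of the resulting
    graph form redundancy groups; the member with the highest median biological
    intensity (ties broken toward the lowest m/z) is kept, the rest are flagged
    ``redundant`` and removed.
    """
    if mzdiff is None:
        mzdiff = MzDiffTable()
    for f in dataset.features:
        if np.isnan(f.mz) or np.isnan(f.rt):
            raise ValueError(f"feature '{f.id}' lacks mz or rt, required for redundancy filtering")
    bios = dataset.sample_ids_of_type("sample")
    if len(bios) < 3:
        return dataset.copy(), _skip_report("redundancy", dataset,
                                            "requires >= 3 biological samples",
                                            r_min=r_min, rt_tol_s=rt_tol_s)
    n = dataset.n_features
    mat = dataset.intensities[bios].to_numpy()
    mz = np.array([f.mz for f in dataset.features])
    rt = np.array([f.rt for f in dataset.features])

    # candidate pairs by RT proximity first (cheap), then mz table, then correlation
    adj = [[] for _ in range(n)]
    order = np.argsort(rt, kind="stable")
    for a_pos in range(n):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, n):
            j = order[b_pos]
            if rt[j] - rt[i] >= rt_tol_s:
                break
            if not mzdiff.matches(mz[i], mz[j]):
                continue
            xi, xj = mat[i], mat[j]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            r = np.corrcoef(xi[ok], xj[ok])[0, 1]
            if r > r_min:
                adj[i].append(j)
                adj[j].append(i)

    # connected components
    comp = np.full(n, -1)
    n_comp = 0
    for i in range(n):
        if comp[i] >= 0 or not adj[i]:
            continue
        stack = [i]
        comp[i] = n_comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(mat, axis=1)
    med = np.nan_to_num(med, nan=-np.inf)

    discarded, keep = {}, []
    for c in range(n_comp):
        members = np.where(comp == c)[0]
        best = min(members, key=lambda k: (-med[k], mz[k]))
        label = f"R{c + 1:03d}"
        for k in members:
            dataset.features[k].redundancy_group = label
            if k != best:
                dataset.features[k].flags.add("redundant")
                discarded[dataset.features[k].id] = (
                    f"group {label}: redundant with '{dataset.features[best].id}'")
    keep = [f.id for f in dataset.features if f.id not in discarded]
    out = dataset.subset_features(keep)
    return out, FilterReport("redundancy", n, out.n_features, discarded,
                             {"r_min": r_min, "rt_tol_s": rt_tol_s,
                              "mz_tolerance": mzdiff.tolerance,
                              "n_groups": n_comp})


def log2_transform(dataset: MSDataset) -> MSDataset:
    """log2-transform all intensities (final step; zeros become missing)."""
    if dataset.log_transformed:
        raise ValueError("dataset is already log2 transformed")
    vals = dataset.intensities.to_numpy()
    if np.nan_to_num(vals, nan=0.0).min() < 0:
        raise ValueError("negative intensities cannot be log2 transformed")
    out = dataset.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logged = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    out.intensities = pd.DataFrame(logged, index=dataset.intensities.index,
                                   columns=dataset.intensities.columns)
    out.log_transformed = True
    return out


@dataclass
class PipelineParams:
    """Parameters of :func:`run_pipeline`; every step can be switched off."""

    steps: tuple = PIPELINE_STEPS
    blank_ratio: float = 3.0
    dilution_r: float = 0.7
    drift_reference: str = "pool"
    loess_span: float = 1.0
    loess_degree: int = 2
    cv_threshold: float = 0.30
    redundancy_r_min: float = 0.9
    rt_tol_s: float = 6.0
    mzdiff: MzDiffTable | None = None

    def __post_init__(self):
        unknown = [s for s in self.steps if s not in PIPELINE_STEPS]
        if unknown:
            raise ValueError(f"unknown pipeline steps: {unknown}")
        canonical = tuple(s for s in PIPELINE_STEPS if s in self.steps)
        if tuple(self.steps) != canonical:
            raise ValueError(f"pipeline step order is fixed to {PIPELINE_STEPS}; "
                             f"got {tuple(self.steps)}")


def run_pipeline(dataset: MSDataset, params: PipelineParams | None = None):
    """Run the full post-processing chain in the fixed order.

    ``blank -> dilution -> drift -> cv -> redundancy -> log2``; steps absent
    from ``params.steps`` are skipped.  Returns the processed dataset and the
    list of per-step :class:`FilterReport` (the feature-count cascade).
    """
    if params is None:
        params = PipelineParams()
    ds = dataset
    reports: list[FilterReport] = []
    if "blank" in params.steps:
        ds, rep = blank_filter(ds, params.blank_ratio)
        reports.append(rep)
    if "dilution" in params.steps:
        ds, rep = dilution_filter(ds, params.dilution_r)
        reports.append(rep)
    if "drift" in params.steps:
        ds, rep = drift_correct(ds, params.drift_reference, params.loess_span,
                                params.loess_degree)
        reports.append(rep)
    if "cv" in params.steps:
        ds, rep = cv_filter(ds, params.cv_threshold)
        reports.append(rep)
    if "redundancy" in params.steps:
        ds, rep = redundancy_filter(ds, params.mzdiff, params.redundancy_r_min,
                                    params.rt_tol_s)
        reports.append(rep)
    if "log2" in params.steps:
        ds = log2_transform(ds)
        reports.append(FilterReport("log2", ds.n_features, ds.n_features))
    if ds is dataset:
        ds = dataset.copy()
    return ds, reports


def cascade_table(reports: list[FilterReport]) -> pd.DataFrame:
    """Feature-count cascade across the executed steps, as a DataFrame."""
    return pd.DataFrame([{
        "step": r.step, "n_in": r.n_features_in, "n_out": r.n_features_out,
        "n_discarded": len(r.discarded), "skipped": r.skipped,
    } for r in reports])
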