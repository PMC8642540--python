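"""Reference-range (rr95) validation of preclinical phenotyping variables.

For each quantitative variable a reference range covering 95% of the values of
a large historical-control cohort is computed per sex.  If the values are
compatible with a normal distribution — directly or after an inverse, log or
square-root transformation, judged by the Shapiro-Wilk test — the range is the
parametric ``mean +- 2 sd`` on the transformed scale, back-transformed;
otherwise the 2.5th and 97.5th empirical percentiles are used.  A new (project)
control cohort is screened by discarding every variable whose per-sex project
mean falls strictly outside the historical range; a PCA overlay provides the
matching multivariate check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA

from .dataset import PreclinicalTable

TRANSFORMS = ("identity", "log", "sqrt", "inverse")

#: recommended minimal cohort size for stable reference limits (CLSI EP28)
RECOMMENDED_MIN_N = 120


def _apply(transform: str, v: np.ndarray) -> np.ndarray:
    if transform == "identity":
        return v
    if transform == "log":
        return np.log(v)
    if transform == "sqrt":
        return np.sqrt(v)
    if transform == "inverse":
        return 1.0 / v
    raise ValueError(f"unknown transform '{transform}'")


def _admissible(transform: str, v: np.ndarray) -> bool:
    if transform == "identity":
        return True
    if transform == "log":
        return bool((v > 0).all())
    if transform == "sqrt":
        return bool((v >= 0).all())
    if transform == "inverse":
        return bool((v != 0).all())
    return False


def select_transform(values, alpha: float = 0.05) -> tuple[str, float]:
    """Choose the normalizing transformation by the Shapiro-Wilk test.

    Tries ``identity``, ``log``, ``sqrt``, ``inverse`` in that order, skipping
    transforms undefined for the data; returns the first one whose transformed
    values have Shapiro-Wilk p >= ``alpha``, together with that p-value.
    Returns ``("none", nan)`` when no transform normalizes the data (the
    percentile bounds are then used).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("select_transform needs >= 3 finite values")
    for t in TRANSFORMS:
        if not _admissible(t, v):
            continue
        tv = _apply(t, v)
        if np.std(tv) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(tv).pvalue)
        if p >= alpha:
            return t, p
    return "none", float("nan")


@dataclass
class ReferenceRange:
    """A per-variable (and per-sex) rr95 reference range on the original scale."""

    variable: str
    sex: str
    transform: str        # identity / log / sqrt / inverse / none
    method: str           # parametric (mean +- 2 sd) or percentile (2.5/97.5)
    lower: float
    upper: float
    n: int
    shapiro_p: float
    small_n_warning: bool

    def contains(self, x: float) -> bool:
        """True unless ``x`` is strictly outside the range (bounds included)."""
        return self.lower <= x <= self.upper


def rr95(values, sex: str = "NA", transform: str | None = None,
         variable: str = "", alpha: float = 0.05,
         min_n: int = RECOMMENDED_MIN_N) -> ReferenceRange:
    """Compute the rr95 reference range of one variable.

    If ``transform`` is None it is selected with :func:`select_transform`.
    For a normalizing transform the bounds are ``mean +- 2 sd`` on the
    transformed scale mapped back to the original scale (bounds swapped for
    the order-reversing inverse transform); for ``"none"`` they are the 2.5th
    and 97.5th percentiles (linear interpolation).  ``small_n_warning`` is set
    when fewer than ``min_n`` animals contribute.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("rr95 needs >= 3 values")
    if np.std(v) == 0:
        raise ValueError("rr95 undefined for zero-variance values")
    if transform is None:
        transform, shapiro_p = select_transform(v, alpha=alpha)
    else:
        if transform != "none" and not _admissible(transform, v):
            raise ValueError(f"transform '{transform}' not defined for these values")
        if transform == "none":
            shapiro_p = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapiro_p = float(stats.shapiro(_apply(transform, v)).pvalue)

    if transform != "none":
        tv = _apply(transform, v)
        m, s = tv.mean(), tv.std(ddof=1)
        lo_t, hi_t = m - 2 * s, m + 2 * s
        if transform == "identity":
            lower, upper = lo_t, hi_t
        elif transform == "log":
            lower, upper = np.exp(lo_t), np.exp(hi_t)
        elif transform == "sqrt":
            lower, upper = max(lo_t, 0.0) ** 2, hi_t ** 2
        else:  # inverse reverses order
            if lo_t <= 0 < hi_t:
                raise ValueError("inverse-transformed range crosses zero; "
                                 "original-scale bounds unbounded")
            lower, upper = 1.0 / hi_t, 1.0 / lo_t
            if lower > upper:
                lower, upper = upper, lower
        method = "parametric"
    else:
        lower, upper = np.percentile(v, [2.5, 97.5])  # type-7 linear interpolation
        method = "percentile"
    return ReferenceRange(variable=variable, sex=sex, transform=transform, method=method,
                          lower=float(lower), upper=float(upper), n=int(v.size),
                          shapiro_p=shapiro_p, small_n_warning=v.size < min_n)


def compute_reference_ranges(table: PreclinicalTable, per_sex: bool = True,
                             alpha: float = 0.05,
                             min_n: int = RECOMMENDED_MIN_N) -> list[ReferenceRange]:
    """rr95 ranges for every variable of a cohort (per sex by default)."""
    groups = [("M",), ("F",)] if per_sex else [("M", "F")]
    out = []
    for var in table.variables:
        for g in groups:
            mask = table.sex.isin(g)
            vals = table.values.loc[mask, var].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size < 3:
                continue
            hint = table.transform_hint.get(var)
            out.append(rr95(vals, sex="/".join(g), transform=hint, variable=var,
                            alpha=alpha, min_n=min_n))
    return out


def ranges_frame(ranges: list[ReferenceRange]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "sex": r.sex, "transform": r.transform,
        "method": r.method, "lower": r.lower, "upper": r.upper, "n": r.n,
        "shapiro_p": r.shapiro_p, "small_n_warning": r.small_n_warning,
    } for r in ranges])


class ControlCheck(NamedTuple):
    """Outcome of screening a project cohort against historical ranges."""

    details: pd.DataFrame   # one row per variable x sex with bounds and project mean
    discarded: list         # variables whose project mean is outside for some sex


def flag_project_controls(historical: PreclinicalTable, project: PreclinicalTable,
                          per_sex: bool = True, alpha: float = 0.05,
                          min_n: int = RECOMMENDED_MIN_N) -> ControlCheck:
    """Screen a project control cohort against historical rr95 ranges.

    A variable is discarded iff the project-control mean (per sex, original
    scale) falls *strictly outside* the historical rr95 of males or females;
    a mean exactly on a bound is kept.
    """
    missing = [v for v in historical.variables if v not in project.variables]
    missing += [v for v in project.variables if v not in historical.variables]
    if missing:
        raise ValueError(f"variables absent from one of the tables: {sorted(set(missing))}")
    groups = [("M",), ("F",)] if per_sex else [("M", "F")]
    rows, discarded = [], []
    for var in historical.variables:
        outside_any = False
        for g in groups:
            hvals = historical.values.loc[historical.sex.isin(g), var].dropna().to_numpy()
            pvals = project.values.loc[project.sex.isin(g), var].dropna().to_numpy()
            if hvals.size < 3 or pvals.size == 0:
                continue
            rr = rr95(hvals, sex="/".join(g), variable=var, alpha=alpha, min_n=min_n)
            pmean = float(pvals.mean())
            outside = not rr.contains(pmean)
            outside_any |= outside
            rows.append({"variable": var, "sex": rr.sex, "transform": rr.transform,
                         "method": rr.method, "lower": rr.lower, "upper": rr.upper,
                         "n_historical": rr.n, "project_mean": pmean,
                         "n_project": int(pvals.size), "outside": outside,
                         "small_n_warning": rr.small_n_warning})
        if outside_any:
            discarded.append(var)
    return ControlCheck(details=pd.DataFrame(rows), discarded=discarded)


class PcaOverlay(NamedTuple):
    historical_scores: np.ndarray
    project_scores: np.ndarray
    inside: np.ndarray        # per project animal: within the 2-D convex hull?
    explained_variance_ratio: np.ndarray


def control_pca_overlay(historical: PreclinicalTable, project: PreclinicalTable,
                        n_components: int = 2) -> PcaOverlay:
    """Project the project cohort into the historical cohort's PCA space.

    The PCA is fitted on the historical animals (variables centered and scaled
    to unit variance; missing values imputed by the historical mean); project
    animals are projected into the same space.  Each project animal is tested
    for membership in the 2-D convex hull of the historical scores.
    """
    shared = [v for v in historical.variables if v in set(project.variables)]
    if not shared:
        raise ValueError("no shared variables between historical and project tables")
    if historical.n_animals < 3:
        raise ValueError("need >= 3 historical animals")
    H = historical.values[shared].to_numpy(dtype=float)
    P = project.values[shared].to_numpy(dtype=float)
    mean = np.nanmean(H, axis=0)
    H = np.where(np.isfinite(H), H, mean)
    P = np.where(np.isfinite(P), P, mean)
    sd = H.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Hs, Ps = (H - mean) / sd, (P - mean) / sd
    k = min(n_components, Hs.shape[0] - 1, Hs.shape[1])
    pca = PCA(n_components=k, svd_solver="full").fit(Hs)
    hsc = pca.transform(Hs)
    psc = pca.transform(Ps)
    try:
        tri = Delaunay(hsc[:, :2])
        inside = tri.find_simplex(psc[:, :2]) >= 0
    except QhullError:
        inside = np.zeros(len(psc), dtype=bool)
    return PcaOverlay(hsc, psc, inside, pca.explained_variance_ratio_)
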