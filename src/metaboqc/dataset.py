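"""Core in-memory containers for LC-MS feature tables and phenotyping tables.

The central object is :class:`MSDataset`, holding a features x samples
intensity matrix together with per-sample and per-feature metadata, mirroring
the three-table ("triplet") exchange convention of processed metabolomics
datasets (dataMatrix / sampleMetadata / variableMetadata).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("blank", "pool", "pool_dilution", "sample")
GENOTYPES = ("LAT", "MX2", "WT", "NA")
SEXES = ("M", "F", "NA")

#: filter labels a feature may carry
FEATURE_FLAGS = ("blank_fail", "dilution_fail", "cv_fail", "redundant", "drift_corrected")


def _records_close(a, b, rtol: float) -> bool:
    """Dataclass records equal field by field, floats within rtol (NaN == NaN)."""
    if type(a) is not type(b):
        return False
    for name in a.__dataclass_fields__:
        va, vb = getattr(a, name), getattr(b, name)
        if isinstance(va, float) and isinstance(vb, float):
            if np.isnan(va) and np.isnan(vb):
                continue
            if not np.isclose(va, vb, rtol=rtol, equal_nan=True):
                return False
        elif va != vb:
            return False
    return True


@dataclass
class SampleRecord:
    """Metadata of one injection in the analytical sequence.

    Parameters
    ----------
    id : unique sample identifier (dataMatrix column name).
    sample_type : one of ``blank``, ``pool``, ``pool_dilution``, ``sample``.
    injection_order : chronological rank of the injection (unique, positive).
    dilution_factor : dilution of a pooled-QC aliquot (``pool_dilution`` only;
        1 means undiluted).
    genotype, sex, batch : study covariates; ``"NA"`` when not applicable.
    """

    id: str
    sample_type: str = "sample"
    injection_order: int = 0
    dilution_factor: float | None = None
    genotype: str = "NA"
    sex: str = "NA"
    batch: str = ""

    def copy(self) -> "SampleRecord":
        return _copy.copy(self)


@dataclass
class FeatureRecord:
    """Metadata of one (m/z, retention-time) feature.

    ``flags`` accumulates filter labels (see :data:`FEATURE_FLAGS`);
    ``redundancy_group`` holds at most one group membership label.
    """

    id: str
    mz: float = float("nan")
    rt: float = float("nan")
    annotation: str | None = None
    flags: set = field(default_factory=set)
    qc_cv: float | None = None
    sample_cv: float | None = None
    redundancy_group: str | None = None

    def copy(self) -> "FeatureRecord":
        new = _copy.copy(self)
        new.flags = set(self.flags)
        return new


class MSDataset:
    """A feature-intensity matrix with aligned sample and feature metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Features x samples, float, ``NaN`` for missing. Index must equal the
        feature ids (same order); columns must equal the sample ids.
    samples : list of SampleRecord
    features : list of FeatureRecord
    log_transformed : bool
        True once intensities are on the log2 scale; raw intensities must be
        non-negative.
    """

    def __init__(self, intensities: pd.DataFrame, samples: list[SampleRecord],
                 features: list[FeatureRecord], log_transformed: bool = False):
        sample_ids = [s.id for s in samples]
        feature_ids = [f.id for f in features]
        if list(intensities.columns) != sample_ids:
            raise ValueError("intensity columns do not match sample ids (same order required)")
        if list(intensities.index) != feature_ids:
            raise ValueError("intensity rows do not match feature ids (same order required)")
        self.intensities = intensities.astype(float)
        self.samples = samples
        self.features = features
        self.log_transformed = bool(log_transformed)

    # -- identifiers ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MSDataset({self.n_features} features x {self.n_samples} samples, "
                f"log_transformed={self.log_transformed})")

    # -- selection helpers --------------------------------------------
    def samples_of_type(self, *types: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.sample_type in types]

    def sample_ids_of_type(self, *types: str) -> list[str]:
        return [s.id for s in self.samples if s.sample_type in types]

    def values_of_type(self, *types: str) -> pd.DataFrame:
        """Intensity sub-matrix restricted to samples of the given types."""
        return self.intensities[self.sample_ids_of_type(*types)]

    def injection_orders(self, ids: list[str] | None = None) -> np.ndarray:
        by_id = {s.id: s.injection_order for s in self.samples}
        if ids is None:
            ids = self.sample_ids
        return np.array([by_id[i] for i in ids], dtype=float)

    def feature(self, fid: str) -> FeatureRecord:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def subset_features(self, keep_ids) -> "MSDataset":
        """New dataset restricted to ``keep_ids`` (original order preserved)."""
        keep = set(keep_ids)
        feats = [f for f in self.features if f.id in keep]
        ids = [f.id for f in feats]
        return MSDataset(self.intensities.loc[ids].copy(), [s.copy() for s in self.samples],
                         feats, self.log_transformed)

    def copy(self) -> "MSDataset":
        return MSDataset(self.intensities.copy(), [s.copy() for s in self.samples],
                         [f.copy() for f in self.features], self.log_transformed)

    # -- comparison ----------------------------------------------------
    def equals(self, other: "MSDataset", rtol: float = 1e-9) -> bool:
        """Field-by-field equality, intensities compared within ``rtol``."""
        if self.sample_ids != other.sample_ids or self.feature_ids != other.feature_ids:
            return False
        if self.log_transformed != other.log_transformed:
            return False
        a, b = self.intensities.to_numpy(), other.intensities.to_numpy()
        same_nan = np.isnan(a) == np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, equal_nan=True)
        if not (same_nan.all() and close.all()):
            return False
        if any(not _records_close(a_, b_, rtol) for a_, b_ in zip(self.samples, other.samples)):
            return False
        return all(_records_close(a_, b_, rtol) for a_, b_ in zip(self.features, other.features))


class PreclinicalTable:
    """Animals x quantitative-variables table with sex and cohort labels.

    Parameters
    ----------
    values : pandas.DataFrame, animals x variables (``NaN`` allowed).
    sex : pandas.Series aligned with ``values.index``; entries in {"M", "F"}.
    cohort : pandas.Series aligned with ``values.index`` (e.g. ``historical``
        vs ``project``).
    transform_hint : optional mapping variable -> transformation name.
    """

    def __init__(self, values: pd.DataFrame, sex: pd.Series, cohort: pd.Series,
                 transform_hint: dict | None = None):
        if not values.index.equals(sex.index) or not values.index.equals(cohort.index):
            raise ValueError("sex and cohort must be indexed by the animal ids of `values`")
        bad = set(sex.unique()) - {"M", "F"}
        if bad:
            raise ValueError(f"sex labels must be 'M' or 'F'; found {sorted(bad)}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable identifiers: {dup}")
        self.values = values.astype(float)
        self.sex = sex
        self.cohort = cohort
        self.transform_hint = dict(transform_hint or {})

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_animals(self) -> int:
        return len(self.values)

    def subset_cohort(self, label: str) -> "PreclinicalTable":
        mask = self.cohort == label
        return PreclinicalTable(self.values.loc[mask].copy(), self.sex.loc[mask].copy(),
                                self.cohort.loc[mask].copy(), self.transform_hint)

    def split_cohorts(self, historical: str = "historical", project: str = "project"):
        return self.subset_cohort(historical), self.subset_cohort(project)
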