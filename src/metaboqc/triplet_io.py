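"""Reading, validation and writing of the three-table feature-dataset format.

Processed untargeted-metabolomics datasets are conventionally exchanged as a
"triplet" of tab-separated files: ``dataMatrix.tsv`` (features x samples
intensities), ``sampleMetadata.tsv`` and ``variableMetadata.tsv``, with the
first column of each file holding the identifiers.  Metadata column names
differ between deposits, so :func:`read_triplet` takes a ``column_map``
translating dialect-specific names onto :class:`~metaboqc.dataset.SampleRecord`
fields.

Missing intensities are written as ``NA`` and read from ``NA`` or the empty
string.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .dataset import (GENOTYPES, SAMPLE_TYPES, SEXES, FeatureRecord, MSDataset,
                      PreclinicalTable, SampleRecord)

#: default mapping SampleRecord field -> sampleMetadata column name
DEFAULT_COLUMN_MAP = {
    "sample_type": "sampleType",
    "injection_order": "injectionOrder",
    "dilution_factor": "dilution",
    "genotype": "genotype",
    "sex": "sex",
    "batch": "batch",
}

#: accepted spellings of sample types in deposited metadata
SAMPLE_TYPE_ALIASES = {
    "blank": "blank",
    "pool": "pool",
    "qc": "pool",
    "pool_dilution": "pool_dilution",
    "pooldilution": "pool_dilution",
    "dilution": "pool_dilution",
    "sample": "sample",
}

_NA_TOKENS = ("NA", "")


class TripletFormatError(ValueError):
    """Malformed or inconsistent triplet files."""


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False, na_values=list(_NA_TOKENS))
    df.index = df.index.astype(str)
    return df


def _check_ids(kind: str, ids) -> None:
    ids = list(ids)
    if any(i == "" or i is None for i in ids):
        raise TripletFormatError(f"empty {kind} identifier found")
    seen, dup = set(), []
    for i in ids:
        if i in seen:
            dup.append(i)
        seen.add(i)
    if dup:
        raise TripletFormatError(f"duplicate {kind} identifiers: {sorted(set(dup))}")


def _opt_float(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def read_triplet(data_matrix_path, sample_metadata_path, variable_metadata_path,
                 column_map: dict | None = None) -> MSDataset:
    """Read a dataMatrix / sampleMetadata / variableMetadata triplet.

    Parameters
    ----------
    column_map : dict, optional
        Mapping from :class:`SampleRecord` field names to the column names used
        in ``sampleMetadata``; merged over :data:`DEFAULT_COLUMN_MAP`.  The
        ``sample_type`` and ``injection_order`` columns are mandatory; a
        missing ``dilution_factor`` column is tolerated (the dilution filter is
        then skipped downstream).

    Returns
    -------
    MSDataset
        Sample and feature order taken from the dataMatrix; never reordered.

    Raises
    ------
    TripletFormatError
        On identifier mismatches (the offending identifiers are named),
        duplicates, non-numeric intensity cells, or missing mandatory columns.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})

    dm = _read_table(data_matrix_path)
    sm = _read_table(sample_metadata_path)
    vm = _read_table(variable_metadata_path)

    _check_ids("sample", dm.columns)
    _check_ids("feature", dm.index)

    missing_s = [c for c in dm.columns if c not in sm.index]
    extra_s = [c for c in sm.index if c not in dm.columns]
    if missing_s or extra_s:
        raise TripletFormatError(
            f"identifier mismatch between dataMatrix and sampleMetadata: "
            f"absent from sampleMetadata={missing_s}, absent from dataMatrix={extra_s}")
    missing_f = [r for r in dm.index if r not in vm.index]
    extra_f = [r for r in vm.index if r not in dm.index]
    if missing_f or extra_f:
        raise TripletFormatError(
            f"identifier mismatch between dataMatrix and variableMetadata: "
            f"absent from variableMetadata={missing_f}, absent from dataMatrix={extra_f}")

    try:
        intensities = dm.astype(float)
    except ValueError as exc:
        raise TripletFormatError(f"non-numeric intensity cell in dataMatrix: {exc}") from exc

    for mand in ("sample_type", "injection_order"):
        if cmap[mand] not in sm.columns:
            raise TripletFormatError(
                f"mandatory sampleMetadata column '{cmap[mand]}' (for {mand}) is missing")

    samples = []
    for sid in dm.columns:
        row = sm.loc[sid]
        raw_type = str(row[cmap["sample_type"]]).strip()
        key = raw_type.lower().replace("-", "_").replace(" ", "_")
        if key not in SAMPLE_TYPE_ALIASES:
            raise TripletFormatError(
                f"sample '{sid}': unknown sample type '{raw_type}' "
                f"(accepted: {sorted(set(SAMPLE_TYPE_ALIASES))})")
        stype = SAMPLE_TYPE_ALIASES[key]
        try:
            order = int(float(row[cmap["injection_order"]]))
        except (TypeError, ValueError) as exc:
            raise TripletFormatError(f"sample '{sid}': non-integer injection order") from exc
        dil = None
        if cmap["dilution_factor"] in sm.columns:
            dil = _opt_float(pd.to_numeric(row[cmap["dilution_factor"]], errors="coerce"))
        if stype != "pool_dilution":
            dil = None
        geno = str(row[cmap["genotype"]]) if cmap["genotype"] in sm.columns else "NA"
        sex = str(row[cmap["sex"]]) if cmap["sex"] in sm.columns else "NA"
        batch = str(row[cmap["batch"]]) if cmap["batch"] in sm.columns else ""
        samples.append(SampleRecord(
            id=sid, sample_type=stype, injection_order=order, dilution_factor=dil,
            genotype=geno if geno in GENOTYPES else "NA",
            sex=sex if sex in SEXES else "NA",
            batch="" if batch in ("nan",) else batch))

    features = []
    for fid in dm.index:
        row = vm.loc[fid]
        mz = _opt_float(pd.to_numeric(row.get("mz"), errors="coerce")) if "mz" in vm.columns else None
        rt = _opt_float(pd.to_numeric(row.get("rt"), errors="coerce")) if "rt" in vm.columns else None
        ann = row.get("annotation") if "annotation" in vm.columns else None
        if isinstance(ann, float) and np.isnan(ann):
            ann = None
        flags = set()
        if "flags" in vm.columns and isinstance(row.get("flags"), str) and row["flags"]:
            flags = set(row["flags"].split(","))
        grp = row.get("redundancy_group") if "redundancy_group" in vm.columns else None
        if isinstance(grp, float) and np.isnan(grp):
            grp = None
        features.append(FeatureRecord(
            id=fid,
            mz=float("nan") if mz is None else mz,
            rt=float("nan") if rt is None else rt,
            annotation=ann, flags=flags,
            qc_cv=_opt_float(pd.to_numeric(row.get("qc_cv"), errors="coerce")) if "qc_cv" in vm.columns else None,
            sample_cv=_opt_float(pd.to_numeric(row.get("sample_cv"), errors="coerce")) if "sample_cv" in vm.columns else None,
            redundancy_group=grp))

    log_flag = False
    if "log_transformed" in sm.columns:
        log_flag = str(sm[cmap.get("log_transformed", "log_transformed")].iloc[0]).lower() in ("true", "1")
    return MSDataset(intensities, samples, features, log_transformed=log_flag)


def write_triplet(dataset: MSDataset, out_dir) -> tuple[str, str, str]:
    """Write a dataset as dataMatrix.tsv / sampleMetadata.tsv / variableMetadata.tsv.

    Missing intensities are serialized as ``NA``.  Round-trips through
    :func:`read_triplet` up to floating-point text precision (12 significant
    digits).
    """
    os.makedirs(out_dir, exist_ok=True)
    dm_path = os.path.join(out_dir, "dataMatrix.tsv")
    sm_path = os.path.join(out_dir, "sampleMetadata.tsv")
    vm_path = os.path.join(out_dir, "variableMetadata.tsv")

    dm = dataset.intensities.copy()
    dm.index.name = "dataMatrix"
    dm.to_csv(dm_path, sep="\t", na_rep="NA", float_format="%.12g")

    sm = pd.DataFrame({
        "sampleType": [s.sample_type for s in dataset.samples],
        "injectionOrder": [s.injection_order for s in dataset.samples],
        "dilution": [s.dilution_factor if s.dilution_factor is not None else np.nan
                      for s in dataset.samples],
        "genotype": [s.genotype for s in dataset.samples],
        "sex": [s.sex for s in dataset.samples],
        "batch": [s.batch for s in dataset.samples],
        "log_transformed": [dataset.log_transformed] * dataset.n_samples,
    }, index=pd.Index(dataset.sample_ids, name="sampleMetadata"))
    sm.to_csv(sm_path, sep="\t", na_rep="NA", float_format="%.12g")

    vm = pd.DataFrame({
        "mz": [f.mz for f in dataset.features],
        "rt": [f.rt for f in dataset.features],
        "annotation": [f.annotation if f.annotation else np.nan for f in dataset.features],
        "flags": [",".join(sorted(f.flags)) if f.flags else np.nan for f in dataset.features],
        "qc_cv": [f.qc_cv if f.qc_cv is not None else np.nan for f in dataset.features],
        "sample_cv": [f.sample_cv if f.sample_cv is not None else np.nan for f in dataset.features],
        "redundancy_group": [f.redundancy_group if f.redundancy_group else np.nan
                              for f in dataset.features],
    }, index=pd.Index(dataset.feature_ids, name="variableMetadata"))
    vm.to_csv(vm_path, sep="\t", na_rep="NA", float_format="%.12g")
    return dm_path, sm_path, vm_path


def validate(dataset: MSDataset) -> list[str]:
    """Check all container invariants; return violation messages (empty if valid).

    Violations are returned, never raised, so a caller can report all problems
    of a dataset at once.
    """
    out = []
    sids = dataset.sample_ids
    fids = dataset.feature_ids
    if len(set(sids)) != len(sids):
        dup = sorted({i for i in sids if sids.count(i) > 1})
        out.append(f"duplicate sample identifiers: {dup}")
    if len(set(fids)) != len(fids):
        dup = sorted({i for i in fids if fids.count(i) > 1})
        out.append(f"duplicate feature identifiers: {dup}")
    if any(i == "" for i in sids):
        out.append("empty sample identifier")
    if any(i == "" for i in fids):
        out.append("empty feature identifier")

    orders = {}
    for s in dataset.samples:
        if s.sample_type not in SAMPLE_TYPES:
            out.append(f"sample '{s.id}': invalid sample_type '{s.sample_type}'")
        if s.injection_order in orders:
            out.append(f"duplicate injection_order {s.injection_order} "
                       f"(samples '{orders[s.injection_order]}' and '{s.id}')")
        else:
            orders[s.injection_order] = s.id
        if s.injection_order <= 0:
            out.append(f"sample '{s.id}': injection_order must be positive")
        if s.sample_type == "pool_dilution" and s.dilution_factor is None:
            out.append(f"sample '{s.id}': pool_dilution without dilution_factor")
        if s.sample_type != "pool_dilution" and s.dilution_factor is not None:
            out.append(f"sample '{s.id}': dilution_factor on a non-dilution sample")
        if s.dilution_factor is not None and s.dilution_factor <= 0:
            out.append(f"sample '{s.id}': dilution_factor must be positive")

    for f in dataset.features:
        if not np.isnan(f.mz) and f.mz <= 0:
            out.append(f"feature '{f.id}': mz must be > 0")
        if not np.isnan(f.rt) and f.rt < 0:
            out.append(f"feature '{f.id}': rt must be >= 0")
        for cv_name in ("qc_cv", "sample_cv"):
            v = getattr(f, cv_name)
            if v is not None and v < 0:
                out.append(f"feature '{f.id}': {cv_name} must be non-negative")

    if not dataset.log_transformed:
        vals = dataset.intensities.to_numpy()
        neg = np.nan_to_num(vals, nan=0.0) < 0
        if neg.any():
            rows = [dataset.feature_ids[i] for i in sorted(set(np.where(neg)[0]))]
            out.append(f"negative raw intensities (log_transformed=false) in features: {rows}")
    return out


# ---------------------------------------------------------------------------
# preclinical table I/O

def read_preclinical(path, sex_col: str = "sex", cohort_col: str = "cohort") -> PreclinicalTable:
    """Read an animals x variables TSV with sex and cohort columns."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                     keep_default_na=False, na_values=list(_NA_TOKENS))
    for col in (sex_col, cohort_col):
        if col not in df.columns:
            raise TripletFormatError(f"preclinical table lacks mandatory column '{col}'")
    sex = df[sex_col].astype(str)
    cohort = df[cohort_col].astype(str)
    values = df.drop(columns=[sex_col, cohort_col]).apply(pd.to_numeric, errors="raise")
    return PreclinicalTable(values, sex, cohort)


def write_preclinical(table: PreclinicalTable, path) -> str:
    df = table.values.copy()
    df.insert(0, "cohort", table.cohort)
    df.insert(0, "sex", table.sex)
    df.index.name = "animal"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
    return str(path)
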