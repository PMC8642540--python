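"""Synthetic LC-MS feature tables and preclinical cohorts with known truth.

The generator emulates the statistical structure an untargeted-metabolomics
post-processing pipeline assumes: an injection sequence with solvent blanks
first, a pooled-QC dilution series, then biological samples bracketed by
pooled QCs at a fixed cadence; per-feature multiplicative lognormal noise over
a ~4-decade dynamic range of baseline abundances; smooth monotone per-feature
signal drift along the injection order; blank-dominated background features;
chemically redundant feature groups (fixed m/z offsets, near-identical
retention times, strongly correlated profiles); and spiked standard compounds.
Every planted structure is recorded in a :class:`SyntheticTruth` so that
filter and metric behaviour can be scored exactly.

Preclinical cohorts are generated with per-sex normal or lognormal variables
and a historical-control vs project split, recording each variable's
generating family for transformation-selection scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FeatureRecord, MSDataset, PreclinicalTable, SampleRecord
from .mzref import DEFAULT_MZ_DIFFS


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


@dataclass
class SyntheticConfig:
    """Study design of a synthetic LC-MS run.

    Defaults mirror a single-batch plasma acquisition: 42 biological samples,
    a pooled QC every 5 injections, 3 solvent blanks, a 1/2/4/8 pooled-QC
    dilution series, 5% pooled-QC technical noise, 25% biological
    between-sample variation, and a signal drift of at most 30% relative
    amplitude over the sequence.
    """

    n_features: int = 200
    n_bio_samples: int = 42
    qc_every: int = 5
    n_blanks: int = 3
    dilution_factors: tuple = (1.0, 2.0, 4.0, 8.0)
    noise_cv: float = 0.05          # technical (injection-level) CV
    bio_cv: float = 0.25            # biological between-sample CV
    drift_amplitude: float = 0.30   # max |g - 1| over the sequence
    frac_blank_features: float = 0.10
    n_redundant_groups: int = 5
    redundant_group_size: int = 3   # representative + (size - 1) satellites
    mz_offsets: tuple = tuple(d for _, d in DEFAULT_MZ_DIFFS[:3])
    n_standards: int = 4
    frac_affected: float = 0.10     # features carrying a genotype/sex effect
    effect_log2: float = 1.0        # typical |log2 fold change| of effects
    seed: int = 0

    def validate(self) -> None:
        if self.qc_every < 2:
            raise ValueError("qc_every must be >= 2")
        for name in ("n_features", "n_bio_samples", "n_blanks", "n_redundant_groups",
                     "n_standards"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("noise_cv", "bio_cv", "drift_amplitude", "frac_blank_features",
                     "frac_affected"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.redundant_group_size < 2 and self.n_redundant_groups > 0:
            raise ValueError("redundant groups need >= 2 members")
        n_blank = round(self.frac_blank_features * self.n_features)
        n_red = self.n_redundant_groups * self.redundant_group_size
        if n_blank + n_red + self.n_standards > self.n_features:
            raise ValueError("config infeasible: planted blank features, redundancy groups "
                             "and standards exceed n_features")


@dataclass
class RedundancyGroup:
    representative: str
    members: list            # satellite feature ids (excluding the representative)
    offsets: list            # m/z offset of each satellite w.r.t. the representative


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_ms_dataset`."""

    blank_feature_ids: list
    redundancy_groups: list
    standard_ids: list
    baselines: pd.Series                 # per-feature true baseline abundance
    drift: pd.DataFrame                  # features x samples multiplicative g(order)
    effects: pd.DataFrame                # feature, covariate, level, log2fc
    config: SyntheticConfig

    @property
    def redundant_member_ids(self) -> list:
        return [m for g in self.redundancy_groups for m in g.members]

    def expected_final_feature_count(self) -> int:
        """Feature count after removing planted blank features and satellites."""
        return self.config.n_features - len(self.blank_feature_ids) - len(self.redundant_member_ids)

    def to_json(self) -> str:
        return json.dumps({
            "blank_feature_ids": self.blank_feature_ids,
            "redundancy_groups": [{"representative": g.representative,
                                   "members": g.members, "offsets": g.offsets}
                                  for g in self.redundancy_groups],
            "standard_ids": self.standard_ids,
            "expected_final_feature_count": self.expected_final_feature_count(),
            "effects": self.effects.to_dict(orient="records"),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
        }, indent=2)


def _injection_sequence(cfg: SyntheticConfig) -> list[SampleRecord]:
    """Blanks, then the dilution series, then pooled-QC-bracketed bio samples."""
    records = []
    order = 0
    for b in range(cfg.n_blanks):
        order += 1
        records.append(SampleRecord(f"blank{b + 1}", "blank", order))
    for d in cfg.dilution_factors:
        order += 1
        label = f"{d:g}".replace(".", "p")
        records.append(SampleRecord(f"dil_{label}", "pool_dilution", order, dilution_factor=float(d)))
    n_pool = 0

    def add_pool():
        nonlocal order, n_pool
        order += 1
        n_pool += 1
        records.append(SampleRecord(f"pool{n_pool:02d}", "pool", order))

    add_pool()
    for i in range(cfg.n_bio_samples):
        order += 1
        records.append(SampleRecord(f"s{i + 1:03d}", "sample", order))
        if (i + 1) % cfg.qc_every == 0 and i + 1 < cfg.n_bio_samples:
            add_pool()
    add_pool()
    return records


def generate_ms_dataset(config: SyntheticConfig | None = None):
    """Generate a synthetic feature table and its ground truth.

    Returns ``(MSDataset, SyntheticTruth)``; fully reproducible for a fixed
    ``config.seed``.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    samples = _injection_sequence(cfg)
    sample_ids = [s.id for s in samples]
    orders = np.array([s.injection_order for s in samples], dtype=float)
    n_samp = len(samples)
    nf = cfg.n_features

    # covariates of the biological samples
    bio_idx = [i for i, s in enumerate(samples) if s.sample_type == "sample"]
    genotypes = np.array(["LAT", "MX2", "WT"])[np.arange(len(bio_idx)) % 3]
    sexes = np.array(["M", "F"])[np.arange(len(bio_idx)) % 2]
    rng.shuffle(genotypes)
    rng.shuffle(sexes)
    for k, i in enumerate(bio_idx):
        samples[i].genotype = str(genotypes[k])
        samples[i].sex = str(sexes[k])

    # feature identities: m/z, RT, baseline abundance over ~4 decades
    fid = [f"M{i + 1:04d}" for i in range(nf)]
    mz = rng.uniform(85.0, 1000.0, nf)
    rt = rng.uniform(30.0, 1080.0, nf)
    baseline = 10.0 ** rng.uniform(3.5, 7.5, nf)

    # planted partition: blank-dominated, redundancy groups, standards
    n_blank_feat = round(cfg.frac_blank_features * nf)
    perm = rng.permutation(nf)
    blank_pos = list(perm[:n_blank_feat])
    cursor = n_blank_feat
    groups = []
    satellites = {}  # feature index -> (rep index, intensity ratio, offset)
    for g in range(cfg.n_redundant_groups):
        rep = perm[cursor]
        cursor += 1
        members = []
        offsets = []
        for _ in range(cfg.redundant_group_size - 1):
            m = perm[cursor]
            cursor += 1
            off = float(rng.choice(cfg.mz_offsets))
            mz[m] = mz[rep] + off + rng.uniform(-4e-4, 4e-4)
            rt[m] = rt[rep] + rng.uniform(-2.5, 2.5)
            ratio = rng.uniform(0.3, 0.7)
            satellites[m] = (rep, ratio, off)
            members.append(fid[m])
            offsets.append(off)
        groups.append(RedundancyGroup(fid[rep], members, offsets))
    standard_pos = list(perm[cursor:cursor + cfg.n_standards])
    cursor += cfg.n_standards
    is_blank_feat = np.zeros(nf, dtype=bool)
    is_blank_feat[blank_pos] = True
    is_standard = np.zeros(nf, dtype=bool)
    is_standard[standard_pos] = True

    # genotype / sex effects on a fraction of ordinary features
    ordinary = [i for i in range(nf)
                if not is_blank_feat[i] and not is_standard[i] and i not in satellites]
    n_affected = round(cfg.frac_affected * len(ordinary))
    affected = list(rng.choice(ordinary, size=n_affected, replace=False)) if n_affected else []
    effect_rows = []
    effect_mult = np.ones((nf, len(bio_idx)))
    for i in affected:
        if rng.random() < 0.5:
            covariate, level = "genotype", str(rng.choice(["LAT", "MX2"]))
            hit = genotypes == level
        else:
            covariate, level = "sex", str(rng.choice(["M", "F"]))
            hit = sexes == level
        lfc = float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.5) * cfg.effect_log2)
        effect_mult[i, hit] = 2.0 ** lfc
        effect_rows.append({"feature": fid[i], "covariate": covariate,
                            "level": level, "log2fc": lfc})

    # smooth monotone drift g(order) = exp(+-log1p(A) * s(t)/max|s|)
    t = (orders - orders.min()) / (orders.max() - orders.min()) * 2.0 - 1.0
    a = np.log1p(cfg.drift_amplitude)
    drift = np.ones((nf, n_samp))
    if cfg.drift_amplitude > 0:
        for i in range(nf):
            if is_standard[i] or i in satellites:
                continue
            b = rng.uniform(-0.4, 0.4)
            c = rng.uniform(-0.3, 0.3)
            s = t + 0.5 * b * t ** 2 + (c / 3.0) * t ** 3
            s = s / np.abs(s).max()
            sign = rng.choice([-1.0, 1.0])
            drift[i] = np.exp(sign * a * s)
        for m, (rep, _, _) in satellites.items():
            drift[m] = drift[rep]

    # expected per-sample levels before drift and technical noise
    level = np.zeros((nf, n_samp))
    bio_factor = np.ones((nf, len(bio_idx)))
    for i in range(nf):
        cv = 2.0 * cfg.noise_cv if is_standard[i] else cfg.bio_cv
        bio_factor[i] = effect_mult[i] * _lognormal_factor(rng, cv, len(bio_idx))
    bio_level = baseline[:, None] * bio_factor
    pool_level = bio_level.mean(axis=1)  # pooling = average of the biological samples
    blank_level = np.where(is_blank_feat, pool_level / 1.5, pool_level / 20.0)

    for j, s in enumerate(samples):
        if s.sample_type == "sample":
            level[:, j] = bio_level[:, bio_idx.index(j)]
        elif s.sample_type == "pool":
            level[:, j] = pool_level
        elif s.sample_type == "pool_dilution":
            level[:, j] = pool_level / s.dilution_factor
        else:  # blank
            level[:, j] = blank_level

    noise = np.ones((nf, n_samp))
    for j, s in enumerate(samples):
        if s.sample_type == "sample":
            continue  # biological variation already drawn above
        noise[:, j] = _lognormal_factor(rng, cfg.noise_cv, nf)
    values = level * drift * noise

    # satellites copy their representative's profile (x ratio, tight noise)
    for m, (rep, ratio, _) in satellites.items():
        values[m] = values[rep] * ratio * _lognormal_factor(rng, 0.3 * cfg.noise_cv, n_samp)
        baseline[m] = baseline[rep] * ratio

    features = [FeatureRecord(fid[i], mz=float(mz[i]), rt=float(rt[i]),
                              annotation="standard" if is_standard[i] else None)
                for i in range(nf)]
    intensities = pd.DataFrame(values, index=fid, columns=sample_ids)
    dataset = MSDataset(intensities, samples, features, log_transformed=False)
    truth = SyntheticTruth(
        blank_feature_ids=[fid[i] for i in blank_pos],
        redundancy_groups=groups,
        standard_ids=[fid[i] for i in standard_pos],
        baselines=pd.Series(baseline, index=fid),
        drift=pd.DataFrame(drift, index=fid, columns=sample_ids),
        effects=pd.DataFrame(effect_rows, columns=["feature", "covariate", "level", "log2fc"]),
        config=cfg)
    return dataset, truth


# ---------------------------------------------------------------------------
# preclinical cohorts

@dataclass
class PreclinicalTruth:
    """Generating family (and canonical transform) of each variable."""

    family: dict              # variable -> "normal" | "lognormal"
    canonical_transform: dict  # variable -> "identity" | "log"
    params: dict              # variable -> per-sex (mean-scale, spread) parameters
    shifted_variables: list = field(default_factory=list)


def generate_preclinical(n_historical: int = 1112, n_project: int = 15,
                         n_variables: int = 200, skewed_fraction: float = 1.0 / 3.0,
                         male_fraction: float = 573.0 / 1112.0, seed: int = 0,
                         n_shifted_variables: int = 0, shift_sd: float = 0.0):
    """Generate a historical + project preclinical phenotyping table.

    Defaults mirror a large historical-control database (1112 wild-type
    animals, 573 males / 539 females, 200 quantitative variables, about one
    third of them skewed) plus a 15-animal project control cohort drawn from
    the same distributions.  ``n_shifted_variables`` project variables can be
    displaced by ``shift_sd`` historical standard deviations to plant
    reference-range violations.

    Returns ``(PreclinicalTable, PreclinicalTruth)``; the table's ``cohort``
    labels are ``historical`` and ``project``.
    """
    if n_historical < 3:
        raise ValueError("n_historical must be >= 3")
    rng = np.random.default_rng(seed)
    n_skewed = round(skewed_fraction * n_variables)
    families = np.array(["lognormal"] * n_skewed + ["normal"] * (n_variables - n_skewed))
    rng.shuffle(families)
    var_names = [f"v{i + 1:03d}" for i in range(n_variables)]

    def make_sexes(n, n_males):
        s = np.array(["M"] * n_males + ["F"] * (n - n_males))
        rng.shuffle(s)
        return s

    n_hist_m = round(male_fraction * n_historical)
    sex_h = make_sexes(n_historical, n_hist_m)
    sex_p = make_sexes(n_project, round(male_fraction * n_project))

    cols_h = np.empty((n_historical, n_variables))
    cols_p = np.empty((n_project, n_variables))
    params = {}
    shifted = sorted(rng.choice(n_variables, size=n_shifted_variables, replace=False).tolist()) \
        if n_shifted_variables else []
    for v in range(n_variables):
        mu_m = rng.uniform(10.0, 200.0)
        mu_f = mu_m * rng.uniform(0.8, 1.2)
        rel = rng.uniform(0.08, 0.15)
        sdlog = rng.uniform(0.3, 0.6)
        params[var_names[v]] = {"mu_M": mu_m, "mu_F": mu_f, "rel_sd": rel, "sdlog": sdlog,
                                "family": families[v]}
        for sex_arr, out in ((sex_h, cols_h), (sex_p, cols_p)):
            for sex_label, mu in (("M", mu_m), ("F", mu_f)):
                mask = sex_arr == sex_label
                n = int(mask.sum())
                if families[v] == "normal":
                    draw = rng.normal(mu, rel * mu, n)
                else:
                    draw = np.exp(rng.normal(np.log(mu), sdlog, n))
                out[mask, v] = draw
        if v in shifted and shift_sd != 0:
            if families[v] == "normal":
                cols_p[:, v] += shift_sd * rel * mu_m
            else:
                cols_p[:, v] *= np.exp(shift_sd * sdlog)

    ids_h = [f"h{i + 1:04d}" for i in range(n_historical)]
    ids_p = [f"p{i + 1:03d}" for i in range(n_project)]
    values = pd.DataFrame(np.vstack([cols_h, cols_p]), index=ids_h + ids_p, columns=var_names)
    sex = pd.Series(np.concatenate([sex_h, sex_p]), index=values.index, name="sex")
    cohort = pd.Series(["historical"] * n_historical + ["project"] * n_project,
                       index=values.index, name="cohort")
    table = PreclinicalTable(values, sex, cohort)
    truth = PreclinicalTruth(
        family={var_names[v]: str(families[v]) for v in range(n_variables)},
        canonical_transform={var_names[v]: ("identity" if families[v] == "normal" else "log")
                             for v in range(n_variables)},
        params=params,
        shifted_variables=[var_names[v] for v in shifted])
    return table, truth
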