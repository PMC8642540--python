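"""The five-filter post-processing chain: stated rules, boundaries, properties."""

import numpy as np
import pandas as pd
import pytest

from metaboqc import (MzDiffTable, PipelineParams, SampleRecord, SyntheticConfig,
                      blank_filter, cv_filter, dilution_filter, drift_correct,
                      generate_ms_dataset, log2_transform, redundancy_filter,
                      run_pipeline)

from conftest import bio, make_dataset


def blanks_and_bio(blank_vals, bio_vals):
    """One-feature dataset with given blank and biological intensities."""
    records = ([SampleRecord(f"b{i+1}", "blank", i + 1) for i in range(len(blank_vals))]
               + bio(len(bio_vals), start_order=len(blank_vals) + 1))
    return make_dataset([list(blank_vals) + list(bio_vals)], records)


class TestBlankFilter:
    @pytest.mark.parametrize("blank_vals,bio_vals,kept", [
        ((3, 3), (8, 8), False),      # 8 < 3*3: discarded
        ((4, 4), (12, 12), True),     # equality passes: only strictly less discarded
        ((0, 0), (5, 5), True),       # zero background always kept
    ])
    def test_stated_rule_and_boundary(self, blank_vals, bio_vals, kept):
        ds = blanks_and_bio(blank_vals, bio_vals)
        out, rep = blank_filter(ds)
        assert (out.n_features == 1) == kept
        if not kept:
            assert "F1" in rep.discarded
            assert "blank_fail" in ds.features[0].flags

    def test_missing_values_ignored_in_means(self):
        ds = blanks_and_bio((3, np.nan), (np.nan, 9, 9))
        out, _ = blank_filter(ds)   # bio mean 9 >= 3*3
        assert out.n_features == 1

    def test_no_blanks_skips_with_warning(self):
        ds = make_dataset([[1, 2, 3]], bio(3))
        with pytest.warns(UserWarning, match="skipped"):
            out, rep = blank_filter(ds)
        assert rep.skipped and out.n_features == 1


def dilution_ds(factors, intensities):
    records = [SampleRecord(f"d{i+1}", "pool_dilution", i + 1, dilution_factor=f)
               for i, f in enumerate(factors)]
    records += bio(3, start_order=len(factors) + 1)
    row = list(intensities) + [1.0, 1.0, 1.0]
    return make_dataset([row], records)


class TestDilutionFilter:
    def test_exact_proportionality_kept(self):
        out, _ = dilution_filter(dilution_ds((1, 2, 4), (10, 5, 2.5)))
        assert out.n_features == 1

    def test_constant_intensities_discarded(self):
        out, rep = dilution_filter(dilution_ds((1, 2, 4), (7, 7, 7)))
        assert out.n_features == 0 and "zero-variance" in rep.discarded["F1"]

    def test_example_r_against_hand_formula(self):
        factors, intens = (1, 2, 4, 8), (10.0, 6.0, 2.0, 1.0)
        x = 1.0 / np.array(factors)
        y = np.array(intens)
        # textbook Pearson formula, written out
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r_hand == pytest.approx(0.98828, abs=1e-5)
        out, _ = dilution_filter(dilution_ds(factors, intens))
        assert out.n_features == 1  # r > 0.7

    def test_too_few_dilutions_skips(self):
        ds = dilution_ds((1, 2), (10, 5))
        with pytest.warns(UserWarning, match="skipped"):
            _, rep = dilution_filter(ds)
        assert rep.skipped


def drift_sequence(n_pool, n_bio, pool_fn, bio_fn):
    """Interleave pools and bios along the injection order with given level functions."""
    records, row = [], []
    pools = np.linspace(1, n_pool + n_bio, n_pool, dtype=int)
    pool_set = set(pools.tolist())
    bi = 0
    for o in range(1, n_pool + n_bio + 1):
        if o in pool_set:
            records.append(SampleRecord(f"p{o}", "pool", o))
            row.append(pool_fn(o))
        else:
            bi += 1
            records.append(SampleRecord(f"s{bi}", "sample", o))
            row.append(bio_fn(o))
    return make_dataset([row], records)


class TestDriftCorrect:
    def test_constant_signal_is_identity(self):
        ds = drift_sequence(6, 6, lambda o: 100.0, lambda o: 100.0)
        out, _ = drift_correct(ds, reference="pool")
        assert np.allclose(out.intensities.to_numpy(), 100.0, rtol=1e-9)

    def test_linear_drift_noiseless_pool_cv_below_1e6(self):
        # 20 injections, intensity strictly linear in the order
        ds = drift_sequence(7, 13, lambda o: 100.0 + 5.0 * o, lambda o: 100.0 + 5.0 * o)
        out, _ = drift_correct(ds, reference="pool")
        pools = out.values_of_type("pool").to_numpy().ravel()
        assert pools.std(ddof=1) / pools.mean() < 1e-6

    def test_few_reference_points_left_uncorrected(self):
        ds = drift_sequence(3, 9, lambda o: 50.0 + o, lambda o: 50.0 + o)
        with pytest.warns(UserWarning):
            out, rep = drift_correct(ds, reference="pool")
        assert rep.skipped
        assert np.allclose(out.intensities.to_numpy(), ds.intensities.to_numpy())
        assert "drift_corrected" not in out.features[0].flags

    def test_reference_median_preserved(self):
        rng = np.random.default_rng(0)
        ds = drift_sequence(8, 16, lambda o: 100 + 3 * o + rng.normal(0, 2),
                            lambda o: 120 + 2 * o + rng.normal(0, 5))
        pool_ids = ds.sample_ids_of_type("pool")
        before = np.median(ds.intensities[pool_ids].to_numpy())
        out, _ = drift_correct(ds, reference="pool")
        after = np.median(out.intensities[pool_ids].to_numpy())
        assert after == pytest.approx(before, rel=1e-6)

    def test_invalid_span_rejected(self):
        ds = drift_sequence(6, 6, lambda o: 1.0, lambda o: 1.0)
        with pytest.raises(ValueError, match="span"):
            drift_correct(ds, span=0.0)
        with pytest.raises(ValueError, match="span"):
            drift_correct(ds, span=1.5)


def pool_bio_ds(rows_pool, rows_bio):
    n_pool = len(rows_pool[0])
    n_bio = len(rows_bio[0])
    records = ([SampleRecord(f"p{i+1}", "pool", i + 1) for i in range(n_pool)]
               + bio(n_bio, start_order=n_pool + 1))
    vals = [list(p) + list(b) for p, b in zip(rows_pool, rows_bio)]
    return make_dataset(vals, records)


class TestCvFilter:
    def test_zero_cv_kept(self):
        ds = pool_bio_ds([[100, 100, 100]], [[90, 110, 95]])
        out, _ = cv_filter(ds)
        assert out.n_features == 1
        assert out.features[0].qc_cv == 0.0

    def test_high_pool_cv_discarded(self):
        ds = pool_bio_ds([[100, 180, 60]], [[1000, 100, 550]])  # CV_pool ~ 0.53
        out, rep = cv_filter(ds)
        assert out.n_features == 0 and "F1" in rep.discarded

    def test_pool_cv_above_bio_cv_discarded(self):
        pool = [100, 120, 80]                    # CV = 0.2
        bio_vals = [100, 110, 90, 105, 95]       # CV ~ 0.076
        ds = pool_bio_ds([pool], [bio_vals])
        out, rep = cv_filter(ds)
        assert out.n_features == 0
        assert "CV_bio" in rep.discarded["F1"]


class TestRedundancyFilter:
    def base(self, profiles, mzs, rts):
        records = bio(len(profiles[0]))
        return make_dataset(profiles, records, mz=mzs, rt=rts)

    def test_isotope_pair_collapsed_to_stronger(self):
        a = [100, 200, 300, 400, 500]
        b = [51, 99, 152, 198, 251]  # ~half intensity, correlated
        ds = self.base([a, b], mzs=[200.0, 201.00336], rts=[300.0, 302.0])
        out, rep = redundancy_filter(ds)
        assert out.feature_ids == ["F1"]
        assert "F2" in rep.discarded
        assert ds.features[0].redundancy_group == ds.features[1].redundancy_group

    def test_unlisted_mz_offset_not_grouped(self):
        a = [100, 200, 300, 400, 500]
        b = [50, 100, 150, 200, 250]
        ds = self.base([a, b], mzs=[200.0, 201.5], rts=[300.0, 302.0])
        out, _ = redundancy_filter(ds)
        assert out.n_features == 2

    def test_distant_rt_not_grouped(self):
        a = [100, 200, 300, 400, 500]
        b = [50, 100, 150, 200, 250]
        ds = self.base([a, b], mzs=[200.0, 201.00336], rts=[300.0, 310.0])
        out, _ = redundancy_filter(ds)
        assert out.n_features == 2

    def test_chain_forms_single_component(self):
        # A-B and B-C match the reference list; A-C (2 x isotope spacing) does not
        a = [100, 200, 300, 400, 500]
        b = [80, 160, 240, 320, 400]
        c = [60, 121, 180, 242, 300]
        ds = self.base([a, b, c],
                       mzs=[200.0, 201.00336, 202.00672], rts=[300.0, 301.0, 302.0])
        # brute-force connected components of the 3-node toy graph
        table = MzDiffTable()
        edges = [(i, j) for i in range(3) for j in range(i + 1, 3)
                 if table.matches([200.0, 201.00336, 202.00672][i],
                                  [200.0, 201.00336, 202.00672][j])]
        assert (0, 1) in edges and (1, 2) in edges and (0, 2) not in edges
        out, rep = redundancy_filter(ds)
        assert out.feature_ids == ["F1"]          # one component of 3, two removed
        assert set(rep.discarded) == {"F2", "F3"}

    def test_tie_breaks_toward_lowest_mz(self):
        a = [100, 200, 300]
        b = [100, 200, 300]
        ds = self.base([a, b], mzs=[300.00336, 299.0], rts=[100.0, 101.0])
        out, _ = redundancy_filter(ds)
        assert out.feature_ids == ["F2"]

    def test_missing_mz_rejected(self):
        ds = self.base([[1, 2, 3]], mzs=[np.nan], rts=[10.0])
        with pytest.raises(ValueError, match="lacks mz or rt"):
            redundancy_filter(ds)


class TestLog2:
    def test_values_and_zero_to_missing(self):
        ds = make_dataset([[8.0, 0.0, 1.0]], bio(3))
        out = log2_transform(ds)
        assert out.intensities.iloc[0, 0] == 3.0
        assert np.isnan(out.intensities.iloc[0, 1])
        assert out.intensities.iloc[0, 2] == 0.0
        assert out.log_transformed

    def test_double_application_rejected(self):
        ds = log2_transform(make_dataset([[8.0]], bio(1)))
        with pytest.raises(ValueError, match="already"):
            log2_transform(ds)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(make_dataset([[-1.0]], bio(1), log_transformed=False))


class TestPipeline:
    def test_all_steps_disabled_is_identity(self, default_synth):
        ds, _ = default_synth
        out, reports = run_pipeline(ds, PipelineParams(steps=()))
        assert out.equals(ds) and reports == []

    def test_reordered_steps_rejected(self):
        with pytest.raises(ValueError, match="order is fixed"):
            PipelineParams(steps=("cv", "blank"))

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PipelineParams(steps=("blank", "zscore"))

    def test_cascade_counts_are_consistent(self, default_synth):
        ds, _ = default_synth
        out, reports = run_pipeline(ds)
        for rep in reports:
            assert rep.n_features_out == rep.n_features_in - len(rep.discarded)
        for prev, nxt in zip(reports, reports[1:]):
            assert nxt.n_features_in == prev.n_features_out
        assert reports[-1].n_features_out == out.n_features


class TestFilterProperties:
    """Idempotence and scale invariance of the filters."""

    @pytest.mark.parametrize("filt,kwargs", [
        (blank_filter, {}), (dilution_filter, {}), (cv_filter, {}),
        (redundancy_filter, {}),
    ])
    def test_idempotent(self, default_synth, filt, kwargs):
        ds, _ = default_synth
        once, _ = filt(ds.copy(), **kwargs)
        twice, _ = filt(once.copy(), **kwargs)
        assert twice.feature_ids == once.feature_ids
        assert np.allclose(twice.intensities.to_numpy(), once.intensities.to_numpy(),
                           equal_nan=True)

    @pytest.mark.parametrize("filt", [blank_filter, dilution_filter, cv_filter])
    def test_scale_invariant(self, default_synth, filt):
        ds, _ = default_synth
        scaled = ds.copy()
        scaled.intensities = scaled.intensities * 137.5
        a, _ = filt(ds.copy())
        b, _ = filt(scaled)
        assert a.feature_ids == b.feature_ids
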