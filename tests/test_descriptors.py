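"""Splicing descriptor computation: filters, loads, frequencies, medians."""

import numpy as np
import pandas as pd
import pytest

from irsplice.descriptors import (
    AsEvent,
    ExpressionMatrix,
    PsiMatrix,
    autoantigen_load,
    expression_descriptors,
    filter_as_events,
    filter_low_abundance,
    log_transform,
    median_by_cancer_type,
    neojunction_load,
    psi_category,
    splicing_frequency,
    splicing_load,
)
from irsplice.errors import InputError

from conftest import random_filtered_psi


class TestExpressionFilters:
    def test_low_abundance_rules(self, toy_expression):
        kept = filter_low_abundance(toy_expression)
        # max 8 < 10 fails; median 0 fails; median 1.65 fails; constant 50 passes
        assert list(kept.tpm.index) == ["kept_high"]

    def test_idempotent(self, toy_expression):
        once = filter_low_abundance(toy_expression)
        twice = filter_low_abundance(once)
        pd.testing.assert_frame_equal(once.tpm, twice.tpm)

    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, np.log2(0.001)), (0.999, 0.0), (7.999, 3.0)],
    )
    def test_log_transform_values(self, value, expected):
        m = ExpressionMatrix(tpm=pd.DataFrame({"s": [value]}, index=["f"]))
        out = log_transform(m)
        assert out.tpm.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_negative_tpm_rejected(self):
        with pytest.raises(InputError):
            ExpressionMatrix(tpm=pd.DataFrame({"s": [-1.0]}, index=["f"]))


class TestAsEventFilter:
    def test_detection_threshold_strict(self):
        # 11 samples; one event detected in 10, another in 11
        vals = np.full((2, 11), 0.5)
        vals[0, 0] = np.nan
        p = PsiMatrix(
            psi=pd.DataFrame(vals, index=["ten", "eleven"],
                             columns=[f"S{i}" for i in range(11)]),
            events=pd.DataFrame({"gene": ["g", "g"], "mode": ["EX", "EX"]},
                                index=["ten", "eleven"]),
        )
        kept = filter_as_events(p)
        assert list(kept.psi.index) == ["eleven"]

    def test_extreme_psi_masked_and_empty_dropped(self):
        vals = np.full((2, 12), 0.98)
        vals[1] = [0.03, 0.5] * 6  # half masked, half kept
        p = PsiMatrix(
            psi=pd.DataFrame(vals, index=["all_high", "mixed"],
                             columns=[f"S{i}" for i in range(12)]),
            events=pd.DataFrame({"gene": ["g", "g"], "mode": ["RI", "RI"]},
                                index=["all_high", "mixed"]),
        )
        kept = filter_as_events(p)
        assert list(kept.psi.index) == ["mixed"]  # all-0.98 event fully masked
        assert kept.psi.loc["mixed"].notna().sum() == 6

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        p = random_filtered_psi(rng)
        once = filter_as_events(p)
        twice = filter_as_events(once)
        pd.testing.assert_frame_equal(once.psi, twice.psi)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            AsEvent(event_id="e", gene="g", mode="XX")


class TestSplicingLoad:
    def test_category_boundaries(self):
        cats = psi_category([0.10, 0.20, 0.21, 0.40, 0.41, 0.80, 0.81, 0.95])
        assert list(cats) == [
            "highly_excluded", "highly_excluded", "mid_excluded", "mid_excluded",
            "mid_included", "mid_included", "highly_included", "highly_included",
        ]

    def test_toy_counts(self, toy_psi):
        load = splicing_load(toy_psi)
        # S0: e1=0.50, e2=0.10, e3=0.85 detected
        assert load.loc["S0", "total"] == 3
        assert load.loc["S0", "mode:EX"] == 1
        assert load.loc["S0", "mode:RI"] == 1
        assert load.loc["S0", "mode:AS3"] == 1
        assert load.loc["S0", "cat:highly_excluded"] == 1
        assert load.loc["S0", "cat:mid_included"] == 1
        assert load.loc["S0", "cat:highly_included"] == 1

    def test_unfiltered_input_rejected(self):
        p = PsiMatrix(
            psi=pd.DataFrame({"S0": [0.99]}, index=["e"]),
            events=pd.DataFrame({"gene": ["g"], "mode": ["EX"]}, index=["e"]),
        )
        with pytest.raises(InputError):
            splicing_load(p)

    def test_conservation_on_random_matrices(self):
        """Total load partitions into mode loads and into category loads."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = random_filtered_psi(rng)
            load = splicing_load(p)
            mode_cols = [c for c in load.columns if c.startswith("mode:")]
            cat_cols = [c for c in load.columns if c.startswith("cat:")]
            assert (load[mode_cols].sum(axis=1) == load["total"]).all()
            assert (load[cat_cols].sum(axis=1) == load["total"]).all()
            assert (load >= 0).all().all()


class TestSplicingFrequency:
    def test_toy_values(self, toy_psi, toy_sample_map):
        freq = splicing_frequency(toy_psi, toy_sample_map)
        # gA in T1: S0 (e1,e2), S1 (e1), S2 (e2) -> 3/3; union counts once
        assert freq.loc["T1", "gA"] == pytest.approx(1.0)
        # gB in T2: S3 nan, S4 nan, S5 0.82 -> 1/3
        assert freq.loc["T2", "gB"] == pytest.approx(1 / 3)

    def test_set_union_oracle(self, toy_sample_map):
        """Brute-force per-gene union over events matches the implementation."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_filtered_psi(rng, n_events=20, n_samples=15)
            smap = pd.Series(
                rng.choice(["T1", "T2", "T3"], size=15),
                index=p.psi.columns,
            )
            freq = splicing_frequency(p, smap)
            for gene in p.events["gene"].unique():
                ev = p.events.index[p.events["gene"] == gene]
                for ct in smap.unique():
                    samples = smap.index[smap == ct]
                    hit = sum(
                        any(not np.isnan(p.psi.loc[e, s]) for e in ev)
                        for s in samples
                    )
                    assert freq.loc[ct, gene] == pytest.approx(hit / len(samples))

    def test_bounds(self, small_study):
        from irsplice.descriptors import filter_as_events

        freq = splicing_frequency(
            filter_as_events(small_study.psi), small_study.sample_map
        )
        assert ((freq >= 0) & (freq <= 1)).all().all()


class TestLoadsAndMedians:
    def test_neojunction_median(self):
        counts = pd.Series({"s1": 12, "s2": 1, "s3": 2, "s4": 3, "s5": 4})
        smap = pd.Series({"s1": "A", "s2": "B", "s3": "B", "s4": "B", "s5": "B"})
        med = neojunction_load(counts, smap)
        assert med["A"] == 12  # single-sample median
        assert med["B"] == 2.5  # even-n midpoint convention

    def test_neojunction_permutation_invariance(self):
        rng = np.random.default_rng(5)
        counts = pd.Series(rng.poisson(20, 12), index=[f"s{i}" for i in range(12)])
        smap = pd.Series(["A"] * 6 + ["B"] * 6, index=counts.index)
        base = neojunction_load(counts, smap)
        perm = counts.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(neojunction_load(perm, smap), base)

    def test_autoantigen_load_restriction(self, toy_psi, toy_sample_map):
        all_genes = set(toy_psi.events["gene"])
        total = splicing_load(toy_psi)["total"]
        full = autoantigen_load(toy_psi, all_genes, toy_sample_map)
        expected = total.groupby(toy_sample_map).median()
        pd.testing.assert_series_equal(full, expected, check_names=False)
        empty = autoantigen_load(toy_psi, set(), toy_sample_map)
        assert (empty == 0).all()

    def test_autoantigen_hand_count(self, toy_psi, toy_sample_map):
        # gA only: S0 has e1+e2 detected -> contributes 2
        load = splicing_load(toy_psi)
        per_sample = toy_psi.psi.loc[["e1", "e2"]].notna().sum(axis=0)
        assert per_sample["S0"] == 2
        res = autoantigen_load(toy_psi, {"gA"}, toy_sample_map)
        assert res["T1"] == per_sample[["S0", "S1", "S2"]].median()

    def test_median_by_cancer_type(self, toy_sample_map):
        tpm = pd.DataFrame(
            [[1.0, 2.0, 100.0, 5.0, 5.0, 5.0]],
            index=["f"],
            columns=toy_sample_map.index,
        )
        m = ExpressionMatrix(tpm=tpm)
        med = median_by_cancer_type(m, toy_sample_map)
        assert med.loc["T1", "f"] == 2.0  # robust to the outlier 100

    def test_unknown_sample_raises(self, toy_expression):
        with pytest.raises(InputError, match="sample"):
            median_by_cancer_type(toy_expression, pd.Series({"S0": "T1"}))


def test_expression_descriptor_pipeline_order(toy_sample_map):
    """Median of raw TPM is taken before the log transform."""
    tpm = pd.DataFrame(
        [[16.0, 16.0, 64.0, 4.0, 4.0, 16.0]],
        index=["f"],
        columns=toy_sample_map.index,
    )
    d = expression_descriptors(ExpressionMatrix(tpm=tpm), toy_sample_map)
    # T1 median raw = 16 -> log2(16.001); log-then-median would give log2 16 + eps
    assert d.values.loc["T1", "gene:f"] == pytest.approx(np.log2(16.001))
    assert d.classes["gene:f"] == "gene_expr"
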