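"""Pearson/Mann-Whitney testing, Bonferroni adjustment and the full table."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cesm_radiomics import (
    CohortConfig,
    bonferroni_adjust,
    build_association_table,
    extract_cohort_features,
    features_to_frame,
    generate_cohort,
    mann_whitney_test,
    pearson_test,
    render_association_markdown,
)
from cesm_radiomics.cohort_io import LesionRecord
from cesm_radiomics.features import FEATURE_NAMES

from oracle_utils import brute_force_mannwhitney_exact_p


class TestPearson:
    def test_perfect_linear_relation(self):
        r, p, n = pearson_test([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_alternating_example_matches_reference(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, -1.0, 1.0, -1.0]
        r, p, _ = pearson_test(x, y)
        ref_r, ref_p = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(ref_r, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            r, p, _ = pearson_test(x, y)
            ref_r, ref_p = scipy.stats.pearsonr(x, y)
            assert r == pytest.approx(ref_r, rel=1e-10, abs=1e-12)
            assert p == pytest.approx(ref_p, rel=1e-8, abs=1e-12)

    def test_planted_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(404)
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        r, _, _ = pearson_test(x, y)
        assert 0.45 < r < 0.55

    def test_pairwise_deletion_reports_n_used(self):
        x = [1.0, np.nan, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, np.nan, 4.0, 6.0]
        _, _, n = pearson_test(x, y)
        assert n == 3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_test([1.0, 2.0], [3.0, 4.0])


class TestMannWhitney:
    def test_disjoint_triples_exact(self):
        u, p = mann_whitney_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_test(a, list(a), mode="normal")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 5), (6, 6), (8, 4)])
    def test_exact_p_equals_full_enumeration(self, rng, n1, n2):
        vals = rng.permutation(100)[: n1 + n2].astype(float)
        a, b = vals[:n1], vals[n1:]
        _, p = mann_whitney_test(a, b, mode="exact")
        assert p == pytest.approx(brute_force_mannwhitney_exact_p(a, b), abs=1e-12)

    def test_exact_with_ties_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            _, p = mann_whitney_test([1, 2, 2], [2, 3, 4], mode="exact")
        assert "falling back" in caplog.text
        assert 0 <= p <= 1

    def test_normal_mode_matches_reference_with_ties(self, rng):
        for _ in range(20):
            a = rng.integers(0, 10, size=15).astype(float)
            b = rng.integers(0, 10, size=12).astype(float)
            u, p = mann_whitney_test(a, b, mode="normal")
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="asymptotic", use_continuity=True)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_test([], [1.0])

    def test_exact_cap_enforced(self):
        a = np.arange(20, dtype=float)
        b = np.arange(50, 70, dtype=float)
        with pytest.raises(ValueError, match="exact mode limited"):
            mann_whitney_test(a, b, mode="exact", exact_cap=25)


class TestBonferroni:
    def test_definition_and_cap(self):
        out = bonferroni_adjust([0.01, 0.2], family_size=14)
        assert out[0] == pytest.approx(0.14)
        assert out[1] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjustment_is_monotone_and_dominates_raw(self, ps):
        out = bonferroni_adjust(ps, family_size=len(ps) + 3)
        assert np.all(out >= np.asarray(ps))
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(out)[order]) >= -1e-15)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError, match="family_size"):
            bonferroni_adjust([0.1, 0.2, 0.3], family_size=2)


class TestAssociationTable:
    def test_structure_and_adjustment(self, small_cohort, small_features):
        _, records, _ = small_cohort
        table = build_association_table(small_features, records)
        assert len(table) == 5 * 14
        assert set(table["outcome"]) == {"ER", "PR", "Ki67", "HER2", "Grade"}
        pear = table[table["statistic_type"] == "pearson_r"]
        assert set(pear["outcome"]) == {"ER", "PR", "Ki67"}
        assert np.all(np.abs(pear["statistic"]) <= 1.0)
        mw = table[table["statistic_type"] == "mannwhitney_U"]
        assert np.all(mw["statistic"] >= 0)
        assert np.allclose(table["p_adjusted"],
                           np.minimum(1.0, 14 * table["p_raw"]))
        assert (table["family_size"] == 14).all()

    def test_global_family_uses_all_seventy_tests(self, small_cohort, small_features):
        _, records, _ = small_cohort
        table = build_association_table(small_features, records, family="global")
        assert (table["family_size"] == 70).all()
        assert np.allclose(table["p_adjusted"], np.minimum(1.0, 70 * table["p_raw"]))

    def test_planted_effect_survives_bonferroni_at_large_n(self):
        cfg = CohortConfig(n_lesions=500, seed=99,
                           effect_map=(("ki67_pct", "RC_VC", 0.5),))
        records, pairs = generate_cohort(cfg)
        feats = features_to_frame(extract_cohort_features(pairs))
        table = build_association_table(feats, records)
        row = table[(table["outcome"] == "Ki67") & (table["feature"] == "RC_VC")].iloc[0]
        assert row.p_adjusted < 0.05
        assert row.statistic > 0.3

    def test_degenerate_single_group_outcome_rejected(self, small_features):
        records = [
            LesionRecord(f"L{i:04d}", f"P{i:04d}", er_pct=50.0 + i, pr_pct=10.0 + i,
                         ki67_pct=30.0 + i, her2="-", grade="G2")
            for i in range(30)
        ]
        with pytest.raises(ValueError, match="single group"):
            build_association_table(small_features, records)

    def test_misaligned_inputs_rejected(self, small_cohort, small_features):
        _, records, _ = small_cohort
        with pytest.raises(ValueError, match="aligned"):
            build_association_table(small_features, records[::-1])

    def test_markdown_rendering_contains_all_features(self, small_cohort, small_features):
        _, records, _ = small_cohort
        text = render_association_markdown(build_association_table(small_features, records))
        for name in FEATURE_NAMES:
            assert name in text
        assert "p < 0.10" in text
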