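"""Training-set construction, multiple testing, binning and p-score assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coipscore import (
    SimConfig,
    assign_pscores,
    benjamini_hochberg,
    bin_training_set,
    build_training_set,
    call_interactors,
    fit_error_model,
    simulate_coip,
    summarize_stress_intensity,
)
from coipscore.errors import InsufficientDataError, ParameterError
from coipscore.scoring import (
    FALSE_INTERACTOR,
    TRUE_INTERACTOR,
    PScoreRecord,
    TrainingEntry,
    welch_test,
)
from conftest import make_quant


# --- independent oracles ------------------------------------------------------


def welch_oracle(a, b):
    """Textbook Welch t and two-sided p via the Satterthwaite df formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (b.mean() - a.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, 2.0 * stats.t.sf(abs(t), df)


def bh_oracle(p):
    """q(i) = min_{j >= i} p(j) * m / j on the sorted p-values, by brute force."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


# --- stress summary -----------------------------------------------------------


class TestSummarizeStressIntensity:
    def test_constant_intensities_give_their_log(self):
        q = make_quant({"p": [1, 1, 1, 1, 1e6, 1e6, 1e6, 1e6]})
        assert summarize_stress_intensity(q, "p") == pytest.approx(6.0)

    def test_median_of_two_detected_logs(self):
        q = make_quant({"p": [1, 1, 1, 1, 1e5, None, 1e7, None]})
        assert summarize_stress_intensity(q, "p") == pytest.approx(6.0)

    def test_all_stress_missing_is_missing(self):
        q = make_quant({"p": [1, 1, 1, 1, None, None, None, None]})
        assert math.isnan(summarize_stress_intensity(q, "p"))

    def test_unknown_protein_raises(self, quant_table):
        with pytest.raises(KeyError):
            summarize_stress_intensity(quant_table, "nope")


# --- differential testing and labels -----------------------------------------


class TestBuildTrainingSet:
    def test_identical_intensities_labeled_false_with_p_one(self):
        q = make_quant({"flat": [1e6] * 8, "up": [1e5] * 4 + [1e7] * 4})
        training, diff = build_training_set(q)
        flat = next(d for d in diff if d.protein_id == "flat")
        assert flat.p_value == 1.0
        assert next(t for t in training if t.protein_id == "flat").label == FALSE_INTERACTOR
        # zero variance, different means: degenerate p = 0
        up = next(d for d in diff if d.protein_id == "up")
        assert up.p_value == 0.0

    def test_control_missing_protein_excluded_but_scored(self):
        q = make_quant(
            {
                "a": [1e6] * 8,
                "b": [2e6] * 8,
                "stress_only": [None, None, None, None, 1e6, 1e6, 1e6, 1e6],
            }
        )
        training, _ = build_training_set(q)
        assert {t.protein_id for t in training} == {"a", "b"}
        model = fit_error_model([(5.0, 0.8), (7.0, 0.2)])
        records = assign_pscores(model, q, training)
        rec = next(r for r in records if r.protein_id == "stress_only")
        assert not rec.in_training_set
        assert not math.isnan(rec.p_score)

    def test_too_few_quantified_proteins_raise(self):
        q = make_quant({"only": [1e6] * 8, "gone": [None] * 4 + [1e6] * 4})
        with pytest.raises(InsufficientDataError):
            build_training_set(q)

    def test_simulated_labels_match_brute_force_oracle(self):
        """Welch+BH labels agree exactly with an independent textbook
        reimplementation; nulls rarely, planted mostly, labeled true."""
        cfg = SimConfig(
            n_background=100,
            n_true=20,
            log2_enrichment=3.0,
            replicate_sigma_log10=0.2,
            missing_midpoint_log10=-10.0,  # no dropout in this check
            include_bait=False,
            seed=20260921,
        )
        q, truth = simulate_coip(cfg)
        training, diff = build_training_set(q)

        # oracle recomputation from the raw table
        p_oracle = {}
        up_oracle = {}
        for pid in q.protein_ids:
            a = np.log10(q.values_for(pid, "control"))
            b = np.log10(q.values_for(pid, "stress"))
            t, p = welch_oracle(a, b)
            p_oracle[pid] = p
            up_oracle[pid] = b.mean() > a.mean()
        ids = [d.protein_id for d in diff]
        q_oracle = dict(zip(ids, bh_oracle([p_oracle[i] for i in ids])))
        for d in diff:
            assert d.p_value == pytest.approx(p_oracle[d.protein_id], abs=1e-12)
            assert d.q_value == pytest.approx(q_oracle[d.protein_id], abs=1e-12)
        labels = {t.protein_id: t.label for t in training}
        for pid in ids:
            expected = (
                TRUE_INTERACTOR
                if q_oracle[pid] <= 0.05 and up_oracle[pid]
                else FALSE_INTERACTOR
            )
            assert labels[pid] == expected

        planted = set(truth.planted())
        n_true_planted = sum(labels[p] == TRUE_INTERACTOR for p in planted)
        n_true_null = sum(
            labels[p] == TRUE_INTERACTOR for p in labels if p not in planted
        )
        assert n_true_planted >= 14  # noncentrality ~6.4 supports >= 0.7 power
        assert n_true_null <= 5


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), [1, 1, 1])
        np.testing.assert_allclose(benjamini_hochberg([0.04]), [0.04])
        assert benjamini_hochberg([]).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)


def test_welch_agrees_with_oracle_on_random_inputs():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 10))
        b = rng.normal(loc=rng.normal(), size=rng.integers(2, 10))
        t, p = welch_test(a, b)
        t_ref, p_ref = welch_oracle(a, b)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


# --- binning ------------------------------------------------------------------


def entries(labels_and_x):
    return [
        TrainingEntry(protein_id=f"p{i:03d}", label=lab, stress_summary=x)
        for i, (lab, x) in enumerate(labels_and_x)
    ]


class TestBinTrainingSet:
    def test_error_fraction_is_false_over_total(self):
        ts = entries(
            [(FALSE_INTERACTOR, 1.0)] * 3
            + [(TRUE_INTERACTOR, 1.1)]
            + [(TRUE_INTERACTOR, 5.0)] * 4
        )
        anchors = bin_training_set(ts, n_bins=2)
        assert anchors[0][1] == pytest.approx(0.75)
        assert anchors[1][1] == 0.0  # a bin of only true interactors

    def test_equal_count_contract(self):
        ts = entries([(FALSE_INTERACTOR, float(i)) for i in range(20)])
        anchors = bin_training_set(ts, n_bins=10)
        assert len(anchors) == 10
        # 2 members per bin: anchor x is the mean of two consecutive values
        np.testing.assert_allclose([a[0] for a in anchors], np.arange(0.5, 20, 2))

    def test_parameter_validation(self):
        ts = entries([(FALSE_INTERACTOR, float(i)) for i in range(5)])
        with pytest.raises(ParameterError):
            bin_training_set(ts, n_bins=1)
        with pytest.raises(InsufficientDataError):
            bin_training_set(ts, n_bins=6)

    def test_ties_broken_by_protein_id(self):
        ts = entries([(FALSE_INTERACTOR, 1.0), (TRUE_INTERACTOR, 1.0)] * 2)
        a1 = bin_training_set(ts, n_bins=2)
        a2 = bin_training_set(list(reversed(ts)), n_bins=2)
        assert a1 == a2  # deterministic under input order permutation


# --- p-scores and calling -----------------------------------------------------


class TestAssignAndCall:
    def test_anchor_exact_and_clamped_pscores(self):
        model = fit_error_model([(5.0, 0.9), (6.0, 0.5), (7.0, 0.1)])
        q = make_quant(
            {
                "at_anchor": [1e6] * 4 + [1e6] * 4,
                "above": [1e6] * 4 + [1e9] * 4,
                "never_in_stress": [1e6] * 4 + [None] * 4,
            }
        )
        training, _ = build_training_set(q)
        records = {r.protein_id: r for r in assign_pscores(model, q, training)}
        assert records["at_anchor"].p_score == pytest.approx(0.5)
        assert records["above"].p_score == pytest.approx(0.1)  # clamped to last anchor
        assert math.isnan(records["never_in_stress"].p_score)
        assert not records["never_in_stress"].called
        assert len(records) == len(q.protein_ids)

    def test_call_interactors_sorting_and_missing(self):
        recs = [
            PScoreRecord("b", 7.0, 0.01, True, True, TRUE_INTERACTOR),
            PScoreRecord("a", 7.0, 0.01, True, True, TRUE_INTERACTOR),
            PScoreRecord("c", 6.0, 0.04, True, False, None),
            PScoreRecord("d", 5.0, 0.5, False, True, FALSE_INTERACTOR),
            PScoreRecord("e", float("nan"), float("nan"), False, False, None),
        ]
        assert call_interactors(recs, threshold=0.05) == ["a", "b", "c"]
        assert call_interactors(recs, threshold=0.001) == []

    def test_planted_rank_below_null_pscores(self):
        """On enriched simulations planted proteins get systematically lower
        p-scores than background (one-sided rank-sum direction check)."""
        cfg = SimConfig(
            n_background=100, n_true=20, log2_enrichment=3.0,
            replicate_sigma_log10=0.2, seed=20260921,
        )
        q, truth = simulate_coip(cfg)
        training, _ = build_training_set(q)
        model = fit_error_model(bin_training_set(training, n_bins=10))
        records = assign_pscores(model, q, training)
        planted = set(truth.planted())
        ps_planted = [r.p_score for r in records if r.protein_id in planted and not math.isnan(r.p_score)]
        ps_null = [r.p_score for r in records if r.protein_id not in planted and not math.isnan(r.p_score)]
        stat = stats.mannwhitneyu(ps_planted, ps_null, alternative="less")
        assert stat.pvalue < 1e-3
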