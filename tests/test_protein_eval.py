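import numpy as np
import pytest

from gofunc.ontology import ICTable, propagate
from gofunc.predictors import ScoreTable, hierarchy_normalize
from gofunc.protein_eval import aupr, evaluate, fmax, smin, term_centric_auc
from gofunc.synthetic import gen_annotations, gen_ontology

from conftest import table
from oracles import oracle_aupr, oracle_fmax, oracle_smin, random_instance


def score_table(scores):
    return ScoreTable(scores={p: dict(row) for p, row in scores.items()})


class TestFmax:
    def test_perfect_predictions(self):
        truth = table({"p1": {"t1", "t2"}, "p2": {"t2"}}, propagated=True)
        preds = score_table({"p1": {"t1": 1.0, "t2": 1.0}, "p2": {"t2": 1.0}})
        value, _ = fmax(preds, truth)
        assert value == pytest.approx(1.0)

    def test_two_threshold_hand_case(self):
        truth = table({"p1": {"t1"}}, propagated=True)
        preds = score_table({"p1": {"t1": 0.9, "t2": 0.4}})
        value, tau = fmax(preds, truth)
        assert value == pytest.approx(1.0)
        assert 0.4 < tau <= 0.9

    def test_ties_resolve_to_smallest_threshold(self):
        truth = table({"p1": {"t1"}}, propagated=True)
        preds = score_table({"p1": {"t1": 1.0}})
        _, tau = fmax(preds, truth)
        assert tau == pytest.approx(0.01)

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            fmax(score_table({}), table({}, propagated=True))


class TestSmin:
    def test_perfect_predictions_zero(self):
        truth = table({"p1": {"t1"}}, propagated=True)
        preds = score_table({"p1": {"t1": 1.0}})
        ic = ICTable(ic={"t1": 3.0})
        assert smin(preds, truth, ic) == pytest.approx(0.0)

    def test_single_missed_term(self):
        truth = table({"p1": {"t1"}}, propagated=True)
        preds = score_table({"p1": {}})
        ic = ICTable(ic={"t1": 2.0})
        assert smin(preds, truth, ic) == pytest.approx(2.0)

    def test_missing_ic_raises(self):
        truth = table({"p1": {"t1"}}, propagated=True)
        with pytest.raises(ValueError):
            smin(score_table({"p1": {"t1": 1.0}}), truth, ICTable(ic={}))


class TestAupr:
    def test_perfect_separation(self):
        truth = table({"p1": {"t1"}, "p2": {"t2"}}, propagated=True)
        preds = score_table({"p1": {"t1": 0.9, "t2": 0.1}, "p2": {"t2": 0.8, "t1": 0.2}})
        assert aupr(preds, truth) == pytest.approx(1.0)

    def test_flat_scores_give_prevalence(self):
        truth = table({"p1": {"t1"}, "p2": {"t1"}}, propagated=True)
        preds = score_table({"p1": {"t1": 0.5, "t2": 0.5}, "p2": {"t1": 0.5, "t2": 0.5}})
        # universe 2 proteins x 2 terms, 2 positives -> prevalence 0.5
        assert aupr(preds, truth) == pytest.approx(0.5)

    def test_no_positive_pair_raises(self):
        with pytest.raises(ValueError):
            aupr(score_table({"p1": {"t1": 0.3}}), table({}, propagated=True))


class TestTermCentricAuc:
    def test_perfectly_ranked_terms(self):
        truth = table({"p1": {"t1"}, "p2": {"t2"}, "p3": {"t2"}}, propagated=True)
        preds = score_table(
            {"p1": {"t1": 0.9, "t2": 0.1}, "p2": {"t2": 0.8}, "p3": {"t2": 0.7}}
        )
        assert term_centric_auc(preds, truth) == pytest.approx(1.0)

    def test_single_term_rank_count(self):
        truth = table({"p1": {"t1"}, "p2": set(), "p3": set()}, propagated=True)
        # p2/p3 have no truth term; give them a second universe term to keep them
        truth.records["p2"] = {"t2"}
        truth.records["p3"] = {"t2"}
        preds = score_table({"p1": {"t1": 0.9}, "p2": {"t1": 0.1}, "p3": {"t1": 0.2}})
        # t1: positive 0.9 above negatives 0.1, 0.2 -> AUC 1; t2 ranks 0 scores
        # below? t2 scores all zero -> ties -> AUC 0.5
        assert term_centric_auc(preds, truth) == pytest.approx((1.0 + 0.5) / 2)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        truth = table(
            {f"p{i}": {"t1"} if rng.random() < 0.5 else {"t2"} for i in range(n)},
            propagated=True,
        )
        preds = score_table(
            {f"p{i}": {"t1": float(rng.random()), "t2": float(rng.random())}
             for i in range(n)}
        )
        assert term_centric_auc(preds, truth) == pytest.approx(0.5, abs=0.08)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_fmax_smin_aupr_match_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n_p = int(rng.integers(3, 50))
        n_t = int(rng.integers(3, 30))
        preds, truth = random_instance(rng, n_p, n_t)
        truth_table = table(truth, propagated=True)
        pred_table = score_table(preds)
        ic = ICTable(ic={f"t{j}": float(rng.uniform(0.1, 5.0)) for j in range(n_t)})

        f_impl, _ = fmax(pred_table, truth_table, exact=True)
        assert f_impl == pytest.approx(oracle_fmax(preds, truth), abs=1e-9)
        s_impl = smin(pred_table, truth_table, ic, exact=True)
        assert s_impl == pytest.approx(oracle_smin(preds, truth, ic.ic), abs=1e-9)
        a_impl = aupr(pred_table, truth_table)
        assert a_impl == pytest.approx(oracle_aupr(preds, truth), abs=1e-9)


class TestEvaluate:
    def test_perfect_predictor_report(self):
        g = gen_ontology(25, seed=0)
        truth = gen_annotations(g, n_proteins=10, seed=1)
        preds = score_table({p: {t: 1.0 for t in ts} for p, ts in truth.records.items()})
        from gofunc.ontology import information_content

        ic = information_content(g, truth)
        report = evaluate(preds, truth, g, ic)
        assert report.fmax == pytest.approx(1.0)
        assert report.smin == pytest.approx(0.0)
        assert report.aupr == pytest.approx(1.0)
        assert report.mean_auc == pytest.approx(1.0)

    def test_report_matches_component_metrics(self):
        g = gen_ontology(25, seed=3)
        truth = gen_annotations(g, n_proteins=12, seed=4)
        rng = np.random.default_rng(5)
        preds = score_table(
            {p: {t: float(rng.random()) for t in ts} for p, ts in truth.records.items()}
        )
        from gofunc.ontology import information_content

        ic = information_content(g, truth)
        report = evaluate(preds, truth, g, ic)
        assert report.fmax == pytest.approx(fmax(preds, truth, g)[0])
        assert report.smin == pytest.approx(smin(preds, truth, ic, g))
        assert report.aupr == pytest.approx(aupr(preds, truth, g))
        assert report.mean_auc == pytest.approx(term_centric_auc(preds, truth, g))

    def test_empty_predictions_fixed_point(self):
        truth = table({"p1": {"t1"}, "p2": {"t1", "t2"}}, propagated=True)
        ic = ICTable(ic={"t1": 1.0, "t2": 2.0})
        report = evaluate(ScoreTable(scores={}), truth, None, ic)
        assert report.fmax == 0.0
        # full remaining uncertainty: mean of (1.0, 3.0)
        assert report.smin == pytest.approx(2.0)


class TestMetricProperties:
    def test_degradation_flipping_correct_score_to_zero(self):
        rng = np.random.default_rng(9)
        preds, truth = random_instance(rng, 15, 10)
        truth_table = table(truth, propagated=True)
        base_f, _ = fmax(score_table(preds), truth_table, exact=True)
        base_a = aupr(score_table(preds), truth_table)
        # zero out one correctly predicted high score
        for p, row in preds.items():
            hit = [t for t, s in row.items() if t in truth[p] and s > 0.5]
            if hit:
                row[hit[0]] = 0.0
                break
        worse_f, _ = fmax(score_table(preds), truth_table, exact=True)
        worse_a = aupr(score_table(preds), truth_table)
        assert worse_f <= base_f + 1e-9
        assert worse_a <= base_a + 1e-9

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        preds, truth = random_instance(rng, 10, 8)
        f0, _ = fmax(score_table(preds), table(truth, propagated=True), exact=True)
        remap_p = {p: f"X{p}" for p in truth}
        remap_t = {f"t{j}": f"Y{j}" for j in range(8)}
        preds2 = {remap_p[p]: {remap_t[t]: s for t, s in row.items()}
                  for p, row in preds.items()}
        truth2 = {remap_p[p]: {remap_t[t] for t in ts} for p, ts in truth.items()}
        f1, _ = fmax(score_table(preds2), table(truth2, propagated=True), exact=True)
        assert f0 == pytest.approx(f1, abs=1e-12)

    def test_hierarchy_normalization_never_reduces_recall(self):
        g = gen_ontology(20, seed=6)
        truth = gen_annotations(g, n_proteins=8, seed=7)
        rng = np.random.default_rng(8)
        preds = score_table(
            {p: {t: float(rng.random()) for t in ts if rng.random() < 0.8}
             for p, ts in truth.records.items()}
        )
        normed = hierarchy_normalize(preds, g)
        for tau in np.arange(0.05, 1.0, 0.1):
            for p, ts in truth.records.items():
                raw = {t for t, s in preds.scores.get(p, {}).items() if s >= tau}
                nrm = {t for t, s in normed.scores.get(p, {}).items() if s >= tau}
                assert len(nrm & ts) >= len(raw & ts)
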