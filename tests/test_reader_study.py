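"""Reader study: trial building, blinding, rate arithmetic, guessing null."""

import os

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histosr import reader_study as rs


def make_pairs(n, category="UT", start=0):
    return [rs.CandidatePair(f"img_{start + i}_x.png", "hr",
                             f"img_{start + i}_y.png", "rhr", category)
            for i in range(n)]


def result_from_counts(counts_by_key):
    res = rs.StudyResult()
    for key, kw in counts_by_key.items():
        res.counts[key] = rs.Counts(**kw)
    return res


# Counts from the published two-tumor reader study (uterine leiomyosarcoma
# and adult granulosa cell tumor, two raters) used as worked examples.
TABLE_COUNTS = {
    ("A", "UT"): dict(correct=97, incorrect=103,
                      authenticity_marked_different=41, authenticity_total=1000,
                      confident=951, confidence_total=1000),
    ("A", "AGCT"): dict(correct=110, incorrect=90,
                        authenticity_marked_different=12, authenticity_total=1000,
                        confident=988, confidence_total=1000),
    ("B", "UT"): dict(correct=105, incorrect=95,
                      authenticity_marked_different=25, authenticity_total=1000,
                      confident=977, confidence_total=1000),
    ("B", "AGCT"): dict(correct=112, incorrect=88,
                        authenticity_marked_different=86, authenticity_total=1000,
                        confident=925, confidence_total=1000),
}


class TestBuildTrials:
    def test_balanced_keys_and_count(self):
        ts = rs.build_trials(make_pairs(200), seed=0)
        assert len(ts.trials) == 200
        assert sum(t.key == "a" for t in ts.trials) == 100

    def test_deterministic_per_seed(self):
        a = rs.build_trials(make_pairs(50), seed=3)
        b = rs.build_trials(make_pairs(50), seed=3)
        assert a.trials == b.trials

    def test_balanced_within_each_category(self):
        pairs = make_pairs(21, "UT") + make_pairs(33, "AGCT", start=100)
        ts = rs.build_trials(pairs, seed=1)
        for cat in ("UT", "AGCT"):
            keys = [t.key for t in ts.trials if t.category == cat]
            assert abs(keys.count("a") - keys.count("b")) <= 1

    def test_pair_with_two_hr_arms_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            rs.CandidatePair("a.png", "hr", "b.png", "hr", "UT")

    def test_emitted_package_is_blinded(self, tmp_path):
        import imageio.v3 as iio

        img_dir = tmp_path / "imgs"
        os.makedirs(img_dir)
        pairs = []
        for i in range(4):
            hp = str(img_dir / f"hr_method_{i}.png")
            rp = str(img_dir / f"rhr_method_{i}.png")
            for path in (hp, rp):
                iio.imwrite(path, np.zeros((4, 4, 3), np.uint8))
            pairs.append(rs.CandidatePair(hp, "hr", rp, "rhr", "UT"))
        ts = rs.build_trials(pairs, seed=0)
        pres = rs.emit_trial_package(ts, str(tmp_path / "study"))
        for name in os.listdir(pres):
            assert "hr" not in name.lower().replace("rhr", "")
            assert "rhr" not in name.lower()
        sheet = open(os.path.join(pres, "answer_sheet.tsv")).read()
        assert "hr" not in sheet and "rhr" not in sheet


@pytest.fixture(scope="module")
def table():
    return result_from_counts(TABLE_COUNTS)


class TestRates:
    def test_forced_choice_accuracy_per_category(self, table):
        assert rs.accuracy_rate(table, "A", "UT") == pytest.approx(48.5)
        assert rs.accuracy_rate(table, "A", "AGCT") == pytest.approx(55.0)
        assert rs.accuracy_rate(table, "B", "UT") == pytest.approx(52.5)
        assert rs.accuracy_rate(table, "B", "AGCT") == pytest.approx(56.0)

    def test_accuracy_average_is_mean_of_category_percentages(self, table):
        assert rs.accuracy_rate_average(table, "A") == pytest.approx(51.75)
        assert rs.accuracy_rate_average(table, "B") == pytest.approx(54.25)

    def test_authenticity_rates_and_averages(self, table):
        assert rs.authenticity_rate(table, "A", "UT") == pytest.approx(95.9)
        assert rs.authenticity_rate(table, "A", "AGCT") == pytest.approx(98.8)
        assert rs.authenticity_rate_average(table, "A") == pytest.approx(97.35)
        assert rs.authenticity_rate_average(table, "B") == pytest.approx(94.45)

    def test_confidence_rates_and_averages(self, table):
        assert rs.confidence_rate(table, "A", "UT") == pytest.approx(95.1)
        assert rs.confidence_rate_average(table, "A") == pytest.approx(96.95)
        assert rs.confidence_rate_average(table, "B") == pytest.approx(95.1)

    def test_all_correct_and_all_confident_limits(self):
        res = result_from_counts({("R", "C"): dict(
            correct=10, incorrect=0, authenticity_marked_different=0,
            authenticity_total=10, confident=10, confidence_total=10)})
        assert rs.accuracy_rate(res, "R", "C") == 100.0
        assert rs.authenticity_rate(res, "R", "C") == 100.0
        assert rs.confidence_rate(res, "R", "C") == 100.0

    def test_zero_totals_rejected(self):
        res = result_from_counts({("R", "C"): dict()})
        for fn in (rs.accuracy_rate, rs.authenticity_rate, rs.confidence_rate):
            with pytest.raises(ValueError):
                fn(res, "R", "C")

    @given(correct=st.integers(0, 500), incorrect=st.integers(0, 500),
           confident=st.integers(0, 500), extra=st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_rates_match_direct_ratio_oracle(self, correct, incorrect, confident, extra):
        total = confident + extra
        res = result_from_counts({("R", "C"): dict(
            correct=correct, incorrect=incorrect,
            confident=confident, confidence_total=total)})
        if correct + incorrect:
            assert rs.accuracy_rate(res, "R", "C") == pytest.approx(
                100.0 * correct / (correct + incorrect))
        if total:
            assert rs.confidence_rate(res, "R", "C") == pytest.approx(
                100.0 * confident / total)

    def test_scoring_invariant_to_trial_order(self):
        pairs = make_pairs(20, "UT") + make_pairs(20, "AGCT", start=50)
        ts = rs.build_trials(pairs, seed=2)
        rng = np.random.default_rng(0)
        answers = {t.trial_id: {"chosen_arm": rng.choice(["a", "b"])}
                   for t in ts.trials}
        direct = rs.score_answers(ts, answers, "R")
        shuffled = rs.TrialSet(trials=[ts.trials[i]
                                       for i in rng.permutation(len(ts.trials))],
                               seed=ts.seed)
        perm = rs.score_answers(shuffled, answers, "R")
        for cat in ("UT", "AGCT"):
            assert rs.accuracy_rate(direct, "R", cat) == rs.accuracy_rate(perm, "R", cat)


class TestNullDistribution:
    def test_observed_rates_consistent_with_guessing(self):
        nd = rs.null_distribution(200, n_reps=100_000, seed=0)
        assert nd.exceedance_p(51.75) > 0.05
        assert nd.exceedance_p(54.25) > 0.05

    def test_perfect_accuracy_inconsistent_with_guessing(self):
        nd = rs.null_distribution(200, n_reps=100_000, seed=0)
        assert nd.exceedance_p(100.0) < 1e-4

    def test_concentrates_at_half_for_large_n(self):
        nd = rs.null_distribution(100_000, n_reps=2_000, seed=1)
        lo, hi = nd.central_interval(0.95)
        assert 49.5 < lo < hi < 50.5

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            rs.null_distribution(0)
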