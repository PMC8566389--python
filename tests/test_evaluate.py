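"""Evaluation layer: printed-table replication and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from glioprog.evaluate import (
    ConfusionMatrix, binary_metrics, clopper_pearson,
    confusion_from_predictions, evaluation_report, mcnemar_test,
    nir_binomial_test, roc_auc,
)

# the four published 2x2 tables (PD positive): tp, fn, fp, tn
PUBLISHED = {
    "mri": ((54, 3, 10, 7), (0.82, 0.95, 0.41)),
    "pet": ((46, 11, 3, 14), (0.81, 0.81, 0.82)),
    "rf": ((52, 5, 5, 12), (0.86, 0.91, 0.71)),
    "expert": ((51, 6, 8, 9), (0.81, 0.89, 0.53)),
}


@pytest.mark.parametrize("name", list(PUBLISHED))
def test_binary_metrics_reproduce_published_tables(name):
    counts, (acc, sens, spec) = PUBLISHED[name]
    m = binary_metrics(ConfusionMatrix(*counts))
    assert round(m["accuracy"], 2) == acc
    assert round(m["sensitivity"], 2) == sens
    assert round(m["specificity"], 2) == spec


def test_degenerate_class_reports_missing_not_zero():
    m = binary_metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
    assert np.isnan(m["sensitivity"])
    assert m["specificity"] == 1.0
    assert m["accuracy"] == 1.0


def test_confusion_cutoff_and_tie_rule():
    cm = confusion_from_predictions([1.0, 1.0, 1.0], ["PD"] * 3)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 0, 0, 0)
    # a probability exactly at the cutoff is called TRC
    cm = confusion_from_predictions([0.5], ["PD"])
    assert (cm.tp, cm.fn) == (0, 1)


def test_confusion_matches_brute_force_tally(rng):
    probs = rng.random(10)
    labels = rng.choice(["PD", "TRC"], 10)
    cm = confusion_from_predictions(probs, labels, cutoff=0.5)
    tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for p, lab in zip(probs, labels):
        pred_pd = p > 0.5
        if lab == "PD":
            tally["tp" if pred_pd else "fn"] += 1
        else:
            tally["fp" if pred_pd else "tn"] += 1
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == tuple(tally.values())
    with pytest.raises(ValueError, match="length"):
        confusion_from_predictions([0.1], ["PD", "TRC"])


def test_clopper_pearson_reproduces_published_intervals():
    lo, hi = clopper_pearson(64, 74)          # published accuracy CI
    assert (round(lo, 2), round(hi, 2)) == (0.77, 0.93)
    lo, hi = clopper_pearson(12, 17)          # published specificity CI
    assert (round(lo, 2), round(hi, 2)) == (0.44, 0.90)


def test_clopper_pearson_boundaries_and_validation():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0
    with pytest.raises(ValueError):
        clopper_pearson(5, 10, level=1.5)
    with pytest.raises(ValueError):
        clopper_pearson(11, 10)


def test_ci_contains_point_estimate_and_shrinks_with_n():
    widths = []
    for n in (20, 80, 320):
        x = int(0.75 * n)
        lo, hi = clopper_pearson(x, n)
        assert lo <= x / n <= hi
        widths.append(hi - lo)
    assert widths == sorted(widths, reverse=True)


def test_nir_binomial_test_published_value():
    nir = 57 / 74
    assert round(nir, 2) == 0.77
    p = nir_binomial_test(64, 74, nir)
    assert round(p, 2) == 0.03


def test_nir_binomial_matches_direct_pmf_summation():
    # brute-force tail: P(X >= 8 | n=10, p=0.5)
    expected = sum(sps.binom.pmf(k, 10, 0.5) for k in (8, 9, 10))
    assert nir_binomial_test(8, 10, 0.5) == pytest.approx(expected, rel=1e-12)
    assert nir_binomial_test(0, 10, 0.3) == pytest.approx(1.0)


def test_mcnemar_exact_closed_forms():
    # equal discordance -> p = 1
    a = np.array([True] * 3 + [False] * 3 + [True] * 4)
    b = np.array([False] * 3 + [True] * 3 + [True] * 4)
    assert mcnemar_test(a, b) == pytest.approx(1.0)
    # one-sided discordance b=6, c=0 -> p = 2 * (1/2)^6
    a = np.array([True] * 6 + [True] * 4)
    b = np.array([False] * 6 + [True] * 4)
    assert mcnemar_test(a, b) == pytest.approx(2 * 0.5 ** 6)
    # no discordance at all
    assert mcnemar_test([True, False], [True, False]) == 1.0


def test_mcnemar_matches_binomial_tail_oracle(rng):
    a = rng.random(40) < 0.7
    b = rng.random(40) < 0.6
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    n = n01 + n10
    # two-sided exact binomial: sum of pmf values not exceeding pmf(n01)
    pmf = sps.binom.pmf(np.arange(n + 1), n, 0.5)
    expected = pmf[pmf <= pmf[n01] * (1 + 1e-12)].sum()
    assert mcnemar_test(a, b) == pytest.approx(min(1.0, expected), rel=1e-9)


def test_roc_auc_extremes_and_pair_counting_oracle(rng):
    auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], ["PD", "PD", "TRC", "TRC"])
    assert auc == 1.0
    # large-sample null: labels independent of probabilities
    probs = rng.random(4000)
    labels = np.where(rng.random(4000) < 0.5, "PD", "TRC")
    auc, _ = roc_auc(probs, labels)
    assert auc == pytest.approx(0.5, abs=0.03)
    # 8-case toy set vs all-pairs concordance count
    probs = np.array([0.9, 0.6, 0.6, 0.4, 0.35, 0.3, 0.2, 0.6])
    labels = np.array(["PD", "PD", "TRC", "PD", "TRC", "TRC", "TRC", "PD"])
    pos = probs[labels == "PD"]
    neg = probs[labels == "TRC"]
    pairs = sum(1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg)
    auc, curve = roc_auc(probs, labels)
    assert auc == pytest.approx(pairs / (len(pos) * len(neg)), rel=1e-12)
    assert curve.shape[1] == 3
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["PD", "PD"])


def test_auc_invariant_under_strictly_monotone_transform(rng):
    probs = rng.random(60)
    labels = np.where(rng.random(60) < 0.4, "PD", "TRC")
    a1, _ = roc_auc(probs, labels)
    a2, _ = roc_auc(1 / (1 + np.exp(-7 * probs)), labels)
    assert a1 == pytest.approx(a2, rel=1e-12)


def test_evaluation_report_composes_all_pieces():
    cm = ConfusionMatrix(52, 5, 5, 12)
    rep = evaluation_report(cm, nir=57 / 74)
    assert round(rep.accuracy, 2) == 0.86
    assert rep.accuracy_ci[0] <= rep.accuracy <= rep.accuracy_ci[1]
    assert rep.sensitivity_ci[0] <= rep.sensitivity <= rep.sensitivity_ci[1]
    assert round(rep.nir_p_one_sided, 2) == 0.03
    d = rep.to_dict()
    assert d["confusion"] == {"tp": 52, "fn": 5, "fp": 5, "tn": 12}
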