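"""Agreement statistics against independent oracles.

The weighted-kappa implementation is checked cell-by-cell against a
brute-force double summation, and unweighted/linear/quadratic kappa are
cross-checked against scikit-learn's independent implementation on label
pairs.
"""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from smokereg.agreement import (
    ContingencyTable,
    WeightScheme,
    cohens_kappa,
    collapse_table,
    concordance,
    kappa_ci,
    pearson_correlation,
    restrict_table,
    screening_metrics,
)


def brute_force_kappa(counts: np.ndarray, q: int | None) -> float:
    """Oracle: explicit double sums over cells, no vectorization."""
    k = counts.shape[0]
    n = counts.sum()
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            if q is None:
                w = 1.0 if i == j else 0.0
            else:
                w = 1.0 - (abs(i - j) / (k - 1)) ** q
            po += w * counts[i, j] / n
            pe += w * (counts[i, :].sum() / n) * (counts[:, j].sum() / n)
    return (po - pe) / (1.0 - pe)


def _labels(k):
    return tuple(f"c{i}" for i in range(k))


def _random_table(rng, k):
    counts = rng.integers(0, 30, size=(k, k)).astype(float)
    counts[0, 0] += 1  # avoid empty tables
    return ContingencyTable(_labels(k), _labels(k), counts)


@pytest.mark.parametrize(
    "scheme,q",
    [(WeightScheme.NONE, None), (WeightScheme.LINEAR, 1), (WeightScheme.QUADRATIC, 2)],
)
def test_kappa_matches_brute_force_oracle(scheme, q):
    rng = np.random.default_rng(20160401)
    for _ in range(200):
        k = int(rng.integers(3, 6))
        t = _random_table(rng, k)
        got = cohens_kappa(t, scheme).statistic
        assert got == pytest.approx(brute_force_kappa(t.counts, q), abs=1e-12)


def test_kappa_cross_checked_against_sklearn():
    rng = np.random.default_rng(5)
    for weights, scheme in [(None, WeightScheme.NONE), ("linear", WeightScheme.LINEAR),
                            ("quadratic", WeightScheme.QUADRATIC)]:
        y1 = rng.integers(0, 4, size=300)
        y2 = rng.integers(0, 4, size=300)
        pairs = [(f"c{a}", f"c{b}") for a, b in zip(y1, y2)]
        t = ContingencyTable.from_pairs(pairs, _labels(4), _labels(4))
        ours = cohens_kappa(t, scheme).statistic
        theirs = cohen_kappa_score(y1, y2, weights=weights)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_all_schemes_coincide_on_two_by_two_tables():
    rng = np.random.default_rng(11)
    for _ in range(100):
        t = _random_table(rng, 2)
        if t.counts.sum(0).min() == 0 or t.counts.sum(1).min() == 0:
            continue
        vals = {s: cohens_kappa(t, s).statistic for s in WeightScheme}
        assert vals[WeightScheme.NONE] == pytest.approx(vals[WeightScheme.LINEAR], abs=1e-12)
        assert vals[WeightScheme.NONE] == pytest.approx(vals[WeightScheme.QUADRATIC], abs=1e-12)


def test_kappa_limits():
    diag = ContingencyTable(_labels(3), _labels(3), np.diag([5, 7, 9]).astype(float))
    for scheme in WeightScheme:
        assert cohens_kappa(diag, scheme).statistic == pytest.approx(1.0)
    # counts equal to the outer product of the marginals → chance agreement
    r = np.array([10.0, 20.0, 30.0])
    c = np.array([6.0, 12.0, 18.0])
    indep = ContingencyTable(_labels(3), _labels(3), np.outer(r, c) / 36.0)
    assert cohens_kappa(indep).statistic == pytest.approx(0.0, abs=1e-12)


def test_degenerate_marginals_rejected():
    t = ContingencyTable(_labels(2), _labels(2), np.array([[10.0, 0.0], [0.0, 0.0]]))
    with pytest.raises(ValueError):
        cohens_kappa(t)


def test_concordance():
    diag = ContingencyTable(_labels(3), _labels(3), np.diag([5, 7, 9]).astype(float))
    assert concordance(diag).statistic == 1.0
    with pytest.raises(ValueError):
        concordance(ContingencyTable(_labels(2), _labels(2), np.zeros((2, 2))))


def test_collapse_conserves_counts_and_rejects_overlap():
    rng = np.random.default_rng(3)
    t = _random_table(rng, 4)
    groups = {"a": ("c0", "c1"), "b": ("c2", "c3")}
    collapsed = collapse_table(t, groups, groups)
    assert collapsed.n == t.n
    identity = {l: (l,) for l in t.row_labels}
    assert (collapse_table(t, identity, identity).counts == t.counts).all()
    with pytest.raises(ValueError):
        collapse_table(t, {"a": ("c0", "c1"), "b": ("c1", "c2")}, identity)
    one = collapse_table(t, {"all": t.row_labels}, {"all": t.col_labels})
    assert concordance(one).statistic == 1.0


def test_restrict_drops_unlisted_labels():
    rng = np.random.default_rng(4)
    t = _random_table(rng, 4)
    r = restrict_table(t, ("c0", "c1"))
    assert r.n == t.counts[:2, :2].sum()


def test_screening_metrics():
    t = ContingencyTable(
        ("eligible", "not_eligible"), ("eligible", "not_eligible"),
        np.array([[41.0, 24.0], [7.0, 124.0]]),
    )
    m = screening_metrics(t)
    assert m.ppv == pytest.approx(41 / 48)
    assert m.npv == pytest.approx(124 / 148)
    assert m.sensitivity == pytest.approx(41 / 65)
    assert m.specificity == pytest.approx(124 / 131)
    assert m.sensitivity * (m.tp + m.fn) == pytest.approx(m.tp)

    perfect = ContingencyTable(
        ("eligible", "not_eligible"), ("eligible", "not_eligible"),
        np.array([[10.0, 0.0], [0.0, 20.0]]),
    )
    pm = screening_metrics(perfect)
    assert (pm.ppv, pm.npv, pm.sensitivity, pm.specificity) == (1.0, 1.0, 1.0, 1.0)

    no_pos = ContingencyTable(
        ("eligible", "not_eligible"), ("eligible", "not_eligible"),
        np.array([[0.0, 5.0], [0.0, 20.0]]),
    )
    assert screening_metrics(no_pos).ppv is None


def test_pearson_correlation():
    line = [(x, x) for x in range(5)]
    assert pearson_correlation(line) == pytest.approx(1.0)
    anti = [(x, -2 * x) for x in range(5)]
    assert pearson_correlation(anti) == pytest.approx(-1.0)
    assert pearson_correlation([(1, 2), (2, 1), (3, 3)]) == pytest.approx(0.5)
    assert pearson_correlation([(1, 1), (1, 2), (1, 3)]) is None
    with pytest.raises(ValueError):
        pearson_correlation([(1, 1)])


def test_kappa_ci_contains_estimate_and_shrinks():
    rng = np.random.default_rng(9)
    t = _random_table(rng, 3)
    res = cohens_kappa(t, WeightScheme.QUADRATIC)
    lo, hi = kappa_ci(t, res)
    assert lo <= res.statistic <= hi
    big = ContingencyTable(_labels(3), _labels(3), np.diag([1e6, 1e6, 1e6]).astype(float))
    res_big = cohens_kappa(big)
    lo_b, hi_b = kappa_ci(big, res_big)
    assert hi_b - lo_b < 1e-2
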