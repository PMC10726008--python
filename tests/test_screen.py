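import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from maldisub.markers import marker_counts
from maldisub.screen import biomarker_table, feature_auc, fisher_exact, heatmap_matrix, pca_scores
from tests.conftest import make_feature_matrix


def fisher_oracle(a, b, c, d):
    """Independent exact-rational enumeration of the two-sided Fisher p."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def table_prob(x):  # hypergeometric mass as an exact Fraction
        from fractions import Fraction

        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    total = sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs)
    return float(total)


def auc_oracle(values, labels):
    """O(n^2) pair counting: P(pos > neg) + 0.5 P(tie)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    s = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return s / (len(pos) * len(neg))


def test_fisher_balanced_table_is_one():
    assert fisher_exact(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)


def test_fisher_small_table_enumeration():
    # margins (3,3)/(2,4): three possible tables, two at or below the observed mass
    assert fisher_exact(2, 1, 0, 3) == pytest.approx(0.4, abs=1e-12)


def test_fisher_published_counts_highly_significant():
    # peak 2,929: 46/59 longum vs 3/41 infantis
    assert fisher_exact(46, 13, 3, 38) < 0.001


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError, match="c"):
        fisher_exact(1, 2, -1, 3)


def test_fisher_matches_exhaustive_oracle_for_all_small_tables():
    for n in range(0, 21):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    p = fisher_exact(a, b, c, d)
                    assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.integers(0, 30)] * 4))
def test_fisher_agrees_with_scipy(table):
    a, b, c, d = table
    ours = fisher_exact(a, b, c, d)
    theirs = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    assert ours == pytest.approx(theirs, abs=1e-9)


def test_feature_auc_perfect_and_constant():
    assert feature_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert feature_auc([3, 3, 3, 3], [0, 0, 1, 1]) == 0.5


def test_feature_auc_half_tie_example():
    # pos {2,3}, neg {1,2}: (1 + 0.5 + 1 + 1) / 4
    assert feature_auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)


def test_feature_auc_single_class_rejected():
    with pytest.raises(ValueError):
        feature_auc([1, 2], [1, 1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_feature_auc_matches_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 50))
    labels = np.zeros(n, int)
    labels[: n // 2] = 1
    values = rng.integers(0, 6, n).astype(float)  # ties likely
    assert feature_auc(values, labels) == pytest.approx(auc_oracle(values, labels), abs=1e-9)


def test_biomarker_table_counts_and_internal_consistency():
    rng = np.random.default_rng(3)
    presence = rng.random((20, 6)) < 0.5
    presence[:, 5] = 0  # one peak absent everywhere
    labels = np.array([0] * 12 + [1] * 8)
    fm = make_feature_matrix(presence.astype(int), labels, replicates=2)
    bt = biomarker_table(fm)
    assert len(bt) == 6
    for row in bt.itertuples():
        assert row.freq_longum == row.n_longum_present / row.n_longum_total
        assert row.fisher_p == pytest.approx(
            fisher_exact(
                row.n_longum_present,
                row.n_longum_total - row.n_longum_present,
                row.n_infantis_present,
                row.n_infantis_total - row.n_infantis_present,
            ),
            abs=1e-12,
        )
    empty = bt.iloc[5]
    assert empty.fisher_p == 1.0
    assert empty.specific_to == "none"
    assert empty.auc == 0.5


def test_biomarker_specificity_calls():
    presence = np.zeros((10, 2), int)
    presence[5:, 0] = 1  # peak 0 exclusive to infantis
    presence[:5, 1] = 1  # peak 1 exclusive to longum
    labels = np.array([0] * 5 + [1] * 5)
    bt = biomarker_table(make_feature_matrix(presence, labels))
    assert bt.iloc[0].specific_to == "infantis"
    assert bt.iloc[1].specific_to == "longum"


def test_pca_scores_centering_and_ordering():
    rng = np.random.default_rng(5)
    rel = rng.random((12, 5))
    rel[1] = rel[0]  # two strains with identical fingerprints
    presence = (rel > 0.2).astype(int)
    rel = rel * presence
    fm = make_feature_matrix(presence, [0] * 6 + [1] * 6, rel_intensity=rel)
    scores, evr = pca_scores(fm)
    np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)
    assert evr[0] >= evr[1]
    np.testing.assert_allclose(scores.iloc[0], scores.iloc[1], atol=1e-9)


def test_pca_needs_three_strains():
    fm = make_feature_matrix(np.eye(2, 3, dtype=int), [0, 1])
    with pytest.raises(ValueError):
        pca_scores(fm)


def test_heatmap_keeps_half_the_peaks_and_stays_binary():
    rng = np.random.default_rng(8)
    presence = (rng.random((30, 18)) < 0.4).astype(int)
    labels = np.array([0] * 18 + [1] * 12)
    fm = make_feature_matrix(presence, labels)
    bt = biomarker_table(fm)
    heat = heatmap_matrix(bt, fm)
    assert heat.shape == (30, 9)  # 18 peaks -> 9 columns
    assert set(np.unique(heat.to_numpy())) <= {0, 1}
    # permuting strain order changes nothing about the set of output rows
    perm = rng.permutation(30)
    fm2 = make_feature_matrix(presence[perm], labels[perm])
    heat2 = heatmap_matrix(biomarker_table(fm2), fm2)
    rows1 = {tuple(r) for r in heat.to_numpy()}
    rows2 = {tuple(r) for r in heat2.to_numpy()}
    assert rows1 == rows2


def test_published_marker_counts_all_significant():
    # every one of the 18 published 2x2 tables is significant at 0.05;
    # the five RFE-selected ones are far below 0.001
    selected = {2929, 4408, 5381, 5394, 8817}
    for mz, k_lon, a_lon, k_inf, a_inf in marker_counts():
        p = fisher_exact(k_lon, a_lon, k_inf, a_inf)
        if mz in selected:
            assert p < 0.001
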