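"""Tanimoto coefficient, reference ranking and enrichment curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spadkit.similarity import (RankedScreen, SimilarityError,
                                compare_descriptors, enrichment_curve,
                                rank_by_reference, tanimoto)
from spadkit.spad import build_feature_matrix, default_gap_set
from tests.test_spad import BITS, GAPS, V2, Peptide


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 0, 1], [1, 0, 1], 1.0),
        ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
        ([1, 1, 0, 0], [1, 0, 1, 0], 1 / 3),
        ([0, 0], [0, 0], 0.0),
    ],
)
def test_tanimoto_examples(x, y, expected):
    assert tanimoto(np.array(x), np.array(y)) == pytest.approx(expected)


def test_tanimoto_length_mismatch():
    with pytest.raises(SimilarityError):
        tanimoto(np.array([1, 0]), np.array([1, 0, 1]))


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, derandomize=True, max_examples=40)
def test_tanimoto_matches_set_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=30)
    y = rng.integers(0, 2, size=30)
    a, b = set(np.flatnonzero(x)), set(np.flatnonzero(y))
    want = len(a & b) / len(a | b) if a | b else 0.0
    got = tanimoto(x, y)
    assert got == pytest.approx(want)
    assert got == pytest.approx(tanimoto(y, x))  # symmetry
    assert 0.0 <= got <= 1.0


def _matrix(rows, ids, labels):
    """Build a FeatureMatrix-like object from dense binary rows."""
    import scipy.sparse as sp

    from spadkit.spad import FeatureMatrix

    m = sp.csr_matrix(np.array(rows, dtype=np.uint8))
    return FeatureMatrix(matrix=m, peptide_ids=ids, labels=labels,
                         columns=list(range(m.shape[1])))


def test_rank_identical_candidate_first():
    fm = _matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                 ["ref", "same", "other"],
                 ["active_reference", "active", "non_active"])
    rs = rank_by_reference(fm, ["ref"])
    assert rs.entries[0][0] == "same" and rs.entries[0][1] == pytest.approx(1.0)
    assert "ref" not in rs.ids


def test_rank_hand_computed_order():
    # T(ref, a) = 1/3, T(ref, b) = 1/2
    fm = _matrix([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]],
                 ["ref", "a", "b"],
                 ["active_reference", "non_active", "active"])
    rs = rank_by_reference(fm, ["ref"])
    assert rs.ids == ["b", "a"]
    assert rs.scores == pytest.approx([0.5, 1 / 3])


def test_rank_disjoint_candidates_keep_input_order():
    fm = _matrix([[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                 ["ref", "c1", "c2"],
                 ["active_reference", "active", "non_active"])
    rs = rank_by_reference(fm, ["ref"])
    assert rs.ids == ["c1", "c2"]
    assert all(s == 0.0 for s in rs.scores)


def test_rank_requires_references():
    fm = _matrix([[1]], ["a"], ["active"])
    with pytest.raises(SimilarityError):
        rank_by_reference(fm, [])
    with pytest.raises(SimilarityError):
        rank_by_reference(fm, ["missing"])


def test_enrichment_hand_enumeration():
    rs = RankedScreen([("a", 0.9, "active"), ("b", 0.8, "non_active"),
                       ("c", 0.7, "active"), ("d", 0.1, "non_active")])
    curve = enrichment_curve(rs)
    pts = set(zip(curve.x.tolist(), curve.y.tolist()))
    assert (0.25, 0.5) in pts and (0.75, 1.0) in pts
    assert curve.x[0] == 0.0 and curve.y[0] == 0.0
    assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0


def test_enrichment_perfect_separation_closed_form():
    n_active, n_total = 4, 20
    entries = [(f"a{i}", 1.0 - i * 0.01, "active") for i in range(n_active)]
    entries += [(f"n{i}", 0.5 - i * 0.01, "non_active")
                for i in range(n_total - n_active)]
    curve = enrichment_curve(RankedScreen(entries))
    assert curve.auc == pytest.approx(1 - n_active / (2 * n_total))
    assert curve.y_at(n_active / n_total) == pytest.approx(1.0)


def test_enrichment_requires_both_classes():
    with pytest.raises(SimilarityError):
        enrichment_curve(RankedScreen([("a", 1.0, "active")]))


def test_random_permutation_null_auc_centers_on_half():
    rng = np.random.default_rng(7)
    labels = ["active"] * 20 + ["non_active"] * 80
    aucs = []
    for _ in range(200):
        scores = rng.random(100)
        order = np.argsort(-scores)
        rs = RankedScreen([(f"p{i}", float(scores[i]), labels[i]) for i in order])
        aucs.append(enrichment_curve(rs).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_enrichment_invariant_to_id_relabeling():
    entries = [("a", 0.9, "active"), ("b", 0.5, "non_active"), ("c", 0.2, "active")]
    renamed = [(f"x{i}", s, l) for i, (_, s, l) in enumerate(entries)]
    c1 = enrichment_curve(RankedScreen(entries))
    c2 = enrichment_curve(RankedScreen(renamed))
    assert np.array_equal(c1.x, c2.x) and np.array_equal(c1.y, c2.y)
    assert c1.auc == c2.auc


def test_single_reference_reduces_to_pairwise_sort():
    peps = [Peptide("r", ("D", "A")), Peptide("p", ("D", "G", "A")),
            Peptide("q", ("A", "G"))]
    fm = build_feature_matrix(peps, BITS, V2, GAPS)
    rs = rank_by_reference(fm, ["r"])
    ref = fm.to_dense()[0]
    want = sorted(
        [(pid, tanimoto(fm.to_dense()[i], ref)) for i, pid in
         enumerate(fm.peptide_ids) if pid != "r"],
        key=lambda e: -e[1],
    )
    assert [w[0] for w in want] == rs.ids
    assert [w[1] for w in want] == pytest.approx(list(rs.scores))


def test_compare_descriptors_table():
    entries = [("a", 0.9, "active"), ("b", 0.5, "non_active"), ("c", 0.2, "active")]
    c1 = enrichment_curve(RankedScreen(entries))
    df = compare_descriptors([("one", c1), ("two", c1)])
    assert df.iloc[0]["auc"] == df.iloc[1]["auc"]
    with pytest.raises(SimilarityError):
        compare_descriptors([("one", c1)])
    other = enrichment_curve(RankedScreen([(f"z{i}", s, l) for i, (_, s, l)
                                           in enumerate(entries)]))
    with pytest.raises(SimilarityError):
        compare_descriptors([("one", c1), ("two", other)])
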