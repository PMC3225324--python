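"""Gap specs, the pair-feature function and the sparse feature matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spadkit.residues import Peptide
from spadkit.spad import (FeatureIndex, GapSpec, build_feature_matrix,
                          default_gap_set, feature_span_report, spad_feature)
from spadkit.vocabulary import SubstructurePattern, Vocabulary


def toy_vocab(n):
    return Vocabulary([
        SubstructurePattern(pattern_id=f"p{i}", category="substructure", smarts="[C]")
        for i in range(n)
    ])


def toy_bits(v, rows):
    """rows: residue code -> base-pattern bit list; complements derived."""
    nb = len(v.base)
    data = []
    for code, base in rows.items():
        base = np.asarray(base, dtype=np.uint8)
        data.append(np.concatenate([base, 1 - base]))
    return pd.DataFrame(np.array(data), index=list(rows), columns=v.pattern_ids,
                        dtype=np.uint8)


def test_default_gap_set_enumeration():
    specs = default_gap_set(2)
    assert [s.spec_id for s in specs] == ["g0", "g1", "g2", "g0-2"]
    assert specs[-1].allowed_gaps == frozenset({0, 1, 2})
    assert 1 in specs[-1].allowed_gaps  # ranged spec matches a pair at gap 1


def test_default_gap_set_degenerate():
    specs = default_gap_set(0)
    assert len(specs) == 1 and specs[0].allowed_gaps == frozenset({0})


def test_default_gap_set_default_size():
    specs = default_gap_set(8)
    assert len(specs) == 12  # 9 exact + {0-2}, {0-4}, {0-8}


def test_gap_spec_validation():
    with pytest.raises(ValueError):
        GapSpec("empty", frozenset())
    with pytest.raises(ValueError):
        default_gap_set(-1)


# toy setting: D carries a donor-like pattern, A an aromatic-like one
V2 = toy_vocab(2)
BITS = toy_bits(V2, {"D": [1, 0], "G": [0, 0], "A": [0, 1]})
GAPS = default_gap_set(2)
I_DON, I_ARO = 0, 1
K_G1 = next(k for k, s in enumerate(GAPS) if s.allowed_gaps == frozenset({1}))
K_R02 = next(k for k, s in enumerate(GAPS) if s.allowed_gaps == frozenset({0, 1, 2}))


def test_pair_feature_is_directional():
    p = Peptide("t", ("D", "G", "A"))
    assert spad_feature(p, BITS, FeatureIndex(I_DON, K_G1, I_ARO), GAPS) == 1
    assert spad_feature(p, BITS, FeatureIndex(I_ARO, K_G1, I_DON), GAPS) == 0


def test_pair_feature_ranged_gap():
    p = Peptide("t", ("D", "G", "A"))
    assert spad_feature(p, BITS, FeatureIndex(I_DON, K_R02, I_ARO), GAPS) == 1


def test_pair_feature_needs_two_positions():
    p = Peptide("t", ("D",))
    for k in range(len(GAPS)):
        assert spad_feature(p, BITS, FeatureIndex(I_DON, k, I_DON), GAPS) == 0


def brute_force_triples(seq, bits, gaps):
    """Independent oracle: enumerate firing triples from occurrences."""
    fires = [set(np.flatnonzero(bits.loc[code].to_numpy())) for code in seq]
    out = set()
    for q1 in range(len(seq)):
        for q2 in range(q1 + 1, len(seq)):
            gap = q2 - q1 - 1
            for k, spec in enumerate(gaps):
                if gap not in spec.allowed_gaps:
                    continue
                for i in fires[q1]:
                    for j in fires[q2]:
                        out.add((i, k, j))
    return out


def test_matrix_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    v = toy_vocab(3)
    codes = list("abcde")
    bits = toy_bits(v, {c: rng.integers(0, 2, size=3).tolist() for c in codes})
    gaps = default_gap_set(3)
    peps = [
        Peptide(f"r{i}", tuple(rng.choice(codes, size=rng.integers(1, 9))))
        for i in range(60)
    ]
    fm = build_feature_matrix(peps, bits, v, gaps)
    for r, p in enumerate(peps):
        got = {fm.columns[c] for c in fm.matrix.getrow(r).indices}
        want = {FeatureIndex(*t) for t in brute_force_triples(p.sequence, bits, gaps)}
        assert got == want
        # and per-triple evaluation agrees
        for t in list(want)[:5]:
            assert spad_feature(p, bits, t, gaps) == 1


@given(st.lists(st.sampled_from(["D", "G", "A"]), min_size=2, max_size=8),
       st.integers(0, 2))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_gap_superset_monotonicity(seq, g):
    p = Peptide("h", tuple(seq))
    narrow = [GapSpec.exact(g)]
    wide = [GapSpec.ranged(0, 4)]
    f1 = spad_feature(p, BITS, FeatureIndex(I_DON, 0, I_ARO), narrow)
    f2 = spad_feature(p, BITS, FeatureIndex(I_DON, 0, I_ARO), wide)
    assert f1 <= f2


@given(st.lists(st.sampled_from(["D", "G", "A"]), min_size=2, max_size=6),
       st.sampled_from(["D", "G", "A"]))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_extension_never_clears_feature(seq, extra):
    base = Peptide("h", tuple(seq))
    longer = Peptide("h2", tuple(seq) + (extra,))
    for k in range(len(GAPS)):
        for i in (I_DON, I_ARO):
            for j in (I_DON, I_ARO):
                fi = FeatureIndex(i, k, j)
                assert spad_feature(base, BITS, fi, GAPS) <= spad_feature(longer, BITS, fi, GAPS)


def test_matrix_determinism_and_duplicates():
    peps = [Peptide("a", ("D", "G", "A")), Peptide("b", ("D", "G", "A")),
            Peptide("c", ("A", "D"))]
    fm1 = build_feature_matrix(peps, BITS, V2, GAPS)
    fm2 = build_feature_matrix(peps, BITS, V2, GAPS)
    assert (fm1.matrix != fm2.matrix).nnz == 0
    assert fm1.columns == fm2.columns
    d = fm1.to_dense()
    assert (d[0] == d[1]).all()  # duplicated peptide, duplicated row


def test_matrix_rejects_empty_input():
    with pytest.raises(ValueError):
        build_feature_matrix([], BITS, V2, GAPS)


def test_matrix_column_order_canonical():
    peps = [Peptide("a", ("D", "A")), Peptide("b", ("A", "D", "G"))]
    fm = build_feature_matrix(peps, BITS, V2, GAPS)
    assert fm.columns == sorted(fm.columns)


def test_unordered_merges_mirror_triples():
    peps = [Peptide("a", ("D", "G", "A"))]
    fm = build_feature_matrix(peps, BITS, V2, GAPS, unordered=True)
    for c in fm.columns:
        assert c.i <= c.j


def test_feature_span_report_ranks_planted_triple():
    rng = np.random.default_rng(3)
    codes = list("abcdD_A".replace("_", "x"))
    v = toy_vocab(2)
    rows = {c: [0, 0] for c in "abcdx"}
    rows["D"] = [1, 0]
    rows["A"] = [0, 1]
    bits = toy_bits(v, rows)
    gaps = default_gap_set(3)
    peps = []
    for i in range(30):
        seq = list(rng.choice(list("abcdx"), size=6))
        seq[1], seq[3] = "D", "A"  # gap 1 motif
        peps.append(Peptide(f"act{i}", tuple(seq), label="active"))
    for i in range(60):
        peps.append(Peptide(f"neg{i}", tuple(rng.choice(codes, size=6)),
                            label="non_active"))
    fm = build_feature_matrix(peps, bits, v, gaps)
    report = feature_span_report(fm)
    assert report.iloc[0]["feature"] == "p0|g1|p1"


def test_feature_span_values():
    assert GapSpec.ranged(0, 4).span == 6
    assert GapSpec.exact(0).span == 2


def test_span_report_flags_constant_labels():
    peps = [Peptide("a", ("D", "A"), label="active"),
            Peptide("b", ("A", "D"), label="active")]
    fm = build_feature_matrix(peps, BITS, V2, GAPS)
    report = feature_span_report(fm)
    assert report["phi"].isna().all()
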