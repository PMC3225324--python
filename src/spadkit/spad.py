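"""The substructure-pair descriptor: gap specs, feature function, matrix.

A pair feature is a triple (x_i, y_k, x_j): two patterns from the combined
vocabulary X and an *intermediate binding* y_k — the set of allowed counts
of residues lying strictly between the residue carrying x_i and the
residue carrying x_j. The feature fires on a peptide when some N→C ordered
position pair (q1 < q2) has x_i firing on residue(q1), x_j on residue(q2),
and q2 − q1 − 1 in the allowed gap set. Pairs are directional by default
(N-side pattern first); an ``unordered`` switch merges mirror triples.

The dataset-level matrix (peptides × observed triples) is built by boolean
matrix products over the per-position bit rows, which is exactly the
existential double loop vectorized; columns are kept in canonical
lexicographic (i, k, j) order and only triples observed at least once are
stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .residues import Peptide
from .vocabulary import Vocabulary, feature_activity_correlation

__all__ = [
    "GapSpec",
    "FeatureIndex",
    "FeatureMatrix",
    "default_gap_set",
    "spad_feature",
    "build_feature_matrix",
    "feature_span_report",
]

MAX_GAP_LIMIT = 32


@dataclass(frozen=True)
class GapSpec:
    """One intermediate binding: allowed residue counts between the pair."""

    spec_id: str
    allowed_gaps: frozenset[int]

    def __post_init__(self):
        if not self.allowed_gaps:
            raise ValueError(f"gap spec {self.spec_id!r}: empty gap set")
        if min(self.allowed_gaps) < 0:
            raise ValueError(f"gap spec {self.spec_id!r}: negative gap")
        if max(self.allowed_gaps) > MAX_GAP_LIMIT:
            raise ValueError(f"gap spec {self.spec_id!r}: gap exceeds {MAX_GAP_LIMIT}")

    @classmethod
    def exact(cls, g: int) -> "GapSpec":
        return cls(spec_id=f"g{g}", allowed_gaps=frozenset({g}))

    @classmethod
    def ranged(cls, lo: int, hi: int) -> "GapSpec":
        return cls(spec_id=f"g{lo}-{hi}", allowed_gaps=frozenset(range(lo, hi + 1)))

    @property
    def span(self) -> int:
        """Spatial extent in residues: the two endpoints plus the widest gap."""
        return max(self.allowed_gaps) + 2


class FeatureIndex(NamedTuple):
    """Column address: N-side pattern i, gap spec k, C-side pattern j."""

    i: int
    k: int
    j: int


def default_gap_set(max_gap: int = 8) -> list[GapSpec]:
    """Exact gaps 0..max_gap plus the ranged specs {0–2}, {0–4}, {0–max_gap}.

    Ranged specs wider than ``max_gap`` are omitted and duplicates (by gap
    set) removed, so ``max_gap=0`` degenerates to the single spec {0}.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    specs = [GapSpec.exact(g) for g in range(max_gap + 1)]
    for hi in (2, 4, max_gap):
        if hi <= max_gap:
            specs.append(GapSpec.ranged(0, hi))
    seen: set[frozenset[int]] = set()
    out = []
    for s in specs:
        if s.allowed_gaps not in seen:
            seen.add(s.allowed_gaps)
            out.append(s)
    return out


def spad_feature(
    peptide: Peptide,
    bits: pd.DataFrame,
    fi: FeatureIndex,
    gaps: Sequence[GapSpec],
) -> int:
    """Evaluate one pair feature on one peptide (0 or 1).

    ``bits`` is the residue bit table; ``fi`` addresses columns of that
    table and an entry of ``gaps``.
    """
    spec = gaps[fi.k]
    pair_cols = bits.iloc[:, [fi.i, fi.j]].to_numpy()
    rows = [pair_cols[bits.index.get_loc(code)] for code in peptide.sequence]
    length = len(peptide)
    for q1 in range(length - 1):
        if not rows[q1][0]:
            continue
        for q2 in range(q1 + 1, length):
            if rows[q2][1] and (q2 - q1 - 1) in spec.allowed_gaps:
                return 1
    return 0


@dataclass
class FeatureMatrix:
    """Sparse binary peptides × observed-triples matrix.

    ``columns`` holds the FeatureIndex (or other descriptor key) of each
    stored column, in canonical order; ``pattern_ids`` and ``gap_specs``
    let a FeatureIndex be decoded back to names.
    """

    matrix: sp.csr_matrix
    peptide_ids: list[str]
    labels: list[str]
    columns: list
    pattern_ids: list[str] = field(default_factory=list)
    gap_specs: list[GapSpec] = field(default_factory=list)
    kind: str = "spad"

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense(), dtype=np.uint8)

    def row(self, peptide_id: str) -> np.ndarray:
        idx = self.peptide_ids.index(peptide_id)
        return np.asarray(self.matrix.getrow(idx).todense()).ravel().astype(np.uint8)

    def column_label(self, col: int) -> str:
        key = self.columns[col]
        if isinstance(key, FeatureIndex):
            return "|".join([
                self.pattern_ids[key.i],
                self.gap_specs[key.k].spec_id,
                self.pattern_ids[key.j],
            ])
        return "|".join(str(part) for part in key)

    def save(self, path: str | Path) -> None:
        """Write MatrixMarket plus a sidecar TSV of column labels."""
        path = Path(path)
        from scipy.io import mmwrite

        mmwrite(str(path), self.matrix.astype(np.uint8))
        with open(path.with_suffix(".columns.tsv"), "w", encoding="utf-8") as fh:
            fh.write("column\tlabel\n")
            for c in range(len(self.columns)):
                fh.write(f"{c}\t{self.column_label(c)}\n")
        with open(path.with_suffix(".rows.tsv"), "w", encoding="utf-8") as fh:
            fh.write("row\tpeptide_id\tlabel\n")
            for r, (pid, lab) in enumerate(zip(self.peptide_ids, self.labels)):
                fh.write(f"{r}\t{pid}\t{lab}\n")


def _peptide_pair_tensor(
    B: np.ndarray, gaps: Sequence[GapSpec]
) -> np.ndarray:
    """Existence tensor of shape (N, M, N): does (x_i, y_k, x_j) fire?

    ``B`` is the length × N per-position bit matrix of one peptide.
    """
    length, n_pat = B.shape
    tensor = np.zeros((n_pat, len(gaps), n_pat), dtype=bool)
    # pairwise existence per exact gap, shared across gap specs
    per_gap: dict[int, np.ndarray] = {}
    for g in range(length - 1):
        per_gap[g] = (B[: length - 1 - g].T @ B[1 + g:]) > 0
    for k, spec in enumerate(gaps):
        acc = None
        for g in spec.allowed_gaps:
            if g in per_gap:
                acc = per_gap[g] if acc is None else (acc | per_gap[g])
        if acc is not None:
            tensor[:, k, :] = acc
    return tensor


def build_feature_matrix(
    peptides: Sequence[Peptide],
    bits: pd.DataFrame,
    vocabulary: Vocabulary,
    gaps: Sequence[GapSpec] | None = None,
    unordered: bool = False,
) -> FeatureMatrix:
    """Evaluate every pair feature on every peptide.

    Stores only triples observed at least once across the dataset, in
    canonical lexicographic (i, k, j) order. With ``unordered=True`` a
    mirror triple (j, k, i) is ORed into its canonical partner (i ≤ j).
    """
    if len(peptides) == 0:
        raise ValueError("no peptides given")
    if gaps is None:
        gaps = default_gap_set()
    pattern_ids = vocabulary.pattern_ids
    if list(bits.columns) != pattern_ids:
        raise ValueError("bit-table columns do not match the vocabulary")

    n_pat, n_gap = len(pattern_ids), len(gaps)
    row_lookup = {code: r for r, code in enumerate(bits.index)}
    table = bits.to_numpy().astype(np.uint8)

    flat_rows: list[np.ndarray] = []
    for p in peptides:
        try:
            B = table[[row_lookup[c] for c in p.sequence]]
        except KeyError as exc:
            raise ValueError(f"peptide {p.id!r}: residue {exc} missing from bit table") from None
        tensor = _peptide_pair_tensor(B, gaps)
        if unordered:
            tensor = tensor | tensor.transpose(2, 1, 0)
            iu = np.tril_indices(n_pat, k=-1)
            tensor[iu[0], :, iu[1]] = False
        flat_rows.append(np.flatnonzero(tensor.reshape(-1)))

    observed = np.unique(np.concatenate(flat_rows)) if flat_rows else np.array([], int)
    indptr = np.zeros(len(peptides) + 1, dtype=np.int64)
    for r, flat in enumerate(flat_rows):
        indptr[r + 1] = indptr[r] + len(flat)
    all_flat = (np.concatenate(flat_rows) if flat_rows
                else np.array([], dtype=np.int64))
    indices = np.searchsorted(observed, all_flat)
    matrix = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.uint8), indices, indptr),
        shape=(len(peptides), len(observed)),
    )
    columns = [
        FeatureIndex(int(f) // (n_gap * n_pat),
                     (int(f) // n_pat) % n_gap,
                     int(f) % n_pat)
        for f in observed
    ]
    return FeatureMatrix(
        matrix=matrix,
        peptide_ids=[p.id for p in peptides],
        labels=[p.label for p in peptides],
        columns=columns,
        pattern_ids=pattern_ids,
        gap_specs=list(gaps),
    )


def feature_span_report(fm: FeatureMatrix, labels: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-triple activity correlation (phi) and spatial span in residues.

    ``labels`` defaults to the matrix's own labels with ``active`` and
    ``active_reference`` as the positive class. Sorted by |phi| descending
    with the canonical column order as tie-break; undefined phi (constant
    column or constant labels) is reported as NaN and sorts last.
    """
    if labels is None:
        labels = [int(l in ("active", "active_reference")) for l in fm.labels]
    y = np.asarray(labels, dtype=np.float64)
    if y.shape[0] != fm.shape[0]:
        raise ValueError("label vector length does not match the matrix")
    X = fm.to_dense().astype(np.float64)
    n = y.shape[0]
    n1 = y.sum()
    s = X.sum(axis=0)
    tp = y @ X
    denom = n1 * (n - n1) * s * (n - s)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n * tp - s * n1) / np.sqrt(denom), np.nan)
    spans = [fm.gap_specs[c.k].span if isinstance(c, FeatureIndex) else np.nan
             for c in fm.columns]
    report = pd.DataFrame(
        {
            "column": np.arange(len(fm.columns)),
            "feature": [fm.column_label(c) for c in range(len(fm.columns))],
            "phi": phi,
            "span_residues": spans,
        }
    )
    order = np.lexsort((report["column"].to_numpy(),
                        -np.nan_to_num(np.abs(phi), nan=-1.0)))
    return report.iloc[order].reset_index(drop=True)
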