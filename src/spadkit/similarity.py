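"""Tanimoto similarity screening and enrichment-factor curves.

Candidates are scored against a set of active-reference fingerprints by
the binary Tanimoto coefficient T(X, Y) = Σ x_k y_k / Σ max(x_k, y_k),
aggregated over references (max by default), and ranked descending. The
enrichment curve sweeps the similarity threshold α over the observed
scores and plots, per threshold, the fraction of the screened library
retrieved (x) against the fraction of active peptides retrieved (y); a
random ordering gives the diagonal in expectation, perfect early
retrieval hugs the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spad import FeatureMatrix

__all__ = [
    "RankedScreen",
    "EnrichmentCurve",
    "tanimoto",
    "rank_by_reference",
    "enrichment_curve",
    "compare_descriptors",
    "plot_curves",
]


class SimilarityError(ValueError):
    pass


def tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """Binary Tanimoto coefficient; two all-zero vectors score 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise SimilarityError("tanimoto requires two equal-length 1-D vectors")
    xb = x != 0
    yb = y != 0
    union = int(np.sum(xb | yb))
    if union == 0:
        return 0.0
    return int(np.sum(xb & yb)) / union


@dataclass
class RankedScreen:
    """Similarity ranking of non-reference peptides, best first.

    ``entries`` rows are (peptide_id, score, label); ties keep input
    order. Reference peptides never appear.
    """

    entries: list[tuple[str, float, str]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [e[2] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["peptide_id", "score", "label"])
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def save(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def rank_by_reference(
    fm: FeatureMatrix,
    references: Iterable[str],
    aggregate: str = "max",
) -> RankedScreen:
    """Score every non-reference peptide against the reference set.

    Each candidate takes its max (or mean) Tanimoto coefficient over the
    references and candidates are sorted descending with a stable
    tie-break on input order.
    """
    ref_ids = list(dict.fromkeys(references))
    if not ref_ids:
        raise SimilarityError("reference set is empty")
    missing = [r for r in ref_ids if r not in fm.peptide_ids]
    if missing:
        raise SimilarityError(f"reference ids not in matrix: {missing}")
    if aggregate not in ("max", "mean"):
        raise SimilarityError("aggregate must be 'max' or 'mean'")

    ref_rows = [fm.peptide_ids.index(r) for r in ref_ids]
    cand_rows = [r for r in range(fm.shape[0]) if r not in set(ref_rows)]

    X = fm.to_dense().astype(np.float32)
    R = X[ref_rows]
    C = X[cand_rows]
    inter = C @ R.T                                   # |A ∩ B|
    sizes_c = C.sum(axis=1, keepdims=True)
    sizes_r = R.sum(axis=1, keepdims=True).T
    union = sizes_c + sizes_r - inter                 # |A ∪ B|
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(union > 0, inter / union, 0.0)
    scores = T.max(axis=1) if aggregate == "max" else T.mean(axis=1)

    order = np.argsort(-scores, kind="stable")
    entries = [
        (fm.peptide_ids[cand_rows[r]], float(scores[r]), fm.labels[cand_rows[r]])
        for r in order
    ]
    return RankedScreen(entries=entries)


@dataclass
class EnrichmentCurve:
    """Threshold-swept retrieval curve with trapezoidal AUC.

    x: fraction of ranked peptides with score ≥ α;
    y: fraction of active peptides with score ≥ α;
    swept over the distinct observed scores, closed at (0,0) and (1,1).
    """

    x: np.ndarray
    y: np.ndarray
    auc: float
    n_total: int
    n_active: int
    peptide_ids: tuple[str, ...]

    def y_at(self, x_frac: float) -> float:
        """Interpolated fraction of actives retrieved at a library fraction."""
        return float(np.interp(x_frac, self.x, self.y))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction_screened": self.x,
                             "fraction_actives": self.y})

    def save(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# auc\t{self.auc:.10g}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def enrichment_curve(rs: RankedScreen) -> EnrichmentCurve:
    """Build the enrichment curve of a ranked screen.

    Requires at least one active and one non-active entry; peptides with
    other labels count in the library denominator but not as actives.
    """
    labels = rs.labels
    n_total = len(labels)
    n_active = sum(1 for l in labels if l == "active")
    n_non = sum(1 for l in labels if l == "non_active")
    if n_active == 0:
        raise SimilarityError("ranked screen contains no active peptides")
    if n_non == 0:
        raise SimilarityError("ranked screen contains no non-active peptides")

    scores = rs.scores
    active = np.array([l == "active" for l in labels])
    xs = [0.0]
    ys = [0.0]
    for alpha in sorted(set(scores.tolist()), reverse=True):
        hit = scores >= alpha
        xs.append(float(hit.sum()) / n_total)
        ys.append(float((hit & active).sum()) / n_active)
    if xs[-1] != 1.0 or ys[-1] != 1.0:
        xs.append(1.0)
        ys.append(1.0)
    x = np.array(xs)
    y = np.array(ys)
    auc = float(np.trapezoid(y, x))
    return EnrichmentCurve(x=x, y=y, auc=auc, n_total=n_total,
                           n_active=n_active, peptide_ids=tuple(rs.ids))


def compare_descriptors(
    curves: Sequence[tuple[str, EnrichmentCurve]],
    early_fractions: Sequence[float] = (0.05, 0.10, 0.25),
) -> pd.DataFrame:
    """Side-by-side AUC and early-retrieval table for ≥ 2 curves.

    All curves must come from the same peptide set; no winner is declared
    beyond the numbers.
    """
    if len(curves) < 2:
        raise SimilarityError("need at least two curves to compare")
    ref_set = frozenset(curves[0][1].peptide_ids)
    for name, c in curves[1:]:
        if frozenset(c.peptide_ids) != ref_set:
            raise SimilarityError(f"curve {name!r} ranks a different peptide set")
    rows = []
    for name, c in curves:
        row = {"descriptor": name, "auc": c.auc}
        for f in early_fractions:
            row[f"actives_at_{int(round(f * 100))}pct"] = c.y_at(f)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_curves(
    curves: Sequence[tuple[str, EnrichmentCurve]],
    path: str | Path,
) -> None:
    """Write an enrichment plot (PNG/SVG by extension) with the diagonal null."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves:
        ax.plot(c.x, c.y, marker=".", label=f"{name} (AUC={c.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random")
    ax.set_xlabel("fraction of library screened")
    ax.set_ylabel("fraction of actives retrieved")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
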