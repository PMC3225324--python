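"""Base substructure vocabulary, residue bit tables and feature screening.

The vocabulary holds an ordered base set Z of substructure patterns; every
base pattern z has a derived complement z* that fires exactly when z does
not (z ∩ z* = ∅, z ∪ z* = everything), and the combined set X = Z ∪ Z* is
what the pair descriptor draws from. Patterns come in three categories:

``atom_count``
    a per-residue count of one atom class (Cl, F, N, O, C, aromatic C, S,
    aromatic N, or "other") binarized by a threshold (count ≥ t);
``substructure``
    a SMARTS presence/absence pattern;
``property``
    a relational SMARTS pattern joining two chemotypes through linker
    atoms (e.g. a methylene and a hydrogen-bond acceptor connected via
    any atom).

Screening implements two statistical retention conditions on the residue
library: drop low-entropy (too specific, or too generic) columns, then
drop the lower-entropy member of any strongly redundant column pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .residues import Residue, ResidueLibrary

__all__ = [
    "ATOM_CLASSES",
    "SubstructurePattern",
    "Vocabulary",
    "load_vocabulary",
    "default_vocabulary",
    "save_vocabulary",
    "match_residue",
    "residue_bit_table",
    "column_entropy",
    "screen_vocabulary",
    "feature_activity_correlation",
]

# the nine atom-count classes; "other" collects every heavy atom that falls
# in none of the eight named classes
ATOM_CLASSES = ("Cl", "F", "N", "O", "C", "C_aromatic", "S", "N_aromatic", "other")

CATEGORIES = ("atom_count", "substructure", "property")


class VocabularyError(ValueError):
    pass


@dataclass(frozen=True)
class SubstructurePattern:
    """One base pattern z, or the derived complement z* of a base pattern."""

    pattern_id: str
    category: str
    smarts: str | None = None
    atom_class: str | None = None
    threshold: int | None = None
    description: str = ""
    is_complement: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise VocabularyError(
                f"pattern {self.pattern_id!r}: unknown category {self.category!r}")
        if self.category == "atom_count":
            if self.atom_class not in ATOM_CLASSES:
                raise VocabularyError(
                    f"pattern {self.pattern_id!r}: atom_class must be one of {ATOM_CLASSES}")
            if self.threshold is None or self.threshold < 1:
                raise VocabularyError(
                    f"pattern {self.pattern_id!r}: atom_count threshold must be >= 1")
        else:
            if not self.smarts:
                raise VocabularyError(f"pattern {self.pattern_id!r}: missing SMARTS")
            if Chem.MolFromSmarts(self.smarts) is None:
                raise VocabularyError(
                    f"pattern {self.pattern_id!r}: invalid SMARTS {self.smarts!r}")

    @property
    def query(self) -> Chem.Mol | None:
        if self.smarts is None:
            return None
        return Chem.MolFromSmarts(self.smarts)

    def complement(self) -> "SubstructurePattern":
        if self.is_complement:
            raise VocabularyError("cannot derive the complement of a complement")
        return replace(self, pattern_id=self.pattern_id + "*", is_complement=True,
                       description=f"complement of {self.pattern_id}")


class Vocabulary:
    """Ordered base set Z with derived complements; combined set X = Z ∪ Z*."""

    def __init__(self, base: Iterable[SubstructurePattern]):
        self.base: list[SubstructurePattern] = list(base)
        if not self.base:
            raise VocabularyError("vocabulary has no base patterns")
        if any(p.is_complement for p in self.base):
            raise VocabularyError("base patterns must not be complements")
        ids = [p.pattern_id for p in self.base]
        if len(set(ids)) != len(ids):
            raise VocabularyError("duplicate pattern ids in vocabulary")
        self.combined: list[SubstructurePattern] = (
            self.base + [p.complement() for p in self.base])

    def __len__(self) -> int:
        return len(self.combined)

    @property
    def size(self) -> int:
        """N = |X| = 2·|Z|."""
        return len(self.combined)

    @property
    def pattern_ids(self) -> list[str]:
        return [p.pattern_id for p in self.combined]

    def index_of(self, pattern_id: str) -> int:
        for i, p in enumerate(self.combined):
            if p.pattern_id == pattern_id:
                return i
        raise KeyError(f"pattern {pattern_id!r} not in vocabulary")

    def subset(self, base_ids: Iterable[str]) -> "Vocabulary":
        keep = set(base_ids)
        return Vocabulary([p for p in self.base if p.pattern_id in keep])


def _pattern_from_entry(entry: dict) -> SubstructurePattern:
    return SubstructurePattern(
        pattern_id=str(entry["id"]),
        category=str(entry["category"]),
        smarts=entry.get("smarts"),
        atom_class=entry.get("atom_class"),
        threshold=entry.get("threshold"),
        description=str(entry.get("description", "")),
    )


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load base patterns from a YAML/JSON file and derive complements."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "patterns" not in doc:
        raise VocabularyError(f"{path}: expected a mapping with a 'patterns' list")
    return Vocabulary(_pattern_from_entry(e) for e in doc["patterns"])


def default_vocabulary() -> Vocabulary:
    """The packaged 49-pattern default base set."""
    ref = resources.files("spadkit.data") / "default_vocabulary.yaml"
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


def save_vocabulary(v: Vocabulary, path: str | Path) -> None:
    entries = []
    for p in v.base:
        entry: dict = {"id": p.pattern_id, "category": p.category}
        if p.category == "atom_count":
            entry["atom_class"] = p.atom_class
            entry["threshold"] = p.threshold
        else:
            entry["smarts"] = p.smarts
        if p.description:
            entry["description"] = p.description
        entries.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"patterns": entries}, fh, sort_keys=False)


def classify_atom(atom: Chem.Atom) -> str:
    """Assign one heavy atom to its atom-count class."""
    sym = atom.GetSymbol()
    if sym == "Cl":
        return "Cl"
    if sym == "F":
        return "F"
    if sym == "C":
        return "C_aromatic" if atom.GetIsAromatic() else "C"
    if sym == "N":
        return "N_aromatic" if atom.GetIsAromatic() else "N"
    if sym == "O":
        return "O"
    if sym == "S":
        return "S"
    return "other"


def atom_class_counts(mol: Chem.Mol) -> dict[str, int]:
    counts = dict.fromkeys(ATOM_CLASSES, 0)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            counts[classify_atom(atom)] += 1
    return counts


def match_residue(residue: Residue, pattern: SubstructurePattern) -> int:
    """Evaluate one pattern on a residue monomer; returns 0 or 1.

    Matching runs on the monomer with its attachment dummies in place,
    i.e. the residue as it sits inside a chain: the backbone nitrogen and
    carbonyl keep their in-chain hydrogen counts, and free-terminus
    artifacts (a carboxylic acid on every residue) never fire. Dummy
    atoms match no element query and are terminal, so they cannot serve
    as linkers in relational patterns. Complement patterns return the
    negation of their base evaluation.
    """
    if pattern.category == "atom_count":
        bit = int(atom_class_counts(residue.mol)[pattern.atom_class]
                  >= pattern.threshold)
    else:
        bit = int(residue.mol.HasSubstructMatch(pattern.query))
    return 1 - bit if pattern.is_complement else bit


def residue_bit_table(library: ResidueLibrary, vocabulary: Vocabulary) -> pd.DataFrame:
    """Residues × combined patterns binary table (uint8 DataFrame).

    Complement columns are exact negations of their base columns, so each
    row sums to |Z|.
    """
    n_base = len(vocabulary.base)
    base_bits = np.zeros((len(library), n_base), dtype=np.uint8)
    queries = [None if p.category == "atom_count" else p.query
               for p in vocabulary.base]
    for i, residue in enumerate(library):
        counts = atom_class_counts(residue.mol)
        for j, pat in enumerate(vocabulary.base):
            if pat.category == "atom_count":
                base_bits[i, j] = counts[pat.atom_class] >= pat.threshold
            else:
                base_bits[i, j] = residue.mol.HasSubstructMatch(queries[j])
    bits = np.hstack([base_bits, 1 - base_bits])
    return pd.DataFrame(bits, index=library.codes, columns=vocabulary.pattern_ids,
                        dtype=np.uint8)


def column_entropy(table: pd.DataFrame, pattern_id: str) -> float:
    """Shannon entropy (bits) of one column's empirical {0,1} distribution."""
    col = table[pattern_id].to_numpy()
    p1 = float(col.mean())
    out = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0.0:
            out -= p * math.log2(p)
    return out


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0  # identical (empty) supports
    return int(np.logical_and(a, b).sum()) / union


def screen_vocabulary(
    table: pd.DataFrame,
    vocabulary: Vocabulary,
    entropy_min: float = 0.08,
    redundancy_max: float = 0.95,
) -> tuple[Vocabulary, pd.DataFrame]:
    """Apply the two statistical retention conditions to the base set.

    First drops base patterns whose residue-column entropy falls below
    ``entropy_min``; then, scanning surviving pairs, drops the
    lower-entropy member of any pair whose supports have Jaccard
    similarity ≥ ``redundancy_max`` (ties drop the later pattern in
    vocabulary order). Complements follow their bases. Returns the
    reduced vocabulary and a per-pattern report of entropy, fate and
    reason.
    """
    if not 0.0 <= redundancy_max <= 1.0:
        raise VocabularyError("redundancy_max must lie in [0, 1]")
    if entropy_min < 0.0:
        raise VocabularyError("entropy_min must be >= 0")

    entropies = {p.pattern_id: column_entropy(table, p.pattern_id)
                 for p in vocabulary.base}
    fate = {p.pattern_id: ("kept", "") for p in vocabulary.base}

    surviving = [p for p in vocabulary.base if entropies[p.pattern_id] >= entropy_min]
    for p in vocabulary.base:
        if entropies[p.pattern_id] < entropy_min:
            fate[p.pattern_id] = ("dropped", "low_entropy")

    cols = {p.pattern_id: table[p.pattern_id].to_numpy().astype(bool)
            for p in surviving}
    dropped: set[str] = set()
    for a_idx in range(len(surviving)):
        pa = surviving[a_idx]
        if pa.pattern_id in dropped:
            continue
        for b_idx in range(a_idx + 1, len(surviving)):
            pb = surviving[b_idx]
            if pb.pattern_id in dropped:
                continue
            if _jaccard(cols[pa.pattern_id], cols[pb.pattern_id]) >= redundancy_max:
                ea, eb = entropies[pa.pattern_id], entropies[pb.pattern_id]
                loser = pb if eb <= ea else pa
                dropped.add(loser.pattern_id)
                fate[loser.pattern_id] = ("dropped", "redundant")
                if loser is pa:
                    break

    kept_ids = [p.pattern_id for p in surviving if p.pattern_id not in dropped]
    report = pd.DataFrame(
        {
            "pattern_id": [p.pattern_id for p in vocabulary.base],
            "category": [p.category for p in vocabulary.base],
            "entropy_bits": [entropies[p.pattern_id] for p in vocabulary.base],
            "fate": [fate[p.pattern_id][0] for p in vocabulary.base],
            "reason": [fate[p.pattern_id][1] for p in vocabulary.base],
        }
    )
    return vocabulary.subset(kept_ids), report


def feature_activity_correlation(bits: np.ndarray, labels: np.ndarray) -> float:
    """Phi (Matthews) coefficient of two binary vectors; NaN if undefined."""
    bits = np.asarray(bits).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if bits.shape != labels.shape or bits.ndim != 1 or bits.size < 2:
        raise VocabularyError("bits and labels must be equal-length 1-D vectors (n >= 2)")
    tp = int(np.sum(bits & labels))
    fp = int(np.sum(bits & ~labels))
    fn = int(np.sum(~bits & labels))
    tn = int(np.sum(~bits & ~labels))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return float("nan")
    return (tp * tn - fp * fn) / math.sqrt(denom)
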