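"""Synthetic residue libraries and planted-motif screening benchmarks.

Real inhibitor screens of non-natural peptides pair a small active family
— sequences sharing a binding motif — with a much larger background of
inactive and random sequences. This generator reproduces that layout so
every stage of the toolkit can be exercised end to end:

* a residue library of the 20 natural monomers plus procedurally
  decorated variants (halogenation, O/N substitutions, ring and chain
  additions on side-chain carbons), up to a configurable size;
* labeled peptide datasets in which every active (with configurable
  penetrance) carries a planted pair motif — a residue matching pattern A
  and a residue matching pattern B placed an exact number of residues
  apart — while negatives are uniform random sequences.

Sizes default to a published C5a-inhibitor screen layout (116 actives,
451 negatives, 450 residue types); everything is deterministic under the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .residues import Peptide, Residue, ResidueLibrary, natural_residue_library
from .vocabulary import Vocabulary, residue_bit_table

__all__ = [
    "GeneratorConfig",
    "generate_residue_library",
    "generate_dataset",
    "assign_references",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic benchmark.

    ``planted_motif`` is (pattern_id_a, gap, pattern_id_b): the motif
    residues sit exactly ``gap`` residues apart, pattern A on the N side.
    ``motif_penetrance`` is the probability an active carries the motif;
    ``decoy_rate`` the probability a negative carries the full motif at
    the true gap; ``match_composition`` additionally gives every negative
    the two motif residues at a clearly wrong spacing (|gap − g| ≥ 2), so
    that residue composition alone carries no signal and only the pair
    geometry separates the classes.
    """

    seed: int = 0
    n_residues: int = 450
    n_active: int = 116
    n_non_active: int = 451
    length_range: tuple[int, int] = (8, 15)
    planted_motif: tuple[str, int, str] = ("guanidine", 3, "imidazole")
    motif_penetrance: float = 1.0
    decoy_rate: float = 0.0
    match_composition: bool = False

    def __post_init__(self):
        if self.n_active < 1 or self.n_non_active < 1:
            raise ValueError("dataset sizes must be >= 1")
        if not (0.0 <= self.motif_penetrance <= 1.0 and 0.0 <= self.decoy_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.planted_motif[1] < 0 or self.planted_motif[1] > hi - 2:
            raise ValueError("planted gap must fit within the maximum length")


# side-chain decoration grammar: fragment SMILES attached by a single bond
# to a CH-bearing side-chain carbon of a base monomer
_DECORATIONS = (
    "F", "Cl", "Br", "C", "CC", "O", "N", "OC", "SC",
    "C(F)(F)F", "C#N", "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C(=O)N", "C(C)C",
)


def _decoration_sites(mol: Chem.Mol) -> list[int]:
    """Side-chain carbons with a substitutable hydrogen.

    Backbone atoms (the attachment dummies, their neighbours, and the
    carbonyl oxygen) are left alone so every variant still assembles.
    """
    backbone: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            backbone.add(atom.GetIdx())
            for nb in atom.GetNeighbors():
                backbone.add(nb.GetIdx())
                for nb2 in nb.GetNeighbors():
                    if nb2.GetSymbol() == "O":
                        backbone.add(nb2.GetIdx())
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIdx() not in backbone
        and a.GetSymbol() == "C"
        and not a.GetIsAromatic()
        and a.GetTotalNumHs() >= 1
    ] + [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIdx() not in backbone
        and a.GetSymbol() == "C"
        and a.GetIsAromatic()
        and a.GetTotalNumHs() >= 1
    ]


def _decorate(mol: Chem.Mol, site: int, fragment: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(fragment)
    if frag is None:
        return None
    offset = mol.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(mol, frag))
    rw.AddBond(site, offset, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_residue_library(cfg: GeneratorConfig) -> ResidueLibrary:
    """The 20 natural monomers plus decorated variants up to ``n_residues``.

    Variants are produced by repeatedly picking a natural monomer, a
    substitutable side-chain carbon and a decoration fragment; duplicates
    (by canonical SMILES) are discarded, so every structure in the
    library is unique. Decoration is single-level — variants are never
    decorated further — which keeps the per-family variant counts (and
    hence the prevalence of each substructure pattern across the
    library) stable across seeds. Deterministic under the seed.
    """
    if cfg.n_residues < 20:
        raise ValueError("n_residues must be at least 20 (the natural monomers)")
    rng = np.random.default_rng(cfg.seed)
    natural = natural_residue_library()
    if cfg.n_residues == 20:
        return natural

    RDLogger.DisableLog("rdApp.*")
    try:
        residues = list(natural)
        seen = {Chem.MolToSmiles(r.mol) for r in residues}
        counter = 0
        attempts = 0
        max_attempts = cfg.n_residues * 200
        while len(residues) < cfg.n_residues:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not generate {cfg.n_residues} unique residues")
            base = residues[int(rng.integers(len(natural)))]
            sites = _decoration_sites(base.mol)
            if not sites:
                continue
            site = sites[int(rng.integers(len(sites)))]
            frag = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
            mol = _decorate(base.mol, site, frag)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            counter += 1
            residues.append(Residue.from_smiles(
                f"X{counter:03d}", f"synthetic variant of {base.name}", canon))
    finally:
        RDLogger.EnableLog("rdApp.*")
    return ResidueLibrary(residues)


def _matching_codes(bits: pd.DataFrame, pattern_id: str) -> list[str]:
    col = bits[pattern_id]
    return [code for code, v in col.items() if v]


def generate_dataset(
    cfg: GeneratorConfig,
    library: ResidueLibrary,
    vocabulary: Vocabulary,
    bits: pd.DataFrame | None = None,
) -> list[Peptide]:
    """Labeled actives and negatives with the planted pair motif.

    The active family conserves its motif residues: the canonical (first
    in library order, hence natural when one exists) carrier of pattern A
    and of pattern B. Actives are uniform random sequences into which,
    with probability ``motif_penetrance``, that conserved residue pair is
    planted exactly ``gap`` residues apart (A on the N side) at a random
    feasible position. Negatives are uniform random sequences, optionally
    composition-matched (same residue pair at a clearly wrong spacing) or
    seeded with full-motif decoys (see GeneratorConfig).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    if bits is None:
        bits = residue_bit_table(library, vocabulary)
    pat_a, gap, pat_b = cfg.planted_motif
    for pid in (pat_a, pat_b):
        if pid not in vocabulary.pattern_ids:
            raise ValueError(f"planted pattern {pid!r} not in vocabulary")
    codes_a = _matching_codes(bits, pat_a)
    codes_b = _matching_codes(bits, pat_b)
    if not codes_a or not codes_b:
        raise ValueError("planted motif has no matching residues in the library")

    all_codes = library.codes
    lo, hi = cfg.length_range

    motif_a = codes_a[0]
    motif_b = codes_b[0]

    def random_sequence(length: int) -> list[str]:
        return [all_codes[i] for i in rng.integers(len(all_codes), size=length)]

    def plant(seq: list[str], at_gap: int) -> None:
        q1 = int(rng.integers(len(seq) - at_gap - 1))
        seq[q1] = motif_a
        seq[q1 + at_gap + 1] = motif_b

    peptides: list[Peptide] = []
    for i in range(cfg.n_active):
        length = int(rng.integers(max(lo, gap + 2), hi + 1))
        seq = random_sequence(length)
        if rng.random() < cfg.motif_penetrance:
            plant(seq, gap)
        peptides.append(Peptide(id=f"act{i:04d}", sequence=tuple(seq), label="active"))
    for i in range(cfg.n_non_active):
        length = int(rng.integers(lo, hi + 1))
        seq = random_sequence(length)
        if rng.random() < cfg.decoy_rate and length >= gap + 2:
            plant(seq, gap)
        elif cfg.match_composition:
            wrong_gaps = [g for g in range(length - 1) if abs(g - gap) >= 2]
            plant(seq, wrong_gaps[int(rng.integers(len(wrong_gaps)))])
        peptides.append(Peptide(id=f"neg{i:04d}", sequence=tuple(seq),
                                label="non_active"))
    return peptides


def assign_references(
    peptides: list[Peptide],
    fraction: float = 0.2,
    seed: int = 0,
) -> list[Peptide]:
    """Relabel a random fraction of actives as ``active_reference``.

    Returns a new list (input order preserved); at least one active stays
    ``active`` and at least one becomes a reference.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    active_pos = [i for i, p in enumerate(peptides) if p.label == "active"]
    if len(active_pos) < 2:
        raise ValueError("need at least two actives to split off references")
    n_ref = min(max(1, int(round(fraction * len(active_pos)))), len(active_pos) - 1)
    chosen = set(rng.choice(active_pos, size=n_ref, replace=False).tolist())
    out = []
    for i, p in enumerate(peptides):
        if i in chosen:
            out.append(Peptide(id=p.id, sequence=p.sequence, label="active_reference"))
        else:
            out.append(p)
    return out
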