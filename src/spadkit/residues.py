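"""Residue libraries, peptide sequences and whole-peptide assembly.

A residue is stored as a full monomer: a 2D molecular graph parsed from
SMILES in which the two backbone attachment points are marked by dummy
atoms — ``[*:1]`` on the nitrogen side (bond to the preceding carbonyl
carbon) and ``[*:2]`` on the carbonyl-carbon side (bond to the following
nitrogen). Keeping the whole monomer, rather than the side chain alone,
preserves backbone-adjacent modifications that non-natural residues may
carry.

Peptide sequences are written N→C in an extended one-letter format where
multi-letter residue codes appear in square brackets, e.g. ``AC[Cha]DE``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem

__all__ = [
    "Residue",
    "ResidueLibrary",
    "Peptide",
    "PEPTIDE_LABELS",
    "parse_residue_library",
    "natural_residue_library",
    "parse_peptides",
    "write_peptides",
    "write_residue_library",
    "tokenize_sequence",
    "assemble_peptide_graph",
]

PEPTIDE_LABELS = ("active", "active_reference", "non_active", "unlabeled")

N_ATTACHMENT = 1  # atom-map number of the N-side dummy
C_ATTACHMENT = 2  # atom-map number of the C-side dummy


class ResidueError(ValueError):
    """Raised for malformed residue libraries or sequences."""


def _attachment_dummies(mol: Chem.Mol) -> dict[int, list[int]]:
    """Map attachment-marker map number -> dummy atom indices."""
    found: dict[int, list[int]] = {N_ATTACHMENT: [], C_ATTACHMENT: []}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() in found:
            found[atom.GetAtomMapNum()].append(atom.GetIdx())
    return found


def _cap_molecule(mol: Chem.Mol) -> Chem.Mol:
    """Replace attachment dummies by neutral free termini (NH2 / COOH).

    The N-side dummy is deleted (the nitrogen regains an implicit
    hydrogen); the C-side dummy becomes a hydroxyl oxygen.
    """
    rw = Chem.RWMol(mol)
    to_remove = []
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() != 0:
            continue
        if atom.GetAtomMapNum() == C_ATTACHMENT:
            atom.SetAtomicNum(8)
            atom.SetAtomMapNum(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
            atom.SetNumRadicalElectrons(0)
        elif atom.GetAtomMapNum() == N_ATTACHMENT:
            to_remove.append(atom.GetIdx())
    for idx in sorted(to_remove, reverse=True):
        rw.RemoveAtom(idx)
    capped = rw.GetMol()
    Chem.SanitizeMol(capped)
    return capped


@dataclass(frozen=True)
class Residue:
    """A peptide monomer with marked N- and C-attachment points."""

    code: str
    name: str
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    capped: Chem.Mol = field(repr=False, compare=False)

    @classmethod
    def from_smiles(cls, code: str, name: str, smiles: str) -> "Residue":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ResidueError(f"residue {code!r}: unparseable SMILES {smiles!r}")
        dummies = _attachment_dummies(mol)
        if len(dummies[N_ATTACHMENT]) != 1 or len(dummies[C_ATTACHMENT]) != 1:
            raise ResidueError(
                f"residue {code!r}: monomer must carry exactly one [*:1] and "
                f"one [*:2] attachment marker"
            )
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ResidueError(f"residue {code!r}: monomer graph is disconnected")
        return cls(code=code, name=name, smiles=smiles, mol=mol,
                   capped=_cap_molecule(mol))


class ResidueLibrary:
    """Ordered, code-unique collection of residues."""

    def __init__(self, residues: Iterable[Residue]):
        self._residues: list[Residue] = list(residues)
        if not self._residues:
            raise ResidueError("residue library is empty")
        self._by_code: dict[str, Residue] = {}
        for r in self._residues:
            if r.code in self._by_code:
                raise ResidueError(f"duplicate residue code {r.code!r}")
            self._by_code[r.code] = r

    def __len__(self) -> int:
        return len(self._residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self._residues)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Residue:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self._residues]


@dataclass(frozen=True)
class Peptide:
    """A linear peptide: id, N→C residue codes, and an activity label."""

    id: str
    sequence: tuple[str, ...]
    label: str = "unlabeled"

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ResidueError(f"peptide {self.id!r}: empty sequence")
        if self.label not in PEPTIDE_LABELS:
            raise ResidueError(
                f"peptide {self.id!r}: label {self.label!r} not in {PEPTIDE_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_string(self) -> str:
        """Render the sequence in the bracketed extended format."""
        return "".join(c if len(c) == 1 else f"[{c}]" for c in self.sequence)


def parse_residue_library(path: str | Path) -> ResidueLibrary:
    """Read a residue library from CSV with columns code, name, smiles."""
    residues = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "name", "smiles"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ResidueError(f"{path}: expected CSV header with columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                residues.append(Residue.from_smiles(row["code"].strip(),
                                                    row["name"].strip(),
                                                    row["smiles"].strip()))
            except ResidueError as exc:
                raise ResidueError(f"{path} line {lineno}: {exc}") from None
    return ResidueLibrary(residues)


def natural_residue_library() -> ResidueLibrary:
    """The packaged library of the 20 natural amino-acid monomers."""
    ref = resources.files("spadkit.data") / "natural_residues.csv"
    with resources.as_file(ref) as path:
        return parse_residue_library(path)


def write_residue_library(library: ResidueLibrary, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name", "smiles"])
        for r in library:
            writer.writerow([r.code, r.name, r.smiles])


def tokenize_sequence(seq: str) -> tuple[str, ...]:
    """Split an extended-format sequence into residue codes, N→C.

    One-letter codes stand alone; multi-letter codes are bracketed.
    """
    tokens: list[str] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch == "[":
            end = seq.find("]", i)
            if end < 0:
                raise ResidueError(f"unbalanced '[' in sequence {seq!r}")
            token = seq[i + 1:end]
            if not token:
                raise ResidueError(f"empty bracketed code in sequence {seq!r}")
            tokens.append(token)
            i = end + 1
        elif ch == "]":
            raise ResidueError(f"unbalanced ']' in sequence {seq!r}")
        else:
            tokens.append(ch)
            i += 1
    return tuple(tokens)


def parse_peptides(path: str | Path, library: ResidueLibrary) -> list[Peptide]:
    """Read peptides from tab-separated text: ``id<TAB>sequence[<TAB>label]``.

    Lines starting with '#' and blank lines are ignored. Every residue code
    must resolve in *library*.
    """
    peptides = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ResidueError(f"{path} line {lineno}: expected 2 or 3 tab-separated fields")
            pid, seq = parts[0], parts[1]
            label = parts[2] if len(parts) == 3 and parts[2] else "unlabeled"
            tokens = tokenize_sequence(seq)
            for tok in tokens:
                if tok not in library:
                    raise ResidueError(
                        f"{path} line {lineno}: peptide {pid!r} uses unknown residue code {tok!r}"
                    )
            peptides.append(Peptide(id=pid, sequence=tokens, label=label))
    return peptides


def write_peptides(peptides: Iterable[Peptide], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peptides:
            fh.write(f"{p.id}\t{p.to_string()}\t{p.label}\n")


def assemble_peptide_graph(peptide: Peptide, library: ResidueLibrary) -> Chem.Mol:
    """Join monomers N→C by amide bonds and cap the free termini.

    Each residue's C-side attachment is bonded to the next residue's
    backbone nitrogen; the first residue keeps a free amine and the last
    a free carboxylic acid. Returns a sanitized, connected RDKit Mol.
    """
    mol = library[peptide.sequence[0]].mol
    for code in peptide.sequence[1:]:
        nxt = library[code].mol
        offset = mol.GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(mol, nxt))
        c_dummy = next(
            a.GetIdx() for a in rw.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == C_ATTACHMENT
            and a.GetIdx() < offset
        )
        n_dummy = next(
            a.GetIdx() for a in rw.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == N_ATTACHMENT
            and a.GetIdx() >= offset
        )
        carbonyl_c = rw.GetAtomWithIdx(c_dummy).GetNeighbors()[0].GetIdx()
        backbone_n = rw.GetAtomWithIdx(n_dummy).GetNeighbors()[0].GetIdx()
        rw.AddBond(carbonyl_c, backbone_n, Chem.BondType.SINGLE)
        for idx in sorted((c_dummy, n_dummy), reverse=True):
            rw.RemoveAtom(idx)
        mol = rw.GetMol()
    assembled = _cap_molecule(mol)
    if len(Chem.GetMolFrags(assembled)) != 1:
        raise ResidueError(f"peptide {peptide.id!r}: assembled graph is disconnected")
    return assembled
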