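"""PDB structure reading and B-factor score writing.

The internal model is deliberately small: ordered :class:`Atom` records grouped
into :class:`Residue` records grouped into a :class:`Structure`.  Atoms keep
the verbatim text of the ATOM/HETATM record they were parsed from, so that
:func:`write_scores_to_bfactor` can rewrite *only* the temperature-factor field
(columns 61-66) and leave every other byte of a well-formed input untouched.
Coordinates are always used in the file's own frame; no superposition is
performed anywhere in the package — mapping predictions onto each structure's
own atoms is what removes the influence of global orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError, EmptyStructureError, FormatError, MappingError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_pdb",
    "read_pdb_models",
    "write_scores_to_bfactor",
    "extract_observed_sequence",
    "THREE_TO_ONE",
]

# 3-letter -> 1-letter code; standard amino acids plus the common modified
# residues deposited as HETATM.  Anything else maps to 'X'.
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
MODIFIED_AA = {
    "MSE": "M",  # selenomethionine
    "SEC": "U",
    "PYL": "O",
    "HYP": "P",
    "MLY": "K",
    "CSO": "C",
    "PTR": "Y",
    "SEP": "S",
    "TPO": "T",
}
THREE_TO_ONE = {**STANDARD_AA, **MODIFIED_AA}


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name when columns 77-78 are blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. "1HB1" remoteness-numbered hydrogens
        stripped = stripped.lstrip("0123456789")
        return stripped[:1].upper()
    # two-letter elements occupy columns 13-14; a name starting in column 14
    # (single-letter element) is stored left-padded in the raw field
    if len(name) >= 2 and name[0] != " " and stripped[:2].upper() in {
        "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "CA", "NI", "CO",
    }:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


@dataclass
class Atom:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    altloc: str
    coord: np.ndarray
    occupancy: float
    raw_line: str = field(repr=False, default="")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in THREE_TO_ONE or self.res_name == "UNK"


class Structure:
    """An ordered set of residues parsed from one PDB file (or model)."""

    def __init__(self, id: str, residues: Sequence[Residue]):
        self.id = id
        self.residues: list[Residue] = list(residues)
        self._atoms: list[Atom] | None = None

    @property
    def atoms(self) -> list[Atom]:
        if self._atoms is None:
            self._atoms = [a for r in self.residues for a in r.atoms]
        return self._atoms

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """(l, 3) array of atom coordinates in file order."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    @property
    def observed_sequence(self) -> str:
        """One letter per amino-acid residue with coordinates, in residue order."""
        return "".join(r.one_letter for r in self.residues if r.is_amino_acid)

    def atom_residue_index(self) -> np.ndarray:
        """Residue index (into ``self.residues``) for every atom, length l."""
        return np.array(
            [j for j, r in enumerate(self.residues) for _ in r.atoms], dtype=np.intp
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Structure(id={self.id!r}, residues={self.n_residues}, atoms={self.n_atoms})"


def _parse_atom_line(line: str, lineno: int, path) -> tuple[tuple, Atom]:
    """Parse one ATOM/HETATM line into (residue key info, Atom)."""
    padded = line.ljust(80)
    try:
        serial = int(padded[6:11])
    except ValueError:
        # PDB files with >99999 atoms may use hybrid numbering; fall back
        serial = lineno
    name = padded[12:16]
    altloc = padded[16]
    res_name = padded[17:20].strip()
    chain_id = padded[21]
    try:
        seq_num = int(padded[22:26])
    except ValueError as exc:
        raise FormatError(f"bad residue number field {padded[22:26]!r}", path, lineno) from exc
    icode = padded[26].strip()
    try:
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
    except ValueError as exc:
        raise FormatError(f"bad coordinate field in record {padded[:54]!r}", path, lineno) from exc
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise FormatError("non-finite coordinate", path, lineno)
    occ_field = padded[54:60].strip()
    try:
        occupancy = float(occ_field) if occ_field else 1.0
    except ValueError as exc:
        raise FormatError(f"bad occupancy field {occ_field!r}", path, lineno) from exc
    element = padded[76:78].strip().capitalize()
    if not element:
        element = _element_from_name(name)
    atom = Atom(
        serial=serial,
        name=name.strip(),
        element=element,
        altloc="" if altloc == " " else altloc,
        coord=np.array([x, y, z], dtype=float),
        occupancy=occupancy,
        raw_line=line.rstrip("\n"),
    )
    return (chain_id, seq_num, icode, res_name), atom


def _resolve_altlocs(residue: Residue) -> None:
    """Keep one atom per atom name: highest occupancy, ties -> first altloc id."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in residue.atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[atom.name] = atom
    residue.atoms = [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins; blank beats 'A', 'A' beats 'B', ...
    if not altloc:
        return 0.0
    return -ord(altloc)


def _split_models(lines: list[str]) -> list[list[tuple[int, str]]]:
    """Group (lineno, line) records by MODEL; a file without MODEL is one model."""
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = []
        elif rec.startswith("ENDMDL"):
            in_model = False
            models.append(current)
            current = []
        elif rec.startswith(("ATOM  ", "HETATM")):
            current.append((lineno, line))
    if not saw_model:
        return [current]
    if current:  # records after last ENDMDL or unterminated MODEL
        models.append(current)
    return [m for m in models if m] or [[]]


def _build_structure(
    records: list[tuple[int, str]],
    structure_id: str,
    path,
    include_modified: bool,
) -> Structure:
    residues: list[Residue] = []
    index: dict[tuple, Residue] = {}
    n_parsed = 0
    for lineno, line in records:
        is_het = line.startswith("HETATM")
        key_info, atom = _parse_atom_line(line, lineno, path)
        chain_id, seq_num, icode, res_name = key_info
        if is_het:
            if not (include_modified and res_name in MODIFIED_AA):
                continue
        key = (chain_id, seq_num, icode, res_name)
        residue = index.get(key)
        if residue is None:
            residue = Residue(chain_id, seq_num, icode, res_name)
            index[key] = residue
            residues.append(residue)
        residue.atoms.append(atom)
        n_parsed += 1
    if n_parsed == 0:
        raise EmptyStructureError("no protein atoms found", path)
    for residue in residues:
        _resolve_altlocs(residue)
    return Structure(structure_id, residues)


def read_pdb(
    path,
    model_policy: str = "first_model",
    include_modified: bool = True,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB-format text file containing at least one ATOM record.
    model_policy
        ``"first_model"`` takes MODEL 1 of a multi-model (e.g. NMR) file;
        ``"error_on_multimodel"`` raises instead.  Use :func:`read_pdb_models`
        to treat each model as an ensemble member.
    include_modified
        Whether HETATM records of modified amino acids (MSE, SEP, ...) are
        read as protein residues.  All other HETATM records are excluded.
    """
    if model_policy not in ("first_model", "error_on_multimodel"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    models = _split_models(lines)
    if len(models) > 1 and model_policy == "error_on_multimodel":
        raise FormatError(f"file contains {len(models)} models", path)
    sid = structure_id if structure_id is not None else path.stem
    return _build_structure(models[0], sid, path, include_modified)


def read_pdb_string(
    text: str,
    structure_id: str,
    include_modified: bool = True,
) -> Structure:
    """Parse PDB-format text held in memory (single model)."""
    models = _split_models(text.splitlines())
    return _build_structure(models[0], structure_id, "<string>", include_modified)


def read_pdb_models(path, include_modified: bool = True) -> list[Structure]:
    """Read every MODEL of a multi-model PDB file as a separate Structure.

    Returned structures are labelled ``<stem>_model<i>`` (1-based); a file
    without MODEL records yields a single structure labelled by its stem.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    models = _split_models(lines)
    if len(models) == 1:
        return [_build_structure(models[0], path.stem, path, include_modified)]
    return [
        _build_structure(m, f"{path.stem}_model{i}", path, include_modified)
        for i, m in enumerate(models, start=1)
    ]


def _format_bfactor(score: float) -> str:
    """Probability in [0,1] -> fixed-width percentage field (columns 61-66).

    Clipped to 99.99 so the value always fits the 6-character field with two
    decimals; 1.0 therefore prints as ``' 99.99'``.
    """
    pct = min(score * 100.0, 99.99)
    return f"{pct:6.2f}"


def write_scores_to_bfactor(
    structure: Structure,
    atom_scores: Sequence[float] | None = None,
    residue_scores: Sequence[float] | Mapping | None = None,
) -> str:
    """Render the structure's PDB text with probabilities in the B-factor column.

    Exactly one of ``atom_scores`` (one probability per atom, file order) or
    ``residue_scores`` (one per residue, broadcast to every atom of the
    residue) must be given.  Scores are written as percentages, fixed width,
    two decimals, clipped at 99.99; every other column of each retained atom
    record is reproduced byte-for-byte.
    """
    if (atom_scores is None) == (residue_scores is None):
        raise ValueError("provide exactly one of atom_scores or residue_scores")

    if residue_scores is not None:
        if isinstance(residue_scores, Mapping):
            try:
                per_res = [float(residue_scores[r.key]) for r in structure.residues]
            except KeyError as exc:
                raise DataError(f"missing score for residue {exc.args[0]}") from None
        else:
            per_res = [float(s) for s in residue_scores]
            if len(per_res) != structure.n_residues:
                raise DataError(
                    f"got {len(per_res)} residue scores for {structure.n_residues} residues"
                )
        per_atom = [s for r, s in zip(structure.residues, per_res) for _ in r.atoms]
    else:
        per_atom = [float(s) for s in atom_scores]
        if len(per_atom) != structure.n_atoms:
            raise DataError(
                f"got {len(per_atom)} atom scores for {structure.n_atoms} atoms"
            )

    for s in per_atom:
        if not (0.0 <= s <= 1.0) or not math.isfinite(s):
            raise DataError(f"score {s!r} outside [0, 1]")

    out_lines: list[str] = []
    for atom, score in zip(structure.atoms, per_atom):
        line = atom.raw_line if atom.raw_line else _synthesise_atom_line(atom)
        if len(line) < 66:
            line = line.ljust(66)
        out_lines.append(line[:60] + _format_bfactor(score) + line[66:])
    out_lines.append("END")
    return "\n".join(out_lines) + "\n"


def _synthesise_atom_line(atom: Atom) -> str:
    # only used for atoms constructed in memory without a source line
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coord
    return (
        f"ATOM  {atom.serial:5d} {name}{atom.altloc or ' '}"
        f"UNK A   1    {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}  0.00"
        f"          {atom.element:>2s}"
    )


def extract_observed_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of the amino-acid residues of one chain, in order.

    Only residues with coordinates contribute; nonstandard residues map via a
    fixed 3->1 table with fallback ``'X'``.
    """
    letters = [
        r.one_letter
        for r in structure.residues
        if r.chain_id == chain_id and r.is_amino_acid
    ]
    if not letters:
        raise MappingError(
            f"structure {structure.id!r} has no amino-acid residues in chain {chain_id!r}"
        )
    return "".join(letters)


def write_pdb(structure: Structure, path) -> None:
    """Write the structure's retained atom records (verbatim) plus END."""
    lines = [a.raw_line if a.raw_line else _synthesise_atom_line(a) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
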