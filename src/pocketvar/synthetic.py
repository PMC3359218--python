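"""Deterministic synthetic fixtures: toy structures, conformer ensembles,
homologue sets with alignments, and planted pocket point clouds.

The generators stand in for the real-world inputs of an ensemble pocket
analysis — constraint-based conformer generators, NMR ensembles, homologous
superfamily sets and the point clouds of geometric pocket predictors — at a
scale where every expected score is known by construction.  Toy structures
are extended chains, geometrically simple on purpose: the scoring scheme is
purely geometric/statistical, so physical realism buys nothing for testing.

Geometry is chosen so that planted pockets are unambiguous: residues sit
8 Å apart along x, each residue's atoms 1.5 Å apart along y, and pocket
points are emitted 3 Å along z from each target-residue atom.  With the
default 3.75 Å scoring cutoff a point can only ever reach its own residue's
atoms (the nearest non-target atom is > 8.5 Å away before perturbation),
so an ensemble with the pocket emitted in a fraction f of members recovers
ensemble probability exactly f at the target residues and exactly 0
elsewhere.  Coordinate perturbations are truncated at 3.8 standard
deviations, which preserves that separation for amplitudes up to ~0.9 Å.

All randomness flows from ``numpy.random.default_rng(seed)`` (PCG64) in a
fixed draw order, so a fixed seed gives byte-identical files on any
platform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .pocket_io import PocketPointSet
from .structure_io import STANDARD_AA, Structure, read_pdb_string

__all__ = [
    "FixtureSpec",
    "make_toy_structure",
    "make_conformer_ensemble",
    "make_pocket_points",
    "make_ensemble_with_pockets",
    "make_homologue_set",
    "HomologueSet",
    "write_points_file",
    "write_fasta_alignment",
    "emit_fixture_directory",
]

RESIDUE_SPACING = 8.0  # Å between residues along x
ATOM_SPACING = 1.5  # Å between a residue's atoms along y
POCKET_OFFSET = 3.0  # Å from a target atom to its pocket point, along z
PERTURBATION_TRUNCATION = 3.8  # standard deviations

_AA_CYCLE = sorted(STANDARD_AA)  # deterministic ALA, ARG, ASN, ...
_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "CZ", "NZ"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic ensemble fixture.

    Defaults mirror a typical small ensemble analysis: 50 conformers (the
    size of the simulated-ensemble sets the probability maps are usually
    drawn from) of a 20-residue chain, perturbed by 0.5 Å Gaussian noise,
    with a 3-residue pocket present in every member.
    """

    n_residues: int = 20
    atoms_per_residue: int = 5
    n_conformers: int = 50
    perturbation_amplitude: float = 0.5
    pocket_target: tuple[int, ...] | None = None  # residue indices, 0-based
    pocket_presence_prob: float = 1.0
    indel_spec: dict[int, list[tuple]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ConfigError("n_residues must be >= 1")
        if self.atoms_per_residue < 1:
            raise ConfigError("atoms_per_residue must be >= 1")
        if self.n_conformers < 1:
            raise ConfigError("n_conformers must be >= 1")
        if self.perturbation_amplitude < 0:
            raise ConfigError("perturbation_amplitude must be >= 0")
        if not 0.0 <= self.pocket_presence_prob <= 1.0:
            raise ConfigError("pocket_presence_prob must lie in [0, 1]")
        if self.pocket_target is None:
            mid = self.n_residues // 2
            self.pocket_target = tuple(
                j for j in (mid - 1, mid, mid + 1) if 0 <= j < self.n_residues
            )
        bad = [j for j in self.pocket_target if not 0 <= j < self.n_residues]
        if bad:
            raise ConfigError(f"pocket_target indices out of range: {bad}")


def _atom_name(t: int) -> str:
    return _ATOM_NAMES[t] if t < len(_ATOM_NAMES) else f"X{t:02d}"[:4]


def _pdb_atom_line(serial, name, res_name, chain, res_num, xyz, occ=1.0, bf=0.0,
                   record="ATOM  ", element=" C") -> str:
    padded_name = name if len(name) == 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"{record}{serial:5d} {padded_name} {res_name} {chain}{res_num:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {element:>2s}"
    )


def _chain_pdb_text(res_names: list[str], atoms_per_residue: int,
                    displacement: np.ndarray | None = None) -> str:
    """Extended-chain PDB text; displacement is an optional (l, 3) offset array."""
    lines = []
    serial = 0
    k = 0
    for j, res_name in enumerate(res_names):
        for t in range(atoms_per_residue):
            serial += 1
            base = np.array([j * RESIDUE_SPACING, t * ATOM_SPACING, 0.0])
            if displacement is not None:
                base = base + displacement[k]
            lines.append(
                _pdb_atom_line(serial, _atom_name(t), res_name, "A", j + 1, base)
            )
            k += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _truncated_normal(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape)
    draw = rng.normal(0.0, sigma, size=shape)
    bound = PERTURBATION_TRUNCATION * sigma
    return np.clip(draw, -bound, bound)


def make_toy_structure(spec: FixtureSpec, structure_id: str = "toy") -> Structure:
    """Extended-chain structure: n_residues regularly spaced, standard names."""
    res_names = [_AA_CYCLE[j % len(_AA_CYCLE)] for j in range(spec.n_residues)]
    return read_pdb_string(
        _chain_pdb_text(res_names, spec.atoms_per_residue), structure_id
    )


def make_conformer_ensemble(spec: FixtureSpec) -> list[Structure]:
    """n_conformers perturbed copies of the toy structure, identical topology.

    Each member's coordinates are the base chain plus truncated Gaussian
    displacements of the given amplitude (per coordinate), so the expected
    per-atom RMS displacement is amplitude * sqrt(3).
    """
    rng = np.random.default_rng(spec.seed)
    res_names = [_AA_CYCLE[j % len(_AA_CYCLE)] for j in range(spec.n_residues)]
    l = spec.n_residues * spec.atoms_per_residue
    members = []
    for i in range(spec.n_conformers):
        disp = _truncated_normal(rng, spec.perturbation_amplitude, (l, 3))
        text = _chain_pdb_text(res_names, spec.atoms_per_residue, disp)
        members.append(read_pdb_string(text, f"conf_{i:04d}"))
    return members


def make_pocket_points(
    structure: Structure,
    target_residues,
    jitter: float = 0.0,
    present: bool = True,
    rng: np.random.Generator | None = None,
    source: str = "generic",
) -> PocketPointSet:
    """Pocket points 3 Å along z from every atom of the target residues.

    With ``jitter`` > 0 each point is displaced by a Gaussian offset whose
    norm is capped at 0.7 Å, keeping every point within the default 3.75 Å
    cutoff of its own atom.  ``present=False`` returns a legitimately empty
    set (a predictor that found no pockets).
    """
    if not present:
        return PocketPointSet.empty(structure.id, source=source)
    target_residues = sorted(set(int(j) for j in target_residues))
    if rng is None:
        rng = np.random.default_rng(0)
    points = []
    for j in target_residues:
        for atom in structure.residues[j].atoms:
            p = atom.coord + np.array([0.0, 0.0, POCKET_OFFSET])
            if jitter > 0:
                off = rng.normal(0.0, jitter, 3)
                norm = float(np.linalg.norm(off))
                if norm > 0.7:
                    off *= 0.7 / norm
                p = p + off
            points.append(np.round(p, 3))
    return PocketPointSet(structure.id, np.array(points), source=source)


def _presence_mask(rng: np.random.Generator, n: int, prob: float) -> np.ndarray:
    """Exactly round(prob * n) members carry the pocket, chosen by seeded draw."""
    n_present = int(round(prob * n))
    mask = np.zeros(n, dtype=bool)
    if n_present:
        mask[rng.choice(n, size=n_present, replace=False)] = True
    return mask


def make_ensemble_with_pockets(
    spec: FixtureSpec, jitter: float = 0.0
) -> tuple[list[Structure], list[PocketPointSet], np.ndarray]:
    """Conformer ensemble plus per-member pocket predictions.

    The pocket is emitted in exactly ``round(pocket_presence_prob *
    n_conformers)`` members (chosen by the seeded generator), so the
    ensemble residue probability at the target residues equals that
    fraction exactly; members without the pocket get a legitimately empty
    prediction.  Returns (structures, point sets, presence mask).
    """
    members = make_conformer_ensemble(spec)
    rng = np.random.default_rng(spec.seed + 1)
    mask = _presence_mask(rng, spec.n_conformers, spec.pocket_presence_prob)
    point_sets = [
        make_pocket_points(m, spec.pocket_target, jitter=jitter, present=bool(mask[i]), rng=rng)
        for i, m in enumerate(members)
    ]
    return members, point_sets, mask


@dataclass
class HomologueSet:
    """A synthetic homologue family with its (correct-by-construction) alignment."""

    structures: list[Structure]
    alignment_rows: dict[str, str]
    alignment_text: str
    target_columns: list[int]  # 0-based alignment columns of the planted pocket
    pocket_members: list[str]  # structure ids carrying the pocket
    point_sets: list[PocketPointSet] = field(default_factory=list)


def _apply_indels(parent_tokens: list[int], ops: list[tuple], member: int):
    """Token list after deletions/insertions.

    Ops: ``("del", start, length)`` removes parent residues
    [start, start+length); ``("ins", after, length)`` inserts new residues
    after parent position ``after`` (-1 for a leading insertion).  Deleted
    positions and insertions are returned for alignment construction.
    """
    deleted: set[int] = set()
    insertions: dict[int, int] = {}
    for op in ops:
        kind = op[0]
        if kind == "del":
            _, start, length = op
            deleted.update(range(start, start + length))
        elif kind == "ins":
            _, after, length = op
            insertions[after] = insertions.get(after, 0) + length
        else:
            raise ConfigError(f"unknown indel op {op!r}")
    return deleted, insertions


def make_homologue_set(spec: FixtureSpec, pocket_jitter: float = 0.0) -> HomologueSet:
    """Homologues derived from one parent chain by per-member indels.

    ``spec.indel_spec`` maps member index -> list of indel ops (see
    :func:`_apply_indels`); members absent from the mapping are identical in
    sequence to the parent.  ``spec.n_conformers`` doubles as the number of
    homologues.  The pocket is planted at the alignment columns of
    ``spec.pocket_target`` (parent residue indices) in exactly
    ``round(pocket_presence_prob * n_members)`` members; a member that lost a
    target residue to a deletion simply contributes fewer target residues.
    """
    n_members = spec.n_conformers
    indel_spec = spec.indel_spec or {}
    rng = np.random.default_rng(spec.seed)
    parent_names = [_AA_CYCLE[j % len(_AA_CYCLE)] for j in range(spec.n_residues)]

    per_member: list[tuple[set[int], dict[int, int]]] = []
    for i in range(n_members):
        per_member.append(_apply_indels(list(range(spec.n_residues)), indel_spec.get(i, []), i))

    # global column layout: for each parent slot, first everyone's insertions
    # (exclusive columns, member-ordered), then the shared parent column
    columns: list[tuple] = []  # ("ins", member, after, idx) or ("parent", j)
    for after in range(-1, spec.n_residues):
        for i in range(n_members):
            _, insertions = per_member[i]
            for idx in range(insertions.get(after, 0)):
                columns.append(("ins", i, after, idx))
        if after + 1 < spec.n_residues:
            columns.append(("parent", after + 1))

    ins_name_cycle = itertools.cycle(_AA_CYCLE[::-1])
    ins_names = {c: next(ins_name_cycle) for c in columns if c[0] == "ins"}

    rows: dict[str, str] = {}
    structures: list[Structure] = []
    for i in range(n_members):
        deleted, _ = per_member[i]
        res_names: list[str] = []
        row_chars: list[str] = []
        for col in columns:
            if col[0] == "parent":
                j = col[1]
                if j in deleted:
                    row_chars.append("-")
                else:
                    res_names.append(parent_names[j])
                    row_chars.append(_one_letter(parent_names[j]))
            else:
                _, member, _, _ = col
                if member == i:
                    res_names.append(ins_names[col])
                    row_chars.append(_one_letter(ins_names[col]))
                else:
                    row_chars.append("-")
        sid = f"hom_{i:02d}"
        disp = _truncated_normal(
            rng, spec.perturbation_amplitude, (len(res_names) * spec.atoms_per_residue, 3)
        )
        structures.append(
            read_pdb_string(_chain_pdb_text(res_names, spec.atoms_per_residue, disp), sid)
        )
        rows[sid] = "".join(row_chars)

    target_columns = [
        c for c, col in enumerate(columns)
        if col[0] == "parent" and col[1] in set(spec.pocket_target)
    ]

    mask = _presence_mask(
        np.random.default_rng(spec.seed + 1), n_members, spec.pocket_presence_prob
    )
    point_sets = []
    pocket_members = []
    col_of_parent = {col[1]: c for c, col in enumerate(columns) if col[0] == "parent"}
    for i, s in enumerate(structures):
        if mask[i]:
            deleted, _ = per_member[i]
            # residue index within this member for each surviving target residue
            member_targets = []
            for j in sorted(set(spec.pocket_target)):
                if j in deleted:
                    continue
                member_targets.append(_member_residue_index(columns, per_member[i], i, j))
            point_sets.append(
                make_pocket_points(s, member_targets, jitter=pocket_jitter, rng=rng)
            )
            pocket_members.append(s.id)
        else:
            point_sets.append(PocketPointSet.empty(s.id))

    alignment_text = write_fasta_alignment(rows, None)
    return HomologueSet(
        structures=structures,
        alignment_rows=rows,
        alignment_text=alignment_text,
        target_columns=target_columns,
        pocket_members=pocket_members,
        point_sets=point_sets,
    )


def _one_letter(res_name: str) -> str:
    return STANDARD_AA[res_name]


def _member_residue_index(columns, member_state, member, parent_j) -> int:
    """Index of parent residue ``parent_j`` within the member's residue list."""
    deleted, _ = member_state
    idx = 0
    for col in columns:
        if col[0] == "parent":
            j = col[1]
            if j in deleted:
                continue
            if j == parent_j:
                return idx
            idx += 1
        elif col[1] == member:
            idx += 1
    raise ValueError(f"parent residue {parent_j} not present in member {member}")


# ---------------------------------------------------------------------------
# file emission (for parser tests and the `fixtures` CLI subcommand)

_DIALECTS = {
    "pass": ("ATOM  ", "PRB", "O"),
    "ligsite": ("ATOM  ", "CTR", "O"),
    "fpocket": ("HETATM", "STP", "O"),
    "generic": ("HETATM", "PNT", "O"),
}


def write_points_file(points: PocketPointSet, path, dialect: str = "generic") -> None:
    """Write a point set in a predictor's PDB dialect.

    ``fpocket`` records carry a cycling pocket id in the residue-number
    column (which the readers deliberately ignore); the other dialects
    number records sequentially.
    """
    try:
        record, res_name, atom_name = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    lines = []
    if len(points) == 0:
        from .pocket_io import EMPTY_PREDICTION_MARKER

        Path(path).write_text(EMPTY_PREDICTION_MARKER + "\nEND\n")
        return
    for i, p in enumerate(points.points):
        res_num = (i % 3) + 1 if dialect == "fpocket" else i + 1
        lines.append(
            _pdb_atom_line(
                i + 1, atom_name, res_name, "Z", res_num, p,
                occ=1.0, bf=0.0, record=record, element=" O",
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta_alignment(rows: dict[str, str], path) -> str:
    """FASTA-format alignment text; written to ``path`` when given."""
    text = "".join(f">{rid}\n{seq}\n" for rid, seq in rows.items())
    if path is not None:
        Path(path).write_text(text)
    return text


def emit_fixture_directory(spec: FixtureSpec, outdir, dialect: str = "generic",
                           mode: str = "conformers") -> dict:
    """Write a complete ready-to-score fixture set into a directory.

    Conformer mode emits one PDB per member plus one point file per member
    (members whose predictor found no pockets get a marker file that the
    readers recognise as a legitimately empty prediction); homologue mode
    additionally writes the FASTA alignment.  Returns a summary of what was
    written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .structure_io import write_pdb  # local import to avoid cycle at module load

    if mode == "conformers":
        structures, point_sets, mask = make_ensemble_with_pockets(spec)
        extra = {"pocket_present": [bool(m) for m in mask]}
        alignment_path = None
    elif mode == "homologues":
        hs = make_homologue_set(spec)
        structures, point_sets = hs.structures, hs.point_sets
        alignment_path = outdir / "alignment.fasta"
        write_fasta_alignment(hs.alignment_rows, alignment_path)
        extra = {
            "pocket_members": hs.pocket_members,
            "target_columns": [c + 1 for c in hs.target_columns],
        }
    else:
        raise ConfigError(f"unknown fixture mode {mode!r}")

    structure_files, point_files, empty_ids = [], [], []
    for s, d in zip(structures, point_sets):
        spath = outdir / f"{s.id}.pdb"
        write_pdb(s, spath)
        structure_files.append(str(spath))
        ppath = outdir / f"{s.id}_points.pdb"
        write_points_file(d, ppath, dialect=dialect)
        point_files.append(str(ppath))
        if len(d) == 0:
            empty_ids.append(s.id)
    return {
        "mode": mode,
        "dialect": dialect,
        "structures": structure_files,
        "points": point_files,
        "empty_prediction_ids": empty_ids,
        "alignment": str(alignment_path) if alignment_path else None,
        "target_residues": [j + 1 for j in spec.pocket_target],
        **extra,
    }
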