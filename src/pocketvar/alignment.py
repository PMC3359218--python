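"""Alignment-column <-> structure-residue correspondence for homologue sets.

Homologous structures have different sequences, so their residues are
compared through a multiple sequence alignment supplied by the user (this
package consumes alignments, it never computes them — aligner choice
materially affects results and belongs upstream).  Alignments must be built
on the *observed* sequences, i.e. the residues actually present with
coordinates in each PDB file; this is asserted at map construction, so a
stale alignment fails loudly rather than silently shifting columns.

Rows may be flagged *reference-only*: they receive a column mapping (so
ensemble scores can be projected onto that structure for display) but are
excluded from every probability sum and from the per-column counts n_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .errors import FormatError, MappingError
from .structure_io import Structure

__all__ = [
    "AlignmentMap",
    "read_alignment",
    "build_alignment_map",
    "project_column_scores",
]

GAP_CHARS = "-."


def read_alignment(path, format: str | None = None) -> dict[str, str]:
    """Read a FASTA or Clustal multiple sequence alignment.

    Returns an ordered mapping id -> gapped sequence (upper-case, with '.'
    gaps normalised to '-').  ``format`` is auto-detected from the first
    line when not given.  Rows of unequal length raise a format error.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        head = text.lstrip().splitlines()[0] if text.strip() else ""
        format = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        with open(path) as handle:
            aln = AlignIO.read(handle, format)
    except ValueError as exc:
        raise FormatError(f"cannot parse {format} alignment: {exc}", path) from exc
    rows: dict[str, str] = {}
    for rec in aln:
        seq = str(rec.seq).upper().replace(".", "-")
        if rec.id in rows:
            raise FormatError(f"duplicate alignment id {rec.id!r}", path)
        rows[rec.id] = seq
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"alignment rows have unequal lengths {sorted(lengths)}", path)
    if not rows:
        raise FormatError("alignment contains no sequences", path)
    return rows


@dataclass
class AlignmentMap:
    """Column -> residue correspondence for each structure.

    ``column_residues(id)`` gives, per alignment column, the index of the
    structure's residue occupying that column, or -1 at a gap.  Ungapping any
    row reproduces that structure's observed sequence exactly (checked at
    construction).
    """

    columns: int
    maps: dict[str, np.ndarray] = field(default_factory=dict)  # lower-case id -> col map
    reference_only_ids: frozenset[str] = frozenset()
    display_ids: dict[str, str] = field(default_factory=dict)  # lower-case -> original

    def column_residues(self, structure_id: str) -> np.ndarray:
        return self.maps[structure_id.lower()]

    def is_reference_only(self, structure_id: str) -> bool:
        return structure_id.lower() in self.reference_only_ids

    @property
    def scored_ids(self) -> list[str]:
        return [
            self.display_ids[k] for k in self.maps if k not in self.reference_only_ids
        ]


def _match_sequences(observed: str, ungapped: str, structure_id: str,
                     max_mismatches: int) -> int:
    """Compare the structure's observed sequence to the ungapped row.

    'X' in the observed sequence matches any letter.  Returns the number of
    tolerated mismatches; raises on length disagreement or excess mismatches,
    naming the first offending position and both letters.
    """
    if len(observed) != len(ungapped):
        raise MappingError(
            f"structure {structure_id!r}: observed sequence has {len(observed)} "
            f"residues but its alignment row has {len(ungapped)} (ungapped)"
        )
    mismatches = [
        (i, o, u)
        for i, (o, u) in enumerate(zip(observed, ungapped))
        if o != u and o != "X"
    ]
    if len(mismatches) > max_mismatches:
        pos, o, u = mismatches[0]
        raise MappingError(
            f"structure {structure_id!r}: sequence mismatch at position {pos + 1} "
            f"(structure has {o!r}, alignment row has {u!r}; "
            f"{len(mismatches)} mismatching positions in total)"
        )
    return len(mismatches)


def build_alignment_map(
    rows: Mapping[str, str],
    structures: Sequence[Structure],
    reference_ids: Iterable[str] = (),
    id_map: Mapping[str, str] | None = None,
    max_mismatches: int = 0,
) -> AlignmentMap:
    """Map alignment columns onto the residues of each structure.

    Structure ids are matched case-insensitively to alignment row ids;
    ``id_map`` (structure id -> row id) overrides.  Structures named in
    ``reference_ids`` get a mapping but are excluded from scoring.
    Alignment rows matching no structure become reference-only as well.
    ``max_mismatches`` > 0 tolerates that many sequence disagreements
    (use only for known header/sequence drift; mismatches are reported in
    the error message when exceeded).
    """
    if not rows:
        raise MappingError("empty alignment")
    columns = len(next(iter(rows.values())))
    rows_by_lower = {rid.lower(): (rid, seq) for rid, seq in rows.items()}
    if len(rows_by_lower) != len(rows):
        raise MappingError("alignment row ids collide case-insensitively")
    id_map_lower = {k.lower(): v.lower() for k, v in (id_map or {}).items()}
    reference = {r.lower() for r in reference_ids}

    maps: dict[str, np.ndarray] = {}
    display: dict[str, str] = {}
    matched_rows: set[str] = set()
    for s in structures:
        sid = s.id.lower()
        row_key = id_map_lower.get(sid, sid)
        if row_key not in rows_by_lower:
            raise MappingError(
                f"structure {s.id!r} has no row in the alignment "
                f"(rows: {sorted(rows.keys())})"
            )
        _, gapped = rows_by_lower[row_key]
        matched_rows.add(row_key)
        ungapped = "".join(c for c in gapped if c not in GAP_CHARS)
        amino_idx = [j for j, res in enumerate(s.residues) if res.is_amino_acid]
        _match_sequences(s.observed_sequence, ungapped, s.id, max_mismatches)
        col_map = np.full(columns, -1, dtype=np.intp)
        cursor = 0
        for c, ch in enumerate(gapped):
            if ch not in GAP_CHARS:
                col_map[c] = amino_idx[cursor]
                cursor += 1
        maps[sid] = col_map
        display[sid] = s.id

    unmatched_rows = set(rows_by_lower) - matched_rows
    reference |= unmatched_rows
    return AlignmentMap(
        columns=columns,
        maps=maps,
        reference_only_ids=frozenset(reference),
        display_ids=display,
    )


def project_column_scores(
    scores,
    display_structure: Structure,
    alignment_map: AlignmentMap,
    which: str = "residue_probs",
) -> np.ndarray:
    """Per-residue scores on a chosen display structure, looked up by column.

    Each display residue receives the score of its alignment column;
    residues at columns that carry no score come back as NaN (the caller
    writes those as 0.00 with a sidecar note).  The display structure may be
    a reference-only alignment member.
    """
    if scores.mode != "aligned":
        raise ValueError("projection applies to aligned-mode scores")
    if which not in ("residue_probs", "residue_mean_atom"):
        raise ValueError(f"unknown score vector {which!r}")
    try:
        col_map = alignment_map.column_residues(display_structure.id)
    except KeyError:
        raise MappingError(
            f"display structure {display_structure.id!r} is absent from the alignment"
        ) from None
    values = getattr(scores, which)
    out = np.full(display_structure.n_residues, np.nan)
    for c in range(alignment_map.columns):
        res_idx = col_map[c]
        if res_idx >= 0:
            out[res_idx] = values[c]
    return out
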