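"""Parsers for pocket-prediction point files.

Geometric pocket predictors emit clouds of probe-sphere centres or grid
points in PDB-format files, each program with its own dialect:

* PASS — final-layer probe spheres in files ending ``probes_r.pdb``;
* LIGSITE-cs — sphere centroids in files ending ``pocket_r.pdb``;
* fpocket — alpha-sphere HETATM records with residue name ``STP``;
* anything else that writes plain PDB-format points (e.g. SiteMap) is
  handled by the generic reader.

All readers reduce to the same :class:`PocketPointSet`: bare 3-D centres.
Distances downstream are measured to sphere *centres*; radii, where the file
provides them, are kept as metadata only.  Pocket/cluster identifiers in the
files are deliberately discarded — the scoring scheme is pocket-agnostic,
which sidesteps the ill-posed problem of delimiting individual pockets.

Programs that directly output per-atom scores (e.g. CASTp) are supported via
:func:`read_prescored_pdb`, which thresholds the B-factor column into a
binary indicator vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyPredictionError, FormatError, PairingError
from .structure_io import Structure

__all__ = [
    "PocketPointSet",
    "PairedSet",
    "read_pass_probes",
    "read_ligsite_centroids",
    "read_fpocket_spheres",
    "read_generic_points",
    "read_prescored_pdb",
    "read_pocket_points",
    "pair_structures_predictions",
]

SOURCES = ("pass", "ligsite", "fpocket", "generic", "prescored")


@dataclass
class PocketPointSet:
    """Pocket-prediction sphere centres for one structure."""

    structure_id: str
    points: np.ndarray  # (n, 3)
    source: str = "generic"
    radii: np.ndarray | None = None
    legitimately_empty: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise FormatError("non-finite pocket point coordinate")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (len(self.points),):
                raise ValueError("radii length must match points")
            if np.any(self.radii <= 0):
                raise ValueError("radii must be positive")
        if len(self.points) == 0 and not self.legitimately_empty:
            raise EmptyPredictionError(
                "empty point set; use PocketPointSet.empty() for a predictor "
                "that legitimately found no pockets"
            )

    @classmethod
    def empty(cls, structure_id: str, source: str = "generic") -> "PocketPointSet":
        """A predictor ran successfully and found zero pockets."""
        return cls(structure_id, np.empty((0, 3)), source=source, legitimately_empty=True)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PairedSet:
    """Matched (structure, prediction) pairs — the unit the ensemble scorer consumes."""

    pairs: list[tuple[Structure, PocketPointSet]] = field(default_factory=list)

    def __post_init__(self):
        if not self.pairs:
            raise PairingError("a paired set needs at least one pair")
        for s, d in self.pairs:
            if s.id != d.structure_id:
                raise PairingError(
                    f"structure {s.id!r} paired with prediction for {d.structure_id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _parse_point_records(path, keep=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Extract coordinates (and occupancy-column radii) from ATOM/HETATM records.

    ``keep`` optionally filters records by their 3-letter residue-name field.
    """
    path = Path(path)
    coords: list[list[float]] = []
    radii: list[float] = []
    any_radius = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM", "ATOM\t")):
            continue
        padded = line.ljust(60)
        if keep is not None and padded[17:20].strip() != keep:
            continue
        try:
            xyz = [float(padded[30:38]), float(padded[38:46]), float(padded[46:54])]
        except ValueError as exc:
            raise FormatError(
                f"bad coordinate field in point record {line[:54]!r}", path, lineno
            ) from exc
        coords.append(xyz)
        try:
            r = float(padded[54:60])
            any_radius = any_radius or r > 0
            radii.append(r)
        except ValueError:
            radii.append(0.0)
    pts = np.array(coords, dtype=float).reshape(-1, 3)
    rad = np.array(radii) if (any_radius and np.all(np.array(radii) > 0)) else None
    return pts, rad


# a predictor that ran and found nothing is recorded on disk with this marker,
# distinguishing it from a truncated or unparsable file
EMPTY_PREDICTION_MARKER = "REMARK NO POCKET POINTS"


def _read_points(path, source: str, keep=None) -> PocketPointSet:
    points, radii = _parse_point_records(path, keep=keep)
    if len(points) == 0:
        for line in Path(path).read_text().splitlines():
            if line.strip().upper().startswith(EMPTY_PREDICTION_MARKER):
                return PocketPointSet.empty(Path(path).stem, source=source)
        raise EmptyPredictionError("no parseable point records", Path(path))
    return PocketPointSet(Path(path).stem, points, source=source, radii=radii)


def read_pass_probes(path) -> PocketPointSet:
    """Read a PASS final-layer probe-sphere file (``*probes_r.pdb``)."""
    return _read_points(path, "pass")


def read_ligsite_centroids(path) -> PocketPointSet:
    """Read a LIGSITE-cs centroid file (``*pocket_r.pdb``).

    Cluster ids carried in the residue-number column are ignored.
    """
    return _read_points(path, "ligsite")


def read_fpocket_spheres(path) -> PocketPointSet:
    """Read fpocket PDB output: one point per alpha-sphere ``STP`` record.

    Protein ATOM records that fpocket echoes into its output are skipped;
    pocket ids (residue numbers of the STP records) are discarded.
    """
    return _read_points(path, "fpocket", keep="STP")


def read_generic_points(path) -> PocketPointSet:
    """Read any PDB-format point list: every ATOM/HETATM coordinate is a point."""
    return _read_points(path, "generic")


_READERS = {
    "pass": read_pass_probes,
    "ligsite": read_ligsite_centroids,
    "fpocket": read_fpocket_spheres,
    "generic": read_generic_points,
}


def read_pocket_points(path, source: str = "generic") -> PocketPointSet:
    """Dispatch to the reader for the given predictor dialect."""
    try:
        reader = _READERS[source]
    except KeyError:
        raise ValueError(f"unknown prediction format {source!r}") from None
    return reader(path)


def read_prescored_pdb(path, structure: Structure, threshold: float = 0.0) -> np.ndarray:
    """Binary per-atom indicators from a pre-scored PDB file.

    The file's atoms must correspond one-to-one, in order, with the
    structure's atoms; atom k is flagged pocket-lining iff its score field
    (the B-factor column) exceeds ``threshold``.
    """
    path = Path(path)
    scores: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        padded = line.ljust(66)
        fld = padded[60:66].strip()
        try:
            scores.append(float(fld) if fld else 0.0)
        except ValueError as exc:
            raise FormatError(f"bad score field {fld!r}", path, lineno) from exc
    if len(scores) != structure.n_atoms:
        raise PairingError(
            f"{path}: {len(scores)} scored atoms do not pair with "
            f"{structure.n_atoms} atoms of structure {structure.id!r}"
        )
    return (np.array(scores) > threshold).astype(np.int8)


# suffixes predictors append to the parent structure's file stem
_STEM_SUFFIXES = ("_probes_r", "probes_r", "_pocket_r", "_pocket-r", "_out", "_pockets", "_points")


def _normalise_stem(stem: str) -> str:
    low = stem.lower()
    for suffix in _STEM_SUFFIXES:
        if low.endswith(suffix):
            return low[: len(low) - len(suffix)].rstrip("_-.")
    return low


def pair_structures_predictions(
    structures: Sequence[Structure],
    predictions: Sequence[PocketPointSet],
    manifest: dict[str, str] | None = None,
) -> PairedSet:
    """Match structures to their predictions one-to-one.

    By default a prediction pairs with the structure whose id equals its own
    id after stripping the predictor's filename suffix (``a.pdb`` pairs with
    ``a_probes_r.pdb``).  An explicit ``manifest`` mapping structure id ->
    prediction id overrides the convention entirely.
    """
    by_id = {p.structure_id: p for p in predictions}
    pairs: list[tuple[Structure, PocketPointSet]] = []
    if manifest is not None:
        missing = [s.id for s in structures if s.id not in manifest]
        if missing:
            raise PairingError(f"manifest lacks entries for structures: {missing}")
        for s in structures:
            pid = manifest[s.id]
            if pid not in by_id:
                raise PairingError(f"manifest names unknown prediction {pid!r} for {s.id!r}")
            pred = by_id[pid]
            pairs.append((s, _rebadge(pred, s.id)))
        return PairedSet(pairs)

    if len(structures) != len(predictions):
        raise PairingError(
            f"{len(structures)} structures vs {len(predictions)} predictions; "
            "give a manifest to pair unequal sets"
        )
    norm_pred = {_normalise_stem(p.structure_id): p for p in predictions}
    if len(norm_pred) != len(predictions):
        raise PairingError("prediction filename stems are not unique after normalisation")
    orphans = []
    for s in structures:
        pred = norm_pred.get(s.id.lower())
        if pred is None:
            orphans.append(s.id)
        else:
            pairs.append((s, _rebadge(pred, s.id)))
    if orphans:
        unused = sorted(set(norm_pred) - {s.id.lower() for s in structures})
        raise PairingError(
            f"unpaired structures: {orphans}; unpaired predictions: {unused}"
        )
    return PairedSet(pairs)


def _rebadge(pred: PocketPointSet, structure_id: str) -> PocketPointSet:
    if pred.structure_id == structure_id:
        return pred
    return PocketPointSet(
        structure_id,
        pred.points,
        source=pred.source,
        radii=pred.radii,
        legitimately_empty=pred.legitimately_empty or len(pred.points) == 0,
    )
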