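"""Ensemble pocket-lining probability scoring — the core of the package.

Given matched pairs ``{s_i, d_i}`` of structures and pocket predictions, an
atom k of structure i is *pocket-lining* (``a_ik = 1``) if it lies within a
cutoff distance (default 3.75 Å, inclusive) of any predicted pocket point,
and a residue j is pocket-lining (``r_ij = 1``) if any of its atoms is.

The per-structure binary indicators aggregate into probabilities:

* atom score   ``p_k = (1/n) Σ_i a_ik`` — the proportion of structures in
  which atom k is pocket-lining (same-topology ensembles only);
* residue score ``p_j = (1/n) Σ_i r_ij``, or for homologues aligned at
  column j, ``p_j = (1/n_j) Σ_i r_ij`` where ``n_j`` counts the structures
  contributing a residue (non-gap) at that column;
* residue mean-atom score
  ``p̄_j = (1/n_j) Σ_i (1/l_ij) Σ_k a_ijk`` — the ensemble-averaged fraction
  of the residue's ``l_ij`` atoms that are pocket-lining, well defined even
  when aligned residues differ in atom count.

Columns where no structure has a residue (``n_j = 0``) are reported as
not-scored (NaN), not as zero: the ratio is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError, MappingError, TopologyError
from .pocket_io import PairedSet, PocketPointSet
from .structure_io import Structure

__all__ = [
    "IndicatorVectors",
    "EnsembleScores",
    "score_atoms",
    "ensemble_atom_probability",
    "ensemble_residue_probability",
    "aligned_residue_probability",
    "residue_mean_atom_score",
    "score_ensemble",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 3.75  # Å, atom-to-point distance for pocket-lining


@dataclass
class IndicatorVectors:
    """Per-structure binary pocket-lining indicators.

    ``atom_indicators`` has one entry per atom (length l) and
    ``residue_indicators`` one per residue (length m); a residue scores 1
    iff any of its *included* atoms scores 1.  ``included_mask`` records
    which atoms took part in scoring (hydrogens may be excluded); excluded
    atoms always carry indicator 0 and are left out of mean-atom averages.
    """

    structure_id: str
    atom_indicators: np.ndarray
    residue_indicators: np.ndarray
    cutoff_used: float
    atom_residue_index: np.ndarray  # atom -> residue position, length l
    included_mask: np.ndarray  # bool, length l
    residue_is_amino: np.ndarray  # bool, length m

    def __post_init__(self):
        self.atom_indicators = np.asarray(self.atom_indicators, dtype=np.int8)
        self.residue_indicators = np.asarray(self.residue_indicators, dtype=np.int8)
        if not set(np.unique(self.atom_indicators)) <= {0, 1}:
            raise DataError("atom indicators must be binary")

    @property
    def l(self) -> int:
        return len(self.atom_indicators)

    @property
    def m(self) -> int:
        return len(self.residue_indicators)

    def residue_atom_fractions(self) -> np.ndarray:
        """Fraction of each residue's included atoms that are pocket-lining.

        This is the inner sum ``(1/l_ij) Σ_k a_ijk`` of the mean-atom score.
        """
        idx = self.atom_residue_index[self.included_mask]
        hits = np.bincount(idx, weights=self.atom_indicators[self.included_mask], minlength=self.m)
        counts = np.bincount(idx, minlength=self.m)
        if np.any((counts == 0) & self.residue_is_amino):
            bad = int(np.argmax((counts == 0) & self.residue_is_amino))
            raise DataError(
                f"residue {bad} of {self.structure_id!r} has no included atoms"
            )
        out = np.zeros(self.m)
        nz = counts > 0
        out[nz] = hits[nz] / counts[nz]
        return out


def derive_residue_indicators(iv_atoms: np.ndarray, atom_residue_index: np.ndarray,
                              m: int) -> np.ndarray:
    """Any-atom rule: residue indicator is 1 iff any of its atoms is 1."""
    hits = np.bincount(atom_residue_index, weights=iv_atoms, minlength=m)
    return (hits > 0).astype(np.int8)


def score_atoms(
    structure: Structure,
    points: PocketPointSet,
    cutoff: float = DEFAULT_CUTOFF,
    include_hydrogens: bool = True,
) -> IndicatorVectors:
    """Flag the pocket-lining atoms and residues of one structure.

    An atom is pocket-lining iff its minimum Euclidean distance to any
    pocket point is <= ``cutoff`` (inclusive at the boundary).  A
    legitimately empty prediction yields all-zero indicators.  With
    ``include_hydrogens=False``, hydrogen (and deuterium) atoms always score
    0 and never trigger their residue.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if structure.n_atoms == 0:
        raise DataError(f"structure {structure.id!r} has no atoms")
    coords = structure.coords()
    if not np.all(np.isfinite(coords)):
        raise DataError(f"structure {structure.id!r} has non-finite coordinates")

    included = np.ones(structure.n_atoms, dtype=bool)
    if not include_hydrogens:
        included = np.array([not a.is_hydrogen for a in structure.atoms])

    a = np.zeros(structure.n_atoms, dtype=np.int8)
    if len(points) > 0:
        tree = cKDTree(points.points)
        dist, _ = tree.query(coords)
        a = ((dist <= cutoff) & included).astype(np.int8)

    ari = structure.atom_residue_index()
    r = derive_residue_indicators(a, ari, structure.n_residues)
    # only amino-acid residues are scored at residue level
    amino = np.array([res.is_amino_acid for res in structure.residues])
    r = (r & amino).astype(np.int8)
    return IndicatorVectors(
        structure_id=structure.id,
        atom_indicators=a,
        residue_indicators=r,
        cutoff_used=cutoff,
        atom_residue_index=ari,
        included_mask=included,
        residue_is_amino=amino,
    )


def _check_same_length(vectors: list[np.ndarray], what: str) -> int:
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise TopologyError(f"{what} lengths differ across structures: {sorted(lengths)}")
    return lengths.pop()


def ensemble_atom_probability(indicator_set: list[IndicatorVectors]) -> np.ndarray:
    """p_k: per-atom proportion of structures in which the atom is pocket-lining."""
    if not indicator_set:
        raise ValueError("need at least one structure")
    _check_same_length([iv.atom_indicators for iv in indicator_set], "atom-indicator")
    stack = np.stack([iv.atom_indicators for iv in indicator_set])
    return stack.mean(axis=0)


def ensemble_residue_probability(indicator_set: list[IndicatorVectors]) -> np.ndarray:
    """p_j: per-residue proportion, same-topology ensembles."""
    if not indicator_set:
        raise ValueError("need at least one structure")
    _check_same_length([iv.residue_indicators for iv in indicator_set], "residue-indicator")
    stack = np.stack([iv.residue_indicators for iv in indicator_set])
    return stack.mean(axis=0)


def _column_residue_matrix(indicator_set, alignment_map):
    """(presence, residue-index) matrices per column for the scored structures.

    Reference-only alignment members are dropped here, so they contribute
    to neither the sums nor n_j.
    """
    indicator_set = [
        iv for iv in indicator_set if not alignment_map.is_reference_only(iv.structure_id)
    ]
    if not indicator_set:
        raise MappingError("every structure in the set is flagged reference-only")
    n_cols = alignment_map.columns
    n = len(indicator_set)
    present = np.zeros((n, n_cols), dtype=bool)
    res_at = np.full((n, n_cols), -1, dtype=np.intp)
    for i, iv in enumerate(indicator_set):
        try:
            col_map = alignment_map.column_residues(iv.structure_id)
        except KeyError:
            raise MappingError(
                f"structure {iv.structure_id!r} is missing from the alignment"
            ) from None
        present[i] = col_map >= 0
        res_at[i] = col_map
    return indicator_set, present, res_at


def aligned_residue_probability(indicator_set: list[IndicatorVectors], alignment_map):
    """Per-column p_j for homologue sets: (1/n_j) Σ r_ij over non-gap structures.

    Returns ``(p, n_j)``; columns with ``n_j = 0`` carry NaN (not-scored).
    """
    if not indicator_set:
        raise ValueError("need at least one structure")
    indicator_set, present, res_at = _column_residue_matrix(indicator_set, alignment_map)
    n_cols = alignment_map.columns
    sums = np.zeros(n_cols)
    for i, iv in enumerate(indicator_set):
        cols = np.nonzero(present[i])[0]
        sums[cols] += iv.residue_indicators[res_at[i, cols]]
    n_j = present.sum(axis=0)
    p = np.full(n_cols, np.nan)
    scored = n_j > 0
    p[scored] = sums[scored] / n_j[scored]
    return p, n_j


def residue_mean_atom_score(
    indicator_set: list[IndicatorVectors], alignment_map=None
) -> np.ndarray:
    """p̄_j: ensemble-averaged fraction of each residue's atoms that are pocket-lining.

    Without an alignment map the structures must share topology and the
    average runs over all n structures; with one, each alignment column is
    averaged over the n_j structures contributing a residue there, and
    columns with n_j = 0 carry NaN.
    """
    if not indicator_set:
        raise ValueError("need at least one structure")
    if alignment_map is None:
        fractions = [iv.residue_atom_fractions() for iv in indicator_set]
        _check_same_length(fractions, "residue")
        return np.stack(fractions).mean(axis=0)
    indicator_set, present, res_at = _column_residue_matrix(indicator_set, alignment_map)
    fractions = [iv.residue_atom_fractions() for iv in indicator_set]
    n_cols = alignment_map.columns
    sums = np.zeros(n_cols)
    for i, frac in enumerate(fractions):
        cols = np.nonzero(present[i])[0]
        sums[cols] += frac[res_at[i, cols]]
    n_j = present.sum(axis=0)
    out = np.full(n_cols, np.nan)
    scored = n_j > 0
    out[scored] = sums[scored] / n_j[scored]
    return out


@dataclass
class EnsembleScores:
    """Aggregated pocket-lining probabilities for a set of structures.

    ``mode`` is ``"same_topology"`` (conformer/NMR ensembles: atom scores
    available, index = residue identifiers of the shared topology) or
    ``"aligned"`` (homologues: scores per alignment column, 1-based column
    numbers as index, per-column structure counts in ``n_j``).
    """

    mode: str
    n: int
    residue_probs: np.ndarray
    residue_mean_atom: np.ndarray
    index: list
    atom_probs: np.ndarray | None = None
    n_j: np.ndarray | None = None
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.mode not in ("same_topology", "aligned"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for v in (self.residue_probs, self.residue_mean_atom, self.atom_probs):
            if v is not None:
                finite = v[np.isfinite(v)]
                if np.any((finite < 0) | (finite > 1)):
                    raise DataError("probabilities must lie in [0, 1]")
        if self.n_j is None:
            self.n_j = np.full(len(self.residue_probs), self.n, dtype=int)

    def residue_table(self) -> pd.DataFrame:
        """One row per residue/column: identifier, n_j, p_res, p_res_mean_atom."""
        return pd.DataFrame(
            {
                "identifier": [str(i) for i in self.index],
                "n_j": self.n_j,
                "p_res": self.residue_probs,
                "p_res_mean_atom": self.residue_mean_atom,
            }
        )

    def atom_table(self, structure: Structure) -> pd.DataFrame:
        """One row per atom of the shared topology (same-topology mode only)."""
        if self.atom_probs is None:
            raise ValueError("atom-level scores are only defined in same_topology mode")
        rows = []
        k = 0
        for res in structure.residues:
            for atom in res.atoms:
                rows.append(
                    (k, res.chain_id, res.seq_num, res.icode, atom.name, self.atom_probs[k])
                )
                k += 1
        return pd.DataFrame(
            rows, columns=["atom_index", "chain", "resnum", "icode", "atom_name", "p_atom"]
        )


def score_ensemble(
    paired: PairedSet,
    cutoff: float = DEFAULT_CUTOFF,
    include_hydrogens: bool = True,
    alignment_map=None,
) -> EnsembleScores:
    """Score every pair and aggregate into ensemble probabilities.

    Same-topology mode (no alignment map) additionally yields per-atom
    probabilities; aligned mode scores per alignment column with per-column
    denominators n_j.
    """
    indicator_set = [
        score_atoms(s, d, cutoff=cutoff, include_hydrogens=include_hydrogens)
        for s, d in paired
    ]
    if alignment_map is None:
        first = paired.pairs[0][0]
        return EnsembleScores(
            mode="same_topology",
            n=paired.n,
            atom_probs=ensemble_atom_probability(indicator_set),
            residue_probs=ensemble_residue_probability(indicator_set),
            residue_mean_atom=residue_mean_atom_score(indicator_set),
            index=[f"{r.chain_id}:{r.seq_num}{r.icode}" for r in first.residues],
            cutoff=cutoff,
        )
    p, n_j = aligned_residue_probability(indicator_set, alignment_map)
    pbar = residue_mean_atom_score(indicator_set, alignment_map)
    n_scored = sum(
        1 for iv in indicator_set if not alignment_map.is_reference_only(iv.structure_id)
    )
    return EnsembleScores(
        mode="aligned",
        n=n_scored,
        residue_probs=p,
        residue_mean_atom=pbar,
        n_j=n_j,
        index=list(range(1, alignment_map.columns + 1)),
        cutoff=cutoff,
    )
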