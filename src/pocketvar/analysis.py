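"""Binding-site/interface definitions and evaluation metrics.

A binding site or protein-protein interface is defined purely geometrically:
the non-hydrogen atoms of the reference protein within 4.5 Å (inclusive) of
any non-hydrogen atom of the binding partner.  On top of such atom subsets
the module provides the metrics used to characterise ensemble pocket scores:

* the percentage of a site's atoms whose score exceeds a threshold
  (e.g. > 0.25 "variably pocket-lining", > 0.75 "persistently pocket-lining");
* quartile-based selection of *persistent* (score >= Q3 of the non-zero
  score distribution) and *variable* (Q1 <= score < Q3) residues;
* confusion-matrix enrichment of a selected residue set against the
  interface residues (sensitivity, specificity, positive predictive value);
* a two-sided rank-sum comparison of the score distribution of a subset
  (e.g. binding-site atoms) against a background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

from .errors import DataError, DegenerateDistributionError
from .structure_io import Structure

__all__ = [
    "AtomSubset",
    "SelectionReport",
    "define_interface",
    "fraction_above_threshold",
    "quartile_selection",
    "interface_enrichment",
    "compare_distributions",
    "interface_residues",
    "DEFAULT_INTERFACE_CUTOFF",
]

DEFAULT_INTERFACE_CUTOFF = 4.5  # Å, heavy atom to heavy atom


@dataclass
class AtomSubset:
    """A labelled set of heavy-atom indices on a reference structure."""

    label: str
    atom_indices: np.ndarray
    definition_cutoff: float

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=np.intp)
        if len(self.atom_indices) == 0:
            raise DataError(f"atom subset {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.atom_indices)


def define_interface(
    reference: Structure,
    partner_atoms: np.ndarray,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
    label: str = "interface",
) -> AtomSubset:
    """Heavy atoms of ``reference`` within ``cutoff`` of any partner heavy atom.

    ``partner_atoms`` are the partner's heavy-atom coordinates, shape (p, 3).
    The boundary is inclusive: an atom at exactly the cutoff distance is in.
    """
    partner = np.asarray(partner_atoms, dtype=float).reshape(-1, 3)
    if len(partner) == 0:
        raise DataError("empty partner atom set")
    if not np.all(np.isfinite(partner)):
        raise DataError("non-finite partner coordinates")
    heavy = np.array([not a.is_hydrogen for a in reference.atoms])
    coords = reference.coords()
    dist, _ = cKDTree(partner).query(coords)
    members = np.nonzero(heavy & (dist <= cutoff))[0]
    if len(members) == 0:
        raise DataError(
            f"no atoms of {reference.id!r} within {cutoff} Å of the partner"
        )
    return AtomSubset(label, members, cutoff)


def interface_residues(reference: Structure, subset: AtomSubset) -> set:
    """Residue keys with at least one heavy atom in the subset (any-atom rule)."""
    ari = reference.atom_residue_index()
    res_idx = sorted(set(ari[subset.atom_indices].tolist()))
    return {reference.residues[j].key for j in res_idx}


def fraction_above_threshold(
    scores: np.ndarray,
    subset: AtomSubset,
    threshold: float,
    strict: bool = True,
) -> float:
    """Percentage of subset atoms with score above a threshold.

    ``strict=True`` uses the strict inequality ``p > t`` (as in
    "score > 0.75"); ``strict=False`` uses ``p >= t``.
    """
    scores = np.asarray(scores, dtype=float)
    if np.max(subset.atom_indices) >= len(scores):
        raise DataError("subset refers to atoms beyond the score vector")
    sub = scores[subset.atom_indices]
    if np.any(~np.isfinite(sub)):
        raise DataError("subset contains unscored atoms")
    hits = np.sum(sub > threshold) if strict else np.sum(sub >= threshold)
    return 100.0 * float(hits) / len(sub)


@dataclass
class SelectionReport:
    """Persistent/variable residue selection from a score distribution.

    Quartiles are computed on the *non-zero* scores only (zeros mean "never
    pocket-lining" and would otherwise dominate the distribution).
    Persistent members have score >= Q3 (the top quarter, inclusive);
    variable members fall in [Q1, Q3).  ``threshold_used`` is the numeric Q3
    cut actually applied, reported so selections from different ensembles or
    predictors can be compared.
    """

    persistent_set: set = field(default_factory=set)
    variable_set: set = field(default_factory=set)
    q1: float = float("nan")
    median: float = float("nan")
    q3: float = float("nan")
    threshold_used: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "threshold_used": self.threshold_used,
            "n_persistent": len(self.persistent_set),
            "n_variable": len(self.variable_set),
            "persistent": sorted(map(str, self.persistent_set)),
            "variable": sorted(map(str, self.variable_set)),
        }


def quartile_selection(
    scores: np.ndarray, ids: Sequence[Hashable] | None = None
) -> SelectionReport:
    """Classify residues/columns as persistent or variable by score quartiles.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" rule).  NaN scores (not-scored columns) and zeros
    are excluded from the distribution and from both sets.  Fewer than four
    non-zero scores make the quartiles meaningless and raise.
    """
    scores = np.asarray(scores, dtype=float)
    if ids is None:
        ids = list(range(len(scores)))
    if len(ids) != len(scores):
        raise ValueError("ids and scores length mismatch")
    finite = np.isfinite(scores)
    nonzero = finite & (scores > 0)
    values = scores[nonzero]
    if len(values) < 4:
        raise DegenerateDistributionError(
            f"need at least 4 non-zero scores for quartiles, got {len(values)}"
        )
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    persistent = {i for i, s, nz in zip(ids, scores, nonzero) if nz and s >= q3}
    variable = {i for i, s, nz in zip(ids, scores, nonzero) if nz and q1 <= s < q3}
    return SelectionReport(
        persistent_set=persistent,
        variable_set=variable,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        threshold_used=float(q3),
    )


def interface_enrichment(
    selected: Iterable[Hashable],
    interface_members: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> dict:
    """Confusion matrix of a selected residue set against interface residues.

    ``universe`` is the full set of scored residues the selection was drawn
    from.  Returns TP/FP/FN/TN plus sensitivity TP/(TP+FN), specificity
    TN/(TN+FP) and positive predictive value TP/(TP+FP), each as a fraction
    and as a percentage.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    selected = set(selected)
    interface = set(interface_members)
    if not selected <= universe:
        raise DataError("selected set is not contained in the universe")
    if not interface <= universe:
        raise DataError("interface set is not contained in the universe")
    tp = len(selected & interface)
    fp = len(selected - interface)
    fn = len(interface - selected)
    tn = len(universe) - tp - fp - fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "ppv_pct": 100.0 * ppv,
    }


def compare_distributions(
    scores_subset: np.ndarray, scores_background: np.ndarray
) -> dict:
    """Two-sided rank-sum (Mann-Whitney U) comparison of two score samples.

    Reports the U statistic, p-value and the direction of the location shift
    ("subset higher" / "subset lower" / "none").  Fully tied input (every
    value identical across both samples) is flagged degenerate; the statistic
    is still returned with p = 1.
    """
    a = np.asarray(scores_subset, dtype=float)
    b = np.asarray(scores_background, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both samples must be non-empty")
    degenerate = len(np.unique(np.concatenate([a, b]))) == 1
    if degenerate:
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        u, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    expected = len(a) * len(b) / 2.0
    if degenerate or u == expected:
        direction = "none"
    else:
        direction = "subset higher" if u > expected else "subset lower"
    return {
        "statistic": float(u),
        "p_value": float(p),
        "direction": direction,
        "degenerate": degenerate,
        "n_subset": len(a),
        "n_background": len(b),
    }
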