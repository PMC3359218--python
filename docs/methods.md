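# Methods

## Model

pocketvar treats pocket prediction post-processing as a counting problem.
A predictor's output for one structure is reduced to a bare point cloud
(sphere centres); an atom is *pocket-lining* if its minimum Euclidean
distance to any point is at most the cutoff, and a residue is pocket-lining
if any of its atoms is (the "any-atom" rule). Per-structure binary
indicators are averaged over the set: the score of an atom, residue or
alignment column is simply the fraction of structures in which it is
pocket-lining, and the mean-atom variant averages, per residue, the
fraction of its atoms that line a pocket. Nothing is fitted; the scheme's
value is that it is pocket-agnostic (no pocket boundaries are ever drawn)
and orientation-free (each prediction is compared only with its own
structure's coordinates, so no superposition is needed or performed).

Consequences worth keeping in mind: the residue score dominates both the
maximum atom score within the residue and the mean-atom score
(r_ij ≥ a_ik for every atom of the residue, hence p_j ≥ max_k p_k and
p̄_j ≤ p_j); scores are monotone in the cutoff; and they are invariant to
the order of the structures.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pocket-lining cutoff | 3.75 | Å | atom-to-point distance; the comparison is *inclusive* at the boundary (the usual reading of "within"); distances are measured to sphere centres, radii are metadata only |
| interface cutoff | 4.5 | Å | heavy-atom to heavy-atom distance defining binding sites and protein–protein interfaces; also inclusive |
| hydrogens | included | — | protonated ensembles score hydrogens like any atom; `include_hydrogens=False` removes them from both the indicators and the mean-atom denominator l_ij (an atom that can never score should not dilute the residue average); interface definitions are always heavy-atom-only |
| score thresholds | 0.25, 0.75 | — | reporting thresholds for "variably" and "persistently" pocket-lining atoms; strict `>` comparisons |
| quartile rule | type 7 | — | linear interpolation between order statistics (numpy default), computed on non-zero scores only; persistence is inclusive (score ≥ Q3), the variable band is [Q1, Q3) |

## Homologue mode

Homologues are compared through a user-supplied multiple sequence alignment
built on the *observed* sequences (the residues actually present with
coordinates). The package never computes alignments — aligner choice
materially affects the result and belongs upstream. At map construction
every row is checked letter-by-letter against the structure's observed
sequence ('X' matches anything; an optional mismatch budget exists for
known header drift and is reported loudly). Columns where no scored
structure has a residue are *not-scored* (NaN), never 0, because the
n_j-denominated ratio is undefined there; when such residues are written
into a display structure's B-factors they appear as 0.00 with a sidecar
file naming them. Alignment rows can be flagged *reference-only*: they get
a column mapping so ensemble scores can be projected onto that structure
for display, but they are excluded from every sum and from n_j.

## File handling

PDB ATOM/HETATM records are read with a small fixed-column codec that keeps
each atom's verbatim source line. This is deliberate: the score writer
replaces only columns 61–66 (the temperature factor) with 100 × score,
fixed width, two decimals, clipped at 99.99 so the value always fits the
field, and reproduces every other byte of a well-formed input unchanged.
Altloc duplicates keep the highest-occupancy copy (ties: alphabetically
first id); multi-model files default to MODEL 1, with an explicit reader
that yields every model as an ensemble member. HETATM records of common
modified amino acids (MSE, SEP, ...) are read as protein; all other
HETATM entities are dropped and never receive residue scores.

Predictor dialects: PASS final-layer probe files and LIGSITE-cs centroid
files are plain coordinate lists; fpocket output is filtered to its
alpha-sphere records (residue name STP); anything else PDB-shaped goes
through the generic reader, which is also the oracle the dialect readers
are tested against. Pocket/cluster ids present in these files are
discarded by design. A predictor that ran successfully but found no
pockets is distinct from a parse failure: in memory it is an explicitly
empty point set, on disk a file whose only content is the marker
`REMARK NO POCKET POINTS`. By default the pipeline skips-and-logs
structures whose prediction file is unusable (predictors do fail on a few
members of large sets); `--strict` aborts instead.

## Synthetic fixtures

The generator emulates the *shape* of real inputs — conformer ensembles,
homologue families with indels and their alignment, predictor point clouds —
not their physics. Structures are extended chains: residues 8 Å apart
along x, atoms 1.5 Å apart along y, conformers perturbed by per-coordinate
Gaussian noise (default 0.5 Å, truncated at 3.8 σ). Planted pockets put one
point 3 Å along z from every atom of each target residue, so with the
default cutoff a point can only ever reach its own residue (nearest
non-target atom > 8.5 Å before perturbation; the truncation preserves the
separation for amplitudes up to ~0.9 Å). A pocket "present in fraction f"
is emitted in exactly round(f·n) members chosen by the seeded generator, so
planted-recovery checks are exact, not statistical. All randomness comes
from NumPy's PCG64 generator in a fixed draw order; a fixed seed gives
byte-identical files on any platform.

What passing these tests shows: the bookkeeping — distances, indicator
logic, denominators, alignment mapping, file round-trips — is exactly
right. What it does not show: anything about the quality of upstream
pocket predictors or aligners on real proteins, which the scheme
deliberately takes as given.

## Numerical and design notes

- Neighbour search uses a k-d tree over the pocket points; its contract
  with the exhaustive atom×point double loop is exact equality, not
  approximation, and is enforced in tests over randomized instances.
- Probabilities are exact rational multiples of 1/n (or 1/n_j) computed in
  double precision; no tolerance games are needed downstream.
- The rank-based location test (`compare_distributions`) is the two-sided
  Mann–Whitney U with asymptotic p-values and tie correction; fully tied
  input is flagged degenerate and returned with p = 1 rather than raised.
- Quartile selection refuses fewer than four non-zero scores rather than
  reporting meaningless quantiles.
- Enrichment metrics use specificity = TN/(TN+FP) with the universe taken
  as all scored amino-acid residues of the reference chain — the natural
  denominator when the whole chain was scored.
- Structure/prediction pairing is by filename stem (predictor suffixes like
  `_probes_r`, `_pocket_r`, `_points` are stripped); an explicit two-column
  manifest overrides it.
- Acceptance-scale problem sizes (ensembles of 100 twelve-residue chains,
  200 randomized oracle instances) are the package's chosen verification
  scale: large enough to exercise every code path and gap pattern, small
  enough that the whole suite reruns in seconds.

## Known limitations

- PDB format only; no mmCIF, no structure repair, no superposition (the
  last by design).
- Residue-level scores are only defined for amino-acid residues; nucleic
  acids and ligands are ignored.
- Chain-to-alignment-row matching is by structure id; multi-chain entries
  should be reduced to the chain of interest upstream.
- The mean-atom score in homologue mode averages over whatever atoms each
  deposited structure resolves; systematically missing side chains bias it
  low for the affected residues.
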