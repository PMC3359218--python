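# pocketvar

Probabilistic scoring of pocket-lining atoms and residues across ensembles of
related protein structures.

## The problem

Geometric pocket predictors (PASS, LIGSITE-cs, fpocket, SiteMap, ...) emit a
cloud of probe-sphere centres for a *single* static structure. Proteins are
dynamic: pockets open, close and reshape across conformers, NMR models and
homologues, and comparing raw point clouds across structures is confounded by
global-orientation differences and by the ill-posed question of where one
pocket ends and the next begins. pocketvar sidesteps both problems by mapping
each prediction onto the atoms of *its own* structure and aggregating the
per-structure binary flags into probabilities — no superposition, no pocket
delimitation.

It is aimed at structural bioinformaticians characterising binding sites,
cryptic or transient pockets, and druggable protein–protein interfaces from
simulated ensembles or homologous superfamilies.

## The scoring scheme

For matched pairs {s_i, d_i} of structures and predictions, atom *k* of
structure *i* is pocket-lining (a_ik = 1) if it lies within a cutoff
(default 3.75 Å, inclusive) of any predicted pocket point; residue *j* is
pocket-lining (r_ij = 1) if any of its atoms is. Aggregating over the *n*
structures:

- atom probability (same-topology ensembles):  p_k = (1/n) Σ_i a_ik
- residue probability:                        p_j = (1/n) Σ_i r_ij
- homologues, per alignment column *j*:        p_j = (1/n_j) Σ_i r_ij,
  where n_j counts structures with a residue (non-gap) at that column
- residue mean-atom score:  p̄_j = (1/n_j) Σ_i (1/l_ij) Σ_k a_ijk,
  the ensemble-averaged fraction of the residue's l_ij atoms that line a
  pocket — well defined even when aligned residues differ in atom count.

Scores are written as percentages into the B-factor column of a chosen
display structure for surface rendering, and evaluated against geometrically
defined binding sites/interfaces (heavy atoms within 4.5 Å of partner heavy
atoms), with quartile-based selection of *persistent* (score ≥ Q3 of the
non-zero distribution) and *variable* (Q1 ≤ score < Q3) pocket residues.

## Worked example

Generate a synthetic 10-member conformer ensemble in which a 3-residue
pocket is present in half the members, score it, and inspect the output:

```
pocketvar fixtures -o fx --n-members 10 --presence 0.5 --seed 5 --dialect fpocket
pocketvar score -s fx/conf_0000.pdb ... -s fx/conf_0009.pdb \
                -p fx/conf_0000_points.pdb ... -p fx/conf_0009_points.pdb \
                --format fpocket -o out
```

`out/residue_scores.tsv` then contains (non-zero rows shown):

```
identifier  n_j  p_res     p_res_mean_atom
A:10        10   0.500000  0.500000
A:11        10   0.500000  0.500000
A:12        10   0.500000  0.500000
```

The pocket was emitted in 5 of the 10 members, so the three target
residues are pocket-lining in exactly 50 % of the ensemble (p_j = 0.50)
and every atom of those residues lines the pocket whenever it is present
(p̄_j = p_j); all other residues score 0. The coloured PDB
`out/conf_0000_residue_scores.pdb` carries these values as percentages in
its B-factor column (`50.00` on the target residues), ready for rendering in
any molecular-graphics program. `pocketvar report --partner partner.pdb ...`
additionally prints interface fractions, quartile selections and
sensitivity/specificity of persistent pockets at the interface.

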