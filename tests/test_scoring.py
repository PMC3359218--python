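"""Indicator scoring and the four ensemble aggregation rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketvar import (
    DataError,
    MappingError,
    PocketPointSet,
    TopologyError,
    aligned_residue_probability,
    ensemble_atom_probability,
    ensemble_residue_probability,
    read_pdb_string,
    residue_mean_atom_score,
    score_atoms,
)
from pocketvar.alignment import AlignmentMap

from conftest import brute_force_indicators, make_indicators, random_structure


def _one_atom_structure(xyz=(0.0, 0.0, 0.0)):
    x, y, z = xyz
    text = (
        f"ATOM      1  CA  ALA A   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\nEND\n"
    )
    return read_pdb_string(text, "one")


class TestScoreAtoms:
    @pytest.mark.parametrize(
        "point_z,expected",
        [(3.0, 1), (4.0, 0), (3.75, 1)],  # 3.75 pins the inclusive boundary
    )
    def test_cutoff_boundary(self, point_z, expected):
        s = _one_atom_structure()
        pts = PocketPointSet("one", np.array([[0.0, 0.0, point_z]]))
        iv = score_atoms(s, pts, cutoff=3.75)
        assert iv.atom_indicators[0] == expected
        assert iv.residue_indicators[0] == expected

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            s = random_structure(rng, n_residues=10, atoms_per_residue=5)
            pts = PocketPointSet(s.id, rng.uniform(-12, 12, (20, 3)))
            iv = score_atoms(s, pts, cutoff=3.75)
            expected = brute_force_indicators(s.coords(), pts.points, 3.75)
            np.testing.assert_array_equal(iv.atom_indicators, expected)

    def test_any_atom_rule_for_residues(self, rng):
        s = random_structure(rng, n_residues=6, atoms_per_residue=4)
        pts = PocketPointSet(s.id, rng.uniform(-12, 12, (8, 3)))
        iv = score_atoms(s, pts)
        ari = s.atom_residue_index()
        for j in range(s.n_residues):
            assert iv.residue_indicators[j] == int(iv.atom_indicators[ari == j].any())

    def test_legitimate_empty_scores_zero(self):
        s = _one_atom_structure()
        iv = score_atoms(s, PocketPointSet.empty("one"))
        assert iv.atom_indicators.sum() == 0 and iv.residue_indicators.sum() == 0

    def test_excluded_hydrogens_never_trigger(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  HA  ALA A   1       0.000   0.000   2.000  1.00  0.00           H\n"
            "END\n"
        )
        s = read_pdb_string(text, "h")
        pts = PocketPointSet("h", np.array([[0.0, 0.0, 5.0]]))  # 3.0 from H, 5.0 from CA
        with_h = score_atoms(s, pts, cutoff=3.75, include_hydrogens=True)
        without_h = score_atoms(s, pts, cutoff=3.75, include_hydrogens=False)
        assert with_h.atom_indicators.tolist() == [0, 1]
        assert with_h.residue_indicators.tolist() == [1]
        assert without_h.atom_indicators.tolist() == [0, 0]
        assert without_h.residue_indicators.tolist() == [0]

    def test_non_amino_residue_never_scored(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  C1  LIG A   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        s = read_pdb_string(text, "lig")
        pts = PocketPointSet("lig", np.array([[0.5, 0.0, 0.0]]))
        iv = score_atoms(s, pts)
        assert iv.atom_indicators.tolist() == [1, 1]
        assert iv.residue_indicators.tolist() == [1, 0]

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            score_atoms(_one_atom_structure(), PocketPointSet.empty("one"), cutoff=0)


class TestEnsembleAveraging:
    def test_atom_probability_proportion(self):
        ivs = [make_indicators([a], [0], 1, structure_id=f"s{i}") for i, a in enumerate([1, 1, 0, 1])]
        np.testing.assert_allclose(ensemble_atom_probability(ivs), [0.75])

    def test_single_structure_identity(self, rng):
        a = rng.integers(0, 2, 12)
        iv = make_indicators(a, np.repeat(np.arange(4), 3), 4)
        np.testing.assert_array_equal(ensemble_atom_probability([iv]), a)
        np.testing.assert_array_equal(
            ensemble_residue_probability([iv]), iv.residue_indicators
        )

    def test_residue_probability_13_of_50(self):
        ivs = [
            make_indicators([1 if i < 13 else 0], [0], 1, structure_id=f"c{i}")
            for i in range(50)
        ]
        np.testing.assert_allclose(ensemble_residue_probability(ivs), [0.26])

    def test_counting_oracle_random_ensemble(self, rng):
        n, l, m = 10, 20, 5
        ari = np.repeat(np.arange(m), l // m)
        ivs = [make_indicators(rng.integers(0, 2, l), ari, m) for _ in range(n)]
        p_atom = ensemble_atom_probability(ivs)
        p_res = ensemble_residue_probability(ivs)
        for k in range(l):
            assert p_atom[k] == sum(iv.atom_indicators[k] for iv in ivs) / n
        for j in range(m):
            assert p_res[j] == sum(iv.residue_indicators[j] for iv in ivs) / n

    def test_length_mismatch_is_topology_error(self):
        ivs = [
            make_indicators([1, 0], [0, 0], 1),
            make_indicators([1, 0, 1], [0, 0, 0], 1),
        ]
        with pytest.raises(TopologyError):
            ensemble_atom_probability(ivs)


class TestMeanAtomScore:
    def test_two_structure_arithmetic(self):
        # one residue, three atoms: [1,0,0] then [1,1,0] -> (1/2)(1/3 + 2/3)
        ivs = [
            make_indicators([1, 0, 0], [0, 0, 0], 1, structure_id="a"),
            make_indicators([1, 1, 0], [0, 0, 0], 1, structure_id="b"),
        ]
        np.testing.assert_allclose(residue_mean_atom_score(ivs), [0.5])

    def test_fully_lining_single_structure(self):
        iv = make_indicators([1, 1, 1], [0, 0, 0], 1)
        np.testing.assert_allclose(residue_mean_atom_score([iv]), [1.0])

    def test_direct_summation_oracle(self, rng):
        n, m, apr = 7, 6, 4
        ari = np.repeat(np.arange(m), apr)
        ivs = [make_indicators(rng.integers(0, 2, m * apr), ari, m) for _ in range(n)]
        expected = np.zeros(m)
        for j in range(m):
            expected[j] = sum(
                iv.atom_indicators[ari == j].mean() for iv in ivs
            ) / n
        np.testing.assert_allclose(residue_mean_atom_score(ivs), expected)

    def test_never_exceeds_any_atom_rule(self, rng):
        ari = np.repeat(np.arange(5), 3)
        ivs = [make_indicators(rng.integers(0, 2, 15), ari, 5) for _ in range(8)]
        pbar = residue_mean_atom_score(ivs)
        p_res = ensemble_residue_probability(ivs)
        assert np.all(pbar <= p_res + 1e-12)


def _map_for(maps, columns):
    return AlignmentMap(
        columns=columns,
        maps={k: np.asarray(v, dtype=np.intp) for k, v in maps.items()},
        display_ids={k: k for k in maps},
    )


class TestAlignedProbability:
    def test_column_present_in_two_of_three(self):
        # column 0: structures a (lining) and b (not); c is gapped there
        amap = _map_for({"a": [0], "b": [0], "c": [-1]}, columns=1)
        ivs = [
            make_indicators([1], [0], 1, structure_id="a"),
            make_indicators([0], [0], 1, structure_id="b"),
            make_indicators([0], [0], 1, structure_id="c"),
        ]
        p, n_j = aligned_residue_probability(ivs, amap)
        assert n_j.tolist() == [2]
        np.testing.assert_allclose(p, [0.5])

    def test_all_gap_column_not_scored(self):
        amap = _map_for({"a": [0, -1], "b": [0, -1]}, columns=2)
        ivs = [
            make_indicators([1], [0], 1, structure_id="a"),
            make_indicators([1], [0], 1, structure_id="b"),
        ]
        p, n_j = aligned_residue_probability(ivs, amap)
        assert n_j.tolist() == [2, 0]
        assert p[0] == 1.0 and np.isnan(p[1])

    def test_missing_structure_is_mapping_error(self):
        amap = _map_for({"a": [0]}, columns=1)
        ivs = [make_indicators([1], [0], 1, structure_id="zzz")]
        with pytest.raises(MappingError):
            aligned_residue_probability(ivs, amap)

    def test_brute_force_on_random_gapped_set(self, rng):
        n, columns = 5, 12
        maps, ivs = {}, []
        for i in range(n):
            present = rng.random(columns) > 0.3
            col_map = np.full(columns, -1, dtype=np.intp)
            col_map[present] = np.arange(present.sum())
            sid = f"h{i}"
            maps[sid] = col_map
            ivs.append(
                make_indicators(
                    rng.integers(0, 2, int(present.sum())),
                    np.arange(present.sum()),
                    int(present.sum()),
                    structure_id=sid,
                )
            )
        p, n_j = aligned_residue_probability(ivs, _map_for(maps, columns))
        for c in range(columns):
            contrib = [
                iv.residue_indicators[maps[iv.structure_id][c]]
                for iv in ivs
                if maps[iv.structure_id][c] >= 0
            ]
            assert n_j[c] == len(contrib)
            if contrib:
                assert p[c] == pytest.approx(sum(contrib) / len(contrib))
            else:
                assert np.isnan(p[c])


# --- randomized structural invariants -------------------------------------

indicator_arrays = st.integers(2, 6).flatmap(
    lambda m: st.lists(
        st.lists(st.integers(0, 1), min_size=3 * m, max_size=3 * m),
        min_size=1,
        max_size=8,
    ).map(lambda rows: (m, rows))
)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(indicator_arrays)
def test_probabilities_are_order_invariant_and_bounded(data):
    """Ensemble scores ignore structure order and stay within [0, 1]."""
    m, rows = data
    ari = np.repeat(np.arange(m), 3)
    ivs = [make_indicators(row, ari, m, structure_id=f"s{i}") for i, row in enumerate(rows)]
    p_atom = ensemble_atom_probability(ivs)
    p_res = ensemble_residue_probability(ivs)
    pbar = residue_mean_atom_score(ivs)
    perm = ivs[::-1]
    np.testing.assert_allclose(ensemble_atom_probability(perm), p_atom)
    np.testing.assert_allclose(ensemble_residue_probability(perm), p_res)
    np.testing.assert_allclose(residue_mean_atom_score(perm), pbar)
    for v in (p_atom, p_res, pbar):
        assert np.all((v >= 0) & (v <= 1))
    # residue dominance: any-atom rule bounds both atom scores and atom means
    for j in range(m):
        assert p_res[j] >= p_atom[ari == j].max() - 1e-12
        assert pbar[j] <= p_res[j] + 1e-12


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 6))
def test_monotone_in_cutoff_and_duplicate_limit(seed, n_copies):
    """Indicators only grow with the cutoff; duplicated pairs reproduce themselves."""
    rng = np.random.default_rng(seed)
    s = random_structure(rng, n_residues=4, atoms_per_residue=3)
    pts = PocketPointSet(s.id, rng.uniform(-12, 12, (6, 3)))
    cut_small, cut_big = sorted(rng.uniform(0.5, 8.0, 2))
    small = score_atoms(s, pts, cutoff=cut_small)
    big = score_atoms(s, pts, cutoff=cut_big)
    assert np.all(small.atom_indicators <= big.atom_indicators)
    assert np.all(small.residue_indicators <= big.residue_indicators)
    copies = [score_atoms(s, pts) for _ in range(n_copies)]
    np.testing.assert_array_equal(
        ensemble_atom_probability(copies), copies[0].atom_indicators
    )
    np.testing.assert_array_equal(
        ensemble_residue_probability(copies), copies[0].residue_indicators
    )


def test_nan_coordinate_is_data_error():
    s = _one_atom_structure()
    s.atoms[0].coord[0] = np.nan
    with pytest.raises(DataError):
        score_atoms(s, PocketPointSet("one", np.zeros((1, 3))))
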