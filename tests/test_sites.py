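"""Geometry of the zinc-site search: coordinators, cliques, density, ranking."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ionbind.sites import (GeometryParams, GridBudgetError, VdwTableError,
                           DensityGrid, apply_vdw_exclusion,
                           build_density_grid, coordination_shell,
                           find_cliques, predict_metal_sites, rank_sites,
                           select_coordinators)
from ionbind.structure import ProteinStructure
from ionbind.synthetic import gen_toy_structure
from ionbind.benchmarks import load_structure_from_text

from conftest import TETRAHEDRON, make_atom, make_structure

PARAMS = GeometryParams()


# --- coordinator selection --------------------------------------------------

def test_select_coordinators_membership():
    st = make_structure([
        make_atom("CA", [0, 0, 0], element="C"),
        make_atom("OD1", [1, 0, 0]),
        make_atom("NZ", [2, 0, 0], residue="LYS"),
    ])
    assert [a.atom_name for a in select_coordinators(st)] == ["OD1"]


def test_select_coordinators_full_asp_residue():
    # brute-force membership: of a complete Asp residue only the backbone
    # carbonyl O and the two carboxylate oxygens are chelator-eligible
    names = ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"]
    st = make_structure([
        make_atom(n, [i * 1.5, 0, 0], residue="ASP", element=n[0])
        for i, n in enumerate(names)])
    expected = [n for n in names if n in PARAMS.coordinator_atom_names]
    assert [a.atom_name for a in select_coordinators(st)] == expected == ["O", "OD1", "OD2"]


def test_select_coordinators_cysteine_sulfur_and_exclusions():
    st = make_structure([
        make_atom("SG", [0, 0, 0], residue="CYS", element="S"),
        make_atom("O", [3, 0, 0], residue="LIG", het=True),   # hetero "O": no
        make_atom("O", [6, 0, 0], residue="HOH", het=True),   # water: no
        make_atom("O", [9, 0, 0], residue="GLY"),             # backbone: yes
    ])
    assert [a.atom_name for a in select_coordinators(st)] == ["SG", "O"]
    assert select_coordinators(st)[0].element == "S"


# --- cliques ----------------------------------------------------------------

def _brute_force_maximal_cliques(positions, cutoff, min_size):
    n = len(positions)
    def is_clique(subset):
        return all(np.linalg.norm(positions[i] - positions[j]) < cutoff
                   for i, j in itertools.combinations(subset, 2))
    cliques = []
    for size in range(min_size, n + 1):
        for subset in itertools.combinations(range(n), size):
            if not is_clique(subset):
                continue
            if any(is_clique(subset + (k,)) for k in range(n) if k not in subset):
                continue  # not maximal
            cliques.append(frozenset(subset))
    return set(cliques)


def test_find_cliques_trivial_cases():
    two = [make_atom("OD1", [0, 0, 0], seq=1), make_atom("OD1", [2, 0, 0], seq=2)]
    assert find_cliques(two, PARAMS) == []
    far = [make_atom("OD1", [0, 0, 0], seq=1), make_atom("OD1", [3, 0, 0], seq=2),
           make_atom("OD1", [6.5, 0, 0], seq=3)]
    assert find_cliques(far, PARAMS) == []


def test_find_cliques_tetrahedron_single_clique():
    scale = 2.5 / np.linalg.norm(TETRAHEDRON[0] - TETRAHEDRON[1])
    atoms = [make_atom("OD1", scale * d, seq=i + 1)
             for i, d in enumerate(TETRAHEDRON)]
    cliques = find_cliques(atoms, PARAMS)
    assert len(cliques) == 1 and len(cliques[0]) == 4


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_find_cliques_matches_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    pos = rng.uniform(0, 9.0, size=(n, 3))
    atoms = [make_atom("OD1", p, seq=i + 1) for i, p in enumerate(pos)]
    got = {frozenset(a.residue_seq - 1 for a in c.member_atoms)
           for c in find_cliques(atoms, PARAMS)}
    expected = _brute_force_maximal_cliques(pos, PARAMS.clique_pair_max,
                                            PARAMS.clique_min_size)
    assert got == expected


def test_adding_atoms_never_removes_cliques():
    rng = np.random.default_rng(7)
    pos = rng.uniform(0, 6.0, size=(6, 3))
    atoms = [make_atom("OD1", p, seq=i + 1) for i, p in enumerate(pos)]
    base = {frozenset(a.site_key for a in c.member_atoms)
            for c in find_cliques(atoms, PARAMS)}
    extra = atoms + [make_atom("OD1", rng.uniform(0, 6.0, 3), seq=100 + i)
                     for i in range(3)]
    grown = [frozenset(a.site_key for a in c.member_atoms)
             for c in find_cliques(extra, PARAMS)]
    # every original clique survives, possibly absorbed into a larger one
    for clique in base:
        assert any(clique <= g for g in grown)


# --- density grid -----------------------------------------------------------

def test_density_counts_match_bruteforce_oracle(tetra_site_structure):
    coords = select_coordinators(tetra_site_structure)
    cliques = find_cliques(coords, PARAMS)
    grid = build_density_grid(tetra_site_structure, cliques, PARAMS)
    pos = np.array([a.position for a in coords])
    rng = np.random.default_rng(11)
    shape = np.array(grid.shape)
    for _ in range(50):
        ijk = rng.integers(0, shape)
        p = grid.voxel_center(ijk)
        d = np.linalg.norm(pos - p, axis=1)
        c = int(np.sum((d >= PARAMS.d_min) & (d <= PARAMS.d_max)))
        expected = c if c >= PARAMS.clique_min_size else 0
        assert grid.counts[tuple(ijk)] == expected


def test_density_origin_voxel_counts_all_four(tetra_site_structure):
    coords = select_coordinators(tetra_site_structure)
    grid = build_density_grid(tetra_site_structure,
                              find_cliques(coords, PARAMS), PARAMS)
    assert grid.value_at([[0.0, 0.0, 0.0]])[0] == 4
    # far from every coordinator: no density
    assert grid.value_at([[2.0 * 2.0 + 5.0, 0.0, 0.0]])[0] == 0


def test_density_monotone_in_dmax(tetra_site_structure):
    coords = select_coordinators(tetra_site_structure)
    small = GeometryParams(d_max=2.5)
    large = GeometryParams(d_max=3.5)
    g_small = build_density_grid(tetra_site_structure,
                                 find_cliques(coords, small), small)
    g_large = build_density_grid(tetra_site_structure,
                                 find_cliques(coords, large), large)
    rng = np.random.default_rng(5)
    pts = rng.uniform(-3, 3, size=(100, 3))
    assert np.all(g_large.value_at(pts) >= g_small.value_at(pts))


def test_grid_budget_error(tetra_site_structure):
    params = GeometryParams(grid_step=0.01, max_voxels=10_000)
    coords = select_coordinators(tetra_site_structure)
    with pytest.raises(GridBudgetError, match="grid_step"):
        build_density_grid(tetra_site_structure,
                           find_cliques(coords, params), params)


# --- VdW exclusion ----------------------------------------------------------

def test_vdw_exclusion_rules(tetra_site_structure):
    coords = select_coordinators(tetra_site_structure)
    grid = build_density_grid(tetra_site_structure,
                              find_cliques(coords, PARAMS), PARAMS)
    excl = apply_vdw_exclusion(grid, tetra_site_structure, PARAMS)
    # voxel at an atom position is excluded
    atom_pos = tetra_site_structure.atoms[0].position
    assert excl.value_at([atom_pos])[0] == 0
    ijk = np.rint((atom_pos - excl.origin) / excl.step).astype(int)
    assert excl.excluded_mask[tuple(ijk)]
    # origin voxel survives: nearest atom 2.0 A away > 1.52 A radius
    assert excl.value_at([[0.0, 0.0, 0.0]])[0] == 4
    # soundness: no surviving voxel is inside any VdW sphere
    nz = np.argwhere(excl.counts > 0)
    centers = excl.origin + nz * excl.step
    for a in tetra_site_structure.atoms:
        r = PARAMS.vdw_radii[a.element.upper()]
        assert np.all(np.linalg.norm(centers - a.position, axis=1) > r)


def test_vdw_missing_element_raises(tetra_site_structure):
    params = GeometryParams(vdw_radii={"C": 1.7})
    coords = select_coordinators(tetra_site_structure)
    grid = build_density_grid(tetra_site_structure,
                              find_cliques(coords, params), params)
    with pytest.raises(VdwTableError, match="O"):
        apply_vdw_exclusion(grid, tetra_site_structure, params)


# --- ranking ----------------------------------------------------------------

def _grid_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int16)
    return DensityGrid(origin=np.zeros(3), step=0.1, shape=counts.shape,
                       counts=counts, excluded_mask=np.zeros(counts.shape, bool))


def test_rank_sites_empty_and_ordering():
    assert rank_sites(_grid_from_counts(np.zeros((5, 5, 5)))) == []
    counts = np.zeros((12, 5, 5))
    counts[1:3, 1:3, 1:3] = 3
    counts[2, 2, 2] = 4        # blob A, peak 4
    counts[8:10, 1:3, 1:3] = 3  # blob B, peak 3 (disjoint)
    sites = rank_sites(_grid_from_counts(counts))
    assert [s.peak_density for s in sites] == [4, 3]
    assert [s.rank for s in sites] == [1, 2]
    assert sites[0].voxel_count == 8 and sites[1].voxel_count == 8
    np.testing.assert_allclose(sites[0].peak_position, [0.2, 0.2, 0.2])


# --- coordination shell -----------------------------------------------------

def test_coordination_shell(tetra_site_structure):
    far = coordination_shell(tetra_site_structure, [50, 50, 50], 2.5)
    assert far.n_coordinators == 0
    shell = coordination_shell(tetra_site_structure, [0, 0, 0], 2.5)
    assert shell.n_coordinators == 4
    tight = coordination_shell(tetra_site_structure, [0, 0, 0], 1.0)
    assert tight.n_coordinators == 0
    with pytest.raises(ValueError):
        coordination_shell(tetra_site_structure, [0, 0, 0], -1.0)


def test_coordination_shell_includes_waters():
    st = make_structure([
        make_atom("OD1", [2, 0, 0], seq=1),
        make_atom("O", [-2, 0, 0], residue="HOH", seq=2, het=True),
    ])
    shell = coordination_shell(st, [0, 0, 0], 2.5)
    assert shell.n_coordinators == 2


# --- end-to-end prediction --------------------------------------------------

def test_predict_recovers_generated_center():
    pdb, truth = gen_toy_structure(21, n_chelators=4, shell_radius=2.0,
                                   geometry="tetrahedral", decoys=15)
    st = load_structure_from_text(pdb)
    sites = predict_metal_sites(st)
    assert sites, "expected a predicted site"
    center = np.array(truth["ground_truth"]["center"])
    assert np.linalg.norm(sites[0].peak_position - center) <= 0.2
    assert len(sites[0].supporting_atoms) == 4


def test_predict_no_coordinators_and_sparse_coordinators():
    carbons = make_structure([make_atom("CB", [i * 4.0, 0, 0], element="C",
                                        seq=i + 1, residue="ALA")
                              for i in range(5)])
    assert predict_metal_sites(carbons) == []
    # coordinators all > 6 A apart: no clique possible by construction
    sparse = make_structure([make_atom("OD1", [i * 7.0, 0, 0], seq=i + 1)
                             for i in range(5)])
    assert predict_metal_sites(sparse) == []


def test_predict_rigid_motion_equivariance():
    pdb, truth = gen_toy_structure(31, n_chelators=5, shell_radius=2.1,
                                   geometry="octahedral", decoys=10)
    st = load_structure_from_text(pdb)
    base = predict_metal_sites(st)

    rng = np.random.default_rng(31)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-10, 10, size=3)
    moved = predict_metal_sites(st.transformed(Q, t))
    # marginal low-count fringe components may split or merge when the voxel
    # lattice is re-laid, but the top-ranked site must move with the frame
    assert base and moved
    assert base[0].peak_density == moved[0].peak_density
    step = GeometryParams().grid_step
    expected_peak = Q @ base[0].peak_position + t
    assert np.linalg.norm(moved[0].peak_position - expected_peak) <= np.sqrt(3) * step
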