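"""Geometric prediction of Zn2+-binding sites in protein structures.

The method places a divalent cation everywhere it could be simultaneously
chelated by several protein coordinator atoms:

1. *Coordinator selection.* Candidate chelators are side-chain O/N/S atoms
   (SG, ND1, NE2, OD1, OD2, OE1, OE2, OG, OG1, OH) plus the backbone
   carbonyl oxygen "O" of standard residues.
2. *Clique detection.* Coordinators are nodes of a graph whose edges join
   pairs closer than ``clique_pair_max`` (6 A by default); maximal cliques
   of at least ``clique_min_size`` (3) atoms seed possible metal placements,
   since a cation ~2 A from each of several chelators forces them to be
   mutually close.
3. *Feasibility density.* On a cubic grid (0.1 A step) spanning the clique
   atoms, each voxel counts the coordinator atoms whose distance lies in
   ``[d_min, d_max]`` (1.7-3.0 A, the observed range of Zn-ligand contacts).
   Counts below ``clique_min_size`` are zeroed: the cation needs at least
   that many simultaneous chelators.
4. *VdW exclusion.* Voxels inside any heavy atom's van der Waals sphere are
   removed (the cation cannot overlap protein atoms).
5. *Ranking.* Remaining non-zero voxels are merged into 26-connected
   components; each component is one predicted site, ranked by its maximum
   count ("density").

The procedure is deterministic and uses distances only; an optional angular
window is reserved in :class:`GeometryParams` but not applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .structure import STANDARD_AA, AtomRecord, ProteinStructure

__all__ = [
    "BONDI_RADII", "DEFAULT_COORDINATOR_NAMES", "GeometryParams",
    "CoordinatorClique", "DensityGrid", "PredictedSite", "CoordinationShell",
    "GridBudgetError", "VdwTableError",
    "select_coordinators", "find_cliques", "build_density_grid",
    "apply_vdw_exclusion", "rank_sites", "coordination_shell",
    "predict_metal_sites",
]

#: Atom names eligible to chelate a divalent cation.
DEFAULT_COORDINATOR_NAMES = frozenset({
    "SG", "ND1", "NE2", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "O",
})

#: Bondi van der Waals radii (A), with common biological metals appended.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "MN": 2.05, "FE": 2.05, "CU": 1.40, "NI": 1.63, "CO": 2.00, "CD": 1.58,
}


class GridBudgetError(MemoryError):
    """The requested grid exceeds the voxel budget; use a coarser step."""


class VdwTableError(KeyError):
    """An element has no entry in the van der Waals radii table."""


@dataclass(frozen=True)
class GeometryParams:
    """Tunable geometry of the site search.

    ``d_max`` caps the cation-chelator distance (3 A); ``d_min`` is the
    clash floor below which a chelator would overlap the cation (1.7 A,
    about the shortest observed Zn-O/Zn-S contacts); ``clique_pair_max``
    and ``clique_min_size`` define the coordinator-graph cliques ("at
    least 3 atoms within 6 A"); ``grid_step`` is the voxel edge (0.1 A).
    ``angle_window`` is a reserved hook for an angular criterion and is
    not applied by the default score.
    """

    coordinator_atom_names: frozenset[str] = DEFAULT_COORDINATOR_NAMES
    d_max: float = 3.0
    d_min: float = 1.7
    clique_pair_max: float = 6.0
    clique_min_size: int = 3
    grid_step: float = 0.1
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    max_voxels: int = 120_000_000
    angle_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min < self.d_max < self.clique_pair_max):
            raise ValueError("require 0 < d_min < d_max < clique_pair_max")
        if self.clique_min_size < 3:
            raise ValueError("clique_min_size must be >= 3")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


@dataclass(frozen=True)
class CoordinatorClique:
    """A maximal set of mutually close coordinator atoms."""

    member_atoms: tuple[AtomRecord, ...]
    centroid: np.ndarray

    def __len__(self) -> int:
        return len(self.member_atoms)


@dataclass
class DensityGrid:
    """Voxelized count of simultaneously reachable coordinators.

    ``counts[i, j, k]`` is the number of coordinator atoms within
    ``[d_min, d_max]`` of the voxel center ``origin + (i, j, k) * step``,
    stored only where that number reaches the clique threshold.
    """

    origin: np.ndarray
    step: float
    shape: tuple[int, int, int]
    counts: np.ndarray
    excluded_mask: np.ndarray

    def voxel_center(self, ijk: Sequence[int]) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.step

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Counts at the voxels nearest to ``points`` (0 outside the grid)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.rint((pts - self.origin) / self.step).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(pts), dtype=self.counts.dtype)
        sel = ijk[inside]
        out[inside] = self.counts[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


@dataclass
class PredictedSite:
    """One connected blob of feasible cation positions."""

    peak_position: np.ndarray
    peak_density: int
    extent: float
    voxel_count: int
    supporting_atoms: list[AtomRecord]
    rank: int


@dataclass
class CoordinationShell:
    """Chelator atoms found within ``cutoff`` of a fixed center."""

    center: np.ndarray
    cutoff: float
    chelator_atoms: list[AtomRecord]

    @property
    def n_coordinators(self) -> int:
        return len(self.chelator_atoms)


def _is_coordinator(atom: AtomRecord, names: frozenset[str], allow_water: bool = False) -> bool:
    if atom.atom_name not in names:
        return False
    if atom.atom_name == "O":
        if atom.is_water:
            return allow_water
        # Backbone carbonyl oxygen of standard residues only.
        return atom.residue_name in STANDARD_AA and not atom.is_hetero
    return True


def select_coordinators(structure: ProteinStructure,
                        params: GeometryParams = GeometryParams()) -> list[AtomRecord]:
    """Return the chelator-eligible atoms of ``structure`` in file order."""
    return [a for a in structure.atoms
            if _is_coordinator(a, params.coordinator_atom_names)]


def find_cliques(coordinators: Sequence[AtomRecord],
                 params: GeometryParams = GeometryParams()) -> list[CoordinatorClique]:
    """All maximal cliques of >= ``clique_min_size`` mutually close coordinators.

    Edges join coordinator pairs strictly closer than ``clique_pair_max``.
    Output order is deterministic (sorted by centroid, lexicographically).
    """
    n = len(coordinators)
    if n < params.clique_min_size:
        return []
    pos = np.array([a.position for a in coordinators])
    tree = cKDTree(pos)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i, j in tree.query_pairs(r=params.clique_pair_max, output_type="ndarray"):
        if np.linalg.norm(pos[i] - pos[j]) < params.clique_pair_max:
            graph.add_edge(int(i), int(j))
    cliques = []
    for members in nx.find_cliques(graph):
        if len(members) < params.clique_min_size:
            continue
        members = sorted(members)
        centroid = pos[members].mean(axis=0)
        cliques.append(CoordinatorClique(
            member_atoms=tuple(coordinators[i] for i in members),
            centroid=centroid,
        ))
    cliques.sort(key=lambda c: tuple(c.centroid))
    return cliques


def _clique_member_atoms(cliques: Iterable[CoordinatorClique]) -> list[AtomRecord]:
    seen: set[tuple[str, int, str]] = set()
    out: list[AtomRecord] = []
    for cl in cliques:
        for a in cl.member_atoms:
            if a.site_key not in seen:
                seen.add(a.site_key)
                out.append(a)
    return out


def build_density_grid(structure: ProteinStructure,
                       cliques: Sequence[CoordinatorClique],
                       params: GeometryParams = GeometryParams()) -> DensityGrid:
    """Count, per voxel, the clique coordinators within ``[d_min, d_max]``.

    The grid spans the bounding box of all clique member atoms padded by
    ``d_max`` (which covers every clique centroid padded by ``d_max``).
    Counts below ``clique_min_size`` are stored as zero.
    """
    if not cliques:
        raise ValueError("at least one clique is required to build a grid")
    atoms = _clique_member_atoms(cliques)
    pos = np.array([a.position for a in atoms])
    step = params.grid_step
    lo = pos.min(axis=0) - params.d_max - step
    hi = pos.max(axis=0) + params.d_max + step
    shape = tuple(int(np.floor((hi[k] - lo[k]) / step)) + 1 for k in range(3))
    n_vox = int(np.prod(shape))
    if n_vox > params.max_voxels:
        raise GridBudgetError(
            f"grid of {shape} = {n_vox} voxels exceeds the budget of "
            f"{params.max_voxels}; increase grid_step (currently {step} A) "
            "or raise max_voxels")

    tree = cKDTree(pos)
    counts = np.zeros(n_vox, dtype=np.int16)
    # Lower bound is inclusive: subtract neighbours strictly below d_min.
    r_lo = np.nextafter(params.d_min, 0.0)
    chunk = 2_000_000
    for start in range(0, n_vox, chunk):
        idx = np.arange(start, min(start + chunk, n_vox))
        ijk = np.stack(np.unravel_index(idx, shape), axis=1)
        centers = lo + ijk * step
        c = (tree.query_ball_point(centers, r=params.d_max, return_length=True)
             - tree.query_ball_point(centers, r=r_lo, return_length=True))
        c[c < params.clique_min_size] = 0
        counts[idx] = c.astype(np.int16)
    counts = counts.reshape(shape)
    return DensityGrid(origin=lo, step=step, shape=shape, counts=counts,
                       excluded_mask=np.zeros(shape, dtype=bool))


def apply_vdw_exclusion(grid: DensityGrid, structure: ProteinStructure,
                        params: GeometryParams = GeometryParams()) -> DensityGrid:
    """Zero every voxel lying within the van der Waals sphere of any heavy atom."""
    mask = grid.excluded_mask.copy()
    shape = np.array(grid.shape)
    step = grid.step
    for atom in structure.atoms:
        el = atom.element.upper()
        if el not in params.vdw_radii:
            raise VdwTableError(
                f"element '{atom.element}' has no van der Waals radius configured")
        r = params.vdw_radii[el]
        rel = (atom.position - grid.origin) / step
        i0 = np.maximum(np.floor(rel - r / step).astype(int), 0)
        i1 = np.minimum(np.ceil(rel + r / step).astype(int), shape - 1)
        if np.any(i0 > i1):
            continue
        ax = [np.arange(i0[k], i1[k] + 1) * step + grid.origin[k] - atom.position[k]
              for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = (slice(i0[0], i1[0] + 1), slice(i0[1], i1[1] + 1), slice(i0[2], i1[2] + 1))
        mask[sub] |= d2 <= r * r
    counts = grid.counts.copy()
    counts[mask] = 0
    return DensityGrid(origin=grid.origin.copy(), step=step, shape=grid.shape,
                       counts=counts, excluded_mask=mask)


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a point set (max pairwise distance)."""
    if len(points) < 2:
        return 0.0
    if len(points) > 4000:
        # The diameter is attained on the convex hull; fall back to a
        # bounding-box diagonal estimate only if the hull is degenerate.
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            return float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    return float(pdist(points).max())


def rank_sites(grid: DensityGrid, merge_connectivity: int = 26,
               coordinators: Optional[Sequence[AtomRecord]] = None,
               params: Optional[GeometryParams] = None) -> list[PredictedSite]:
    """Group non-zero voxels into connected components and rank them.

    Components are merged with the 26-neighborhood (or 6 if requested).
    Each becomes one :class:`PredictedSite` whose peak is the max-count
    voxel. Ideal-shell feasibility regions are flat-topped, so tied peak
    voxels are ordered by coordination symmetry when ``coordinators`` are
    supplied: the spread (standard deviation, quantized at half a grid
    step) of the distances to the in-range chelators is minimized first --
    a cation at the center of a chelation shell sits at near-equal
    distance from every ligand. Remaining ties fall back to the distance
    to the centroid of the tied voxels, then to lexicographic order, so
    the result is fully deterministic. Sites are sorted by peak density
    then voxel count, descending.
    """
    if merge_connectivity == 26:
        connect = np.ones((3, 3, 3), dtype=bool)
    elif merge_connectivity == 6:
        connect = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("merge_connectivity must be 6 or 26")
    labels, n_comp = ndimage.label(grid.counts > 0, structure=connect)
    if n_comp == 0:
        return []

    sites: list[PredictedSite] = []
    slices = ndimage.find_objects(labels)
    for comp, slc in enumerate(slices, start=1):
        local = labels[slc] == comp
        vals = np.asarray(grid.counts[slc])[local]
        ijk = np.argwhere(local) + np.array([s.start for s in slc])
        centers = grid.origin + ijk * grid.step
        peak_val = int(vals.max())
        cand = centers[vals == peak_val]
        centroid = cand.mean(axis=0)
        d2 = np.einsum("ij,ij->i", cand - centroid, cand - centroid)
        if coordinators is not None and params is not None and len(cand) > 1:
            cpos = np.array([a.position for a in coordinators])
            dist = np.linalg.norm(cand[:, None, :] - cpos[None, :, :], axis=2)
            in_range = (dist >= params.d_min) & (dist <= params.d_max)
            k = np.maximum(in_range.sum(axis=1), 1)
            mean = (dist * in_range).sum(axis=1) / k
            spread = np.sqrt((((dist - mean[:, None]) * in_range) ** 2
                              ).sum(axis=1) / k)
            sym_bin = np.floor(spread / (0.5 * grid.step)).astype(int)
        else:
            sym_bin = np.zeros(len(cand), dtype=int)
        order = sorted(range(len(cand)),
                       key=lambda i: (int(sym_bin[i]), round(float(d2[i]), 9),
                                      tuple(cand[i])))
        peak = cand[order[0]]

        supporting: list[AtomRecord] = []
        if coordinators is not None and params is not None:
            for a in coordinators:
                d = float(np.linalg.norm(a.position - peak))
                if params.d_min <= d <= params.d_max:
                    supporting.append(a)
        sites.append(PredictedSite(
            peak_position=peak,
            peak_density=peak_val,
            extent=_max_pairwise_distance(centers),
            voxel_count=int(local.sum()),
            supporting_atoms=supporting,
            rank=0,
        ))
    sites.sort(key=lambda s: (-s.peak_density, -s.voxel_count, tuple(s.peak_position)))
    for i, s in enumerate(sites, start=1):
        s.rank = i
    return sites


def coordination_shell(structure: ProteinStructure, center: Sequence[float],
                       cutoff: float,
                       params: GeometryParams = GeometryParams()) -> CoordinationShell:
    """Chelator-eligible atoms (including water oxygens) within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    c = np.asarray(center, dtype=float)
    chelators = [
        a for a in structure.atoms
        if _is_coordinator(a, params.coordinator_atom_names, allow_water=True)
        and np.linalg.norm(a.position - c) <= cutoff
    ]
    return CoordinationShell(center=c, cutoff=cutoff, chelator_atoms=chelators)


def predict_metal_sites(structure: ProteinStructure,
                        params: GeometryParams = GeometryParams()) -> list[PredictedSite]:
    """Full pipeline: coordinators -> cliques -> density -> exclusion -> ranking."""
    coordinators = select_coordinators(structure, params)
    cliques = find_cliques(coordinators, params)
    if not cliques:
        return []
    grid = build_density_grid(structure, cliques, params)
    grid = apply_vdw_exclusion(grid, structure, params)
    return rank_sites(grid, coordinators=coordinators, params=params)
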