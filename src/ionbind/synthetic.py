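"""Generators for every input the pipeline consumes, with known ground truth.

Each generator is a pure function of its seed and parameters, emulating the
study conditions: ITC titrations of a 25 uM protein cell with 2 uL
injections of a 375-750 uM ion syringe; equilibrium dialysis over a
2-150 uM free-zinc range; two-state thermal scans from 15 to 95 C; and
idealized tetrahedral/octahedral chelation shells embedded in decoy atom
clouds for the site-prediction geometry.

Noise conventions (additive Gaussian throughout):

* ITC -- ``noise_frac`` of the largest clean per-injection heat;
* dialysis -- multiplicative ``noise_frac`` on the bound amount, matching
  a per-measurement relative error of the metal assay;
* melt curves -- ``noise_frac`` of the transition amplitude.

Every generator returns (or writes alongside its data file) a ground-truth
record sufficient to score parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .dialysis import DialysisWell, hill
from .itc import Isotherm, ModelParams, TitrationProtocol, simulate_isotherm
from .thermal import MeltCurve

__all__ = ["gen_itc_dataset", "gen_dialysis_dataset", "gen_melt_curve",
           "gen_toy_structure", "TETRAHEDRAL_DIRECTIONS", "OCTAHEDRAL_DIRECTIONS"]

TETRAHEDRAL_DIRECTIONS = np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)

OCTAHEDRAL_DIRECTIONS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
    [0.0, -1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
])


def _params_truth(params: ModelParams) -> dict:
    d = asdict(params)
    d["model"] = type(params).__name__
    return d


def gen_itc_dataset(seed: int, protocol: TitrationProtocol,
                    model_params: ModelParams, noise_frac: float = 0.01,
                    out_dir: Optional[str | Path] = None
                    ) -> tuple[Isotherm, dict]:
    """Simulate one titration with noise scaled to the clean heat range."""
    clean = simulate_isotherm(protocol, model_params, noise_sd=0.0)
    noise_sd = noise_frac * float(np.max(np.abs(clean.heat)))
    iso = simulate_isotherm(protocol, model_params, noise_sd=noise_sd, seed=seed)
    truth = {
        "seed": seed,
        "noise_sd_kcal_per_mol": noise_sd,
        "ground_truth": _params_truth(model_params),
        "protocol": {
            "cell_volume_L": protocol.cell_volume,
            "cell_protein_conc_M": protocol.cell_protein_conc,
            "syringe_ligand_conc_M": protocol.syringe_ligand_conc,
            "injection_volumes_L": list(protocol.injection_volumes),
            "temperature_K": protocol.temperature,
        },
    }
    if out_dir is not None:
        from .io import write_isotherm_tsv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_isotherm_tsv(out / "isotherm.tsv", iso, protocol)
        (out / "isotherm.truth.json").write_text(json.dumps(truth, indent=1))
    return iso, truth


def gen_dialysis_dataset(seed: int, b_max: float = 1.5, k_half: float = 4.7e-6,
                         h: float = 1.0, protein_conc: float = 5e-6,
                         free_grid: Optional[Sequence[float]] = None,
                         noise_frac: float = 0.05,
                         out_dir: Optional[str | Path] = None
                         ) -> tuple[list[DialysisWell], dict]:
    """Paired-chamber totals following a Hill law.

    The default free grid is 8 points log-spaced over the study's
    2-150 uM zinc range; the buffer side carries the free concentration
    and the protein side the free plus noisy bound amount.
    """
    if free_grid is None:
        free_grid = np.geomspace(2e-6, 150e-6, 8)
    free = np.asarray(free_grid, dtype=float)
    if np.any(free <= 0):
        raise ValueError("free grid must be positive")
    rng = np.random.default_rng(seed)
    bound_conc = protein_conc * hill(free, b_max, k_half, h)
    noisy_bound = bound_conc * (1.0 + rng.normal(0.0, noise_frac, size=free.shape))
    wells = [DialysisWell(total_metal_protein_side=float(f + nb),
                          total_metal_buffer_side=float(f),
                          protein_conc=protein_conc)
             for f, nb in zip(free, np.clip(noisy_bound, 0.0, None))]
    truth = {"seed": seed, "noise_frac": noise_frac,
             "ground_truth": {"b_max": b_max, "k_half_M": k_half, "h": h,
                              "protein_conc_M": protein_conc}}
    if out_dir is not None:
        from .io import write_wells_tsv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_wells_tsv(out / "wells.tsv", wells)
        (out / "wells.truth.json").write_text(json.dumps(truth, indent=1))
    return wells, truth


def gen_melt_curve(seed: int, kind: str = "lambda_max", t_m: float = 40.0,
                   width: float = 3.0,
                   baselines: tuple[float, float] = (338.0, 352.0),
                   baseline_slopes: tuple[float, float] = (0.0, 0.0),
                   t_range: tuple[float, float] = (15.0, 95.0),
                   t_step: float = 0.5, noise_frac: float = 0.01,
                   out_dir: Optional[str | Path] = None
                   ) -> tuple[MeltCurve, dict]:
    """Two-state melt (or scattering-rise) curve with linear baselines.

    For ``kind="scattering"`` the curve is a flat baseline followed by a
    sigmoidal rise centered at ``t_m`` (interpreted as T_agg). Noise sd is
    ``noise_frac`` times the transition amplitude. ``width -> 0`` produces
    a step centered at ``t_m``.
    """
    if not (t_range[0] < t_m < t_range[1]):
        raise ValueError("t_m must lie inside the scanned range")
    t = np.arange(t_range[0], t_range[1] + 0.5 * t_step, t_step)
    a_n, a_d = baselines
    b_n, b_d = baseline_slopes
    if width > 0:
        sig = 1.0 / (1.0 + np.exp(np.clip((t_m - t) / width, -500, 500)))
    else:
        sig = (t >= t_m).astype(float)
    native = a_n + b_n * t
    denat = a_d + b_d * t
    obs = native + (denat - native) * sig
    amplitude = abs(a_d - a_n)
    noise_sd = noise_frac * amplitude
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
    curve = MeltCurve(temperatures=t, observable=obs, kind=kind)
    truth = {"seed": seed, "noise_sd": noise_sd,
             "ground_truth": {"t_m_C": t_m, "width_C": width,
                              "baselines": list(baselines),
                              "baseline_slopes": list(baseline_slopes),
                              "kind": kind}}
    if out_dir is not None:
        from .io import write_melt_tsv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_melt_tsv(out / "melt.tsv", curve)
        (out / "melt.truth.json").write_text(json.dumps(truth, indent=1))
    return curve, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_toy_structure(seed: int, n_chelators: int = 4, shell_radius: float = 2.0,
                      geometry: str = "tetrahedral", decoys: int = 0,
                      center: Optional[Sequence[float]] = None,
                      out_dir: Optional[str | Path] = None) -> tuple[str, dict]:
    """Minimal PDB text with an ideal chelation shell in a decoy cloud.

    Chelator oxygens are written as OD1 atoms of separate ASP residues at
    ideal ``tetrahedral`` or ``octahedral`` vertices (randomly rotated per
    seed) at ``shell_radius`` from a recorded center; ``decoys`` carbon
    atoms are scattered at 5-12 A from the center, far enough to form no
    clique and exclude no feasible cation position. Returns the PDB text
    and the ground-truth record.
    """
    if not (3 <= n_chelators <= 6):
        raise ValueError("n_chelators must be between 3 and 6")
    if not (1.8 <= shell_radius <= 3.0):
        raise ValueError("shell_radius must be between 1.8 and 3.0 A")
    if geometry == "tetrahedral":
        dirs = TETRAHEDRAL_DIRECTIONS
    elif geometry == "octahedral":
        dirs = OCTAHEDRAL_DIRECTIONS
    else:
        raise ValueError("geometry must be 'tetrahedral' or 'octahedral'")
    if n_chelators > len(dirs):
        raise ValueError(f"{geometry} geometry supports at most {len(dirs)} chelators")

    rng = np.random.default_rng(seed)
    if center is None:
        center = rng.uniform(-5.0, 5.0, size=3)
    center = np.asarray(center, dtype=float)
    rot = _random_rotation(rng)
    chel_pos = center + shell_radius * (dirs[:n_chelators] @ rot.T)

    decoy_pos = np.empty((decoys, 3))
    for i in range(decoys):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        decoy_pos[i] = center + rng.uniform(5.0, 12.0) * u

    st = gemmi.Structure()
    st.name = f"toy-{geometry}-{seed}"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    serial = 1
    for i, p in enumerate(chel_pos):
        res = gemmi.Residue()
        res.name = "ASP"
        res.seqid = gemmi.SeqId(str(i + 1))
        atom = gemmi.Atom()
        atom.name = "OD1"
        atom.element = gemmi.Element("O")
        atom.pos = gemmi.Position(*p)
        atom.occ = 1.0
        atom.serial = serial
        serial += 1
        res.add_atom(atom)
        chain.add_residue(res)
    for i, p in enumerate(decoy_pos):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(str(n_chelators + i + 1))
        atom = gemmi.Atom()
        atom.name = "CB"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*p)
        atom.occ = 1.0
        atom.serial = serial
        serial += 1
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    pdb_text = st.make_pdb_string()

    truth = {"seed": seed,
             "ground_truth": {"center": center.tolist(),
                              "shell_radius_A": shell_radius,
                              "geometry": geometry,
                              "n_chelators": n_chelators,
                              "decoys": decoys}}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "toy.pdb").write_text(pdb_text)
        (out / "toy.truth.json").write_text(json.dumps(truth, indent=1))
    return pdb_text, truth
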