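"""Seed-deterministic synthetic inputs for every analysis stage.

The generators emulate the statistical and geometric structure the analysis
modules assume: noisy single-site titration isotherms at the reverse
(protein-into-ligand) scheme; idealised halogen-bond site geometries built to
requested interaction distances and angles; ideal bulk water and planted
ordered-water-site trajectories for the solvation-grid estimators; assigned
chemical-shift tables with planted perturbations; damped-sinusoid
interferograms (via `xbsolv.nmr.simulate_interferogram`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AtomRecord, StructureModel
from .itc import BindingParams, Isotherm, TitrationScheme, injection_heats
from .gist import SolventTrajectory
from .nmr import ShiftTable

__all__ = [
    "CX_BOND_LENGTHS",
    "make_isotherm_set",
    "make_xb_fixture",
    "make_bulk_water_traj",
    "make_ordered_site_traj",
    "make_shift_tables",
    "random_quaternions",
    "concentrated_quaternions",
]

#: Idealised C-X bond lengths (A) used only to place the donor carbon; tests
#: assert the interaction distances, never these.
CX_BOND_LENGTHS = {"H": 1.09, "F": 1.35, "CL": 1.74, "BR": 1.90, "I": 2.10}


def make_isotherm_set(
    params: BindingParams,
    scheme: TitrationScheme | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    displacement: str = "mean",
) -> list[Isotherm]:
    """Replicate isotherms = model heats + i.i.d. Gaussian noise.

    ``noise_sd`` defaults to 1% of the largest absolute model heat.
    """
    scheme = scheme or TitrationScheme.reverse_galectin()
    model = injection_heats(scheme, params, displacement)
    if noise_sd is None:
        noise_sd = 0.01 * float(np.max(np.abs(model)))
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=model.size) if noise_sd > 0 else 0.0
        out.append(Isotherm(heats_uJ=model + noise, scheme=scheme,
                            replicate_id=f"r{k + 1}"))
    return out


def _atom(element, name, resname, resnum, pos, chain="A") -> AtomRecord:
    return AtomRecord(element=element, name=name, residue_name=resname,
                      residue_number=resnum, chain=chain,
                      position=np.asarray(pos, float))


def make_xb_fixture(
    halogen: str,
    d_XO: float,
    angle_CXO: float = 180.0,
    water: tuple[float, float] | None = None,
    belt_donor_angle: float | None = None,
    belt_donor_distance: float = 3.3,
) -> StructureModel:
    """Minimal halogen-bond site: ligand C-X pair, a backbone-carbonyl mimic
    (Gly182-like), optionally a bridging water and a belt amide nitrogen
    (Asn174-like).

    The halogen sits at the origin with the acceptor oxygen at ``d_XO`` along
    +x; the donor carbon subtends ``angle_CXO`` at the halogen.  ``water``
    gives the two bridge legs (d(X..Ow), d(Ow..O_acceptor)); the water is
    placed in the xy-plane below the axis, which requires the legs to satisfy
    the triangle inequality with ``d_XO``.  All requested distances and
    angles are reproduced exactly by construction.
    """
    el = halogen.strip().upper()
    if el not in CX_BOND_LENGTHS:
        raise ValueError(f"unsupported substituent {halogen!r}")
    if d_XO <= 0:
        raise ValueError("d_XO must be positive")
    x_pos = np.zeros(3)
    o_pos = np.array([d_XO, 0.0, 0.0])
    theta = np.radians(angle_CXO)
    c_pos = x_pos + CX_BOND_LENGTHS[el] * np.array([np.cos(theta), np.sin(theta), 0.0])
    atoms = [
        _atom("C", "C1", "LIG", 1, c_pos),
        _atom(el, f"{el}1", "LIG", 1, x_pos),
        _atom("C", "C", "GLY", 182, o_pos + np.array([0.7, 1.0, 0.0])),
        _atom("O", "O", "GLY", 182, o_pos),
    ]
    if water is not None:
        d_xw, d_wo = water
        if d_xw <= 0 or d_wo <= 0:
            raise ValueError("water bridge legs must be positive")
        wx = (d_xw**2 - d_wo**2 + d_XO**2) / (2.0 * d_XO)
        h2 = d_xw**2 - wx**2
        if h2 < 0:
            raise ValueError("water bridge legs violate the triangle inequality")
        atoms.append(_atom("O", "O", "HOH", 501, [wx, -np.sqrt(h2), 0.0]))
    if belt_donor_angle is not None:
        c_hat = (c_pos - x_pos) / np.linalg.norm(c_pos - x_pos)
        perp = np.array([0.0, 0.0, 1.0])
        beta = np.radians(belt_donor_angle)
        u = np.cos(beta) * c_hat + np.sin(beta) * perp
        atoms.append(_atom("N", "ND2", "ASN", 174, x_pos + belt_donor_distance * u))
    return StructureModel(atoms, title=f"synthetic XB fixture ({el}, d_XO={d_XO} A)")


def random_quaternions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform unit quaternions (uniform on SO(3) after double cover)."""
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def concentrated_quaternions(rng: np.random.Generator, n: int,
                             concentration: float) -> np.ndarray:
    """Rotations concentrated around the identity: tangent-space Gaussian
    rotation vectors with standard deviation 1/sqrt(concentration) rad."""
    if concentration <= 0:
        return random_quaternions(rng, n)
    w = rng.normal(0.0, 1.0 / np.sqrt(concentration), size=(n, 3))
    theta = np.linalg.norm(w, axis=1)
    q = np.zeros((n, 4))
    q[:, 0] = np.cos(theta / 2.0)
    small = theta < 1e-12
    scale = np.where(small, 0.5, np.sin(theta / 2.0) / np.where(small, 1.0, theta))
    q[:, 1:] = w * scale[:, None]
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def make_bulk_water_traj(
    box: Sequence[float],
    n_waters: int,
    n_frames: int,
    temperature_K: float = 300.0,
    seed: int = 0,
) -> SolventTrajectory:
    """Ideal bulk: positions uniform in the box, orientations uniform on
    SO(3), frames independent.  The null model for the solvation grid."""
    if n_waters < 1 or n_frames < 1:
        raise ValueError("need positive water and frame counts")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = rng.uniform(0.0, 1.0, size=(n_frames, n_waters, 3)) * box
    quats = random_quaternions(rng, n_frames * n_waters).reshape(n_frames, n_waters, 4)
    return SolventTrajectory(water_positions=pos, water_quats=quats, box=box,
                             temperature_K=temperature_K)


def make_ordered_site_traj(
    site_center: Sequence[float],
    positional_sd: float,
    orientation_concentration: float,
    box: Sequence[float],
    n_background: int,
    n_frames: int,
    temperature_K: float = 300.0,
    seed: int = 0,
    site_enabled: bool = True,
) -> SolventTrajectory:
    """One water Gaussian-pinned at ``site_center`` with concentrated
    orientations; the remaining waters are ideal bulk.  With the site
    disabled this reduces exactly to the bulk generator's distribution."""
    box = np.asarray(box, dtype=float)
    center = np.asarray(site_center, dtype=float)
    if np.any(center < 0) or np.any(center > box):
        raise ValueError("site center must lie inside the box")
    rng = np.random.default_rng(seed)
    n_site = 1 if site_enabled else 0
    n_tot = n_background + n_site
    if n_tot < 1:
        raise ValueError("trajectory would contain no waters")
    pos = np.empty((n_frames, n_tot, 3))
    quats = np.empty((n_frames, n_tot, 4))
    if site_enabled:
        pos[:, 0, :] = center + rng.normal(0.0, positional_sd, size=(n_frames, 3))
        quats[:, 0, :] = concentrated_quaternions(rng, n_frames, orientation_concentration)
    if n_background:
        pos[:, n_site:, :] = rng.uniform(0.0, 1.0, size=(n_frames, n_background, 3)) * box
        quats[:, n_site:, :] = random_quaternions(
            rng, n_frames * n_background).reshape(n_frames, n_background, 4)
    return SolventTrajectory(water_positions=pos, water_quats=quats, box=box,
                             temperature_K=temperature_K)


def make_shift_tables(
    magnitudes: dict[str, float],
    planted_residues: Sequence[int] = (182, 183),
    residues: Sequence[int] = tuple(range(172, 188)),
    reference_label: str = "ref",
    per_unit_dd_ppm: tuple[float, float] = (0.01, 0.05),
    noise_ppm: float = 0.0,
    seed: int = 0,
) -> dict[str, ShiftTable]:
    """Assigned-shift tables with perturbations planted at chosen residues.

    ``magnitudes`` maps complex labels to a perturbation scale (e.g. |ΔΔH|
    in kJ/mol); planted residues move linearly with it, by
    ``per_unit_dd_ppm`` (1H, 15N) ppm per unit, all other residues stay at
    the reference value (plus optional noise).  Returns tables keyed by
    label, including the unperturbed ``reference_label`` table.
    """
    rng = np.random.default_rng(seed)
    res = np.asarray(residues)
    base_h = 8.0 + rng.uniform(-0.8, 0.8, size=res.size)
    base_n = 118.0 + rng.uniform(-6.0, 6.0, size=res.size)

    def table(label: str, scale: float) -> ShiftTable:
        rows = []
        for i, r in enumerate(res):
            bump_h = per_unit_dd_ppm[0] * scale if r in planted_residues else 0.0
            bump_n = per_unit_dd_ppm[1] * scale if r in planted_residues else 0.0
            eps = rng.normal(0.0, noise_ppm, size=2) if noise_ppm > 0 else (0.0, 0.0)
            rows.append({"residue": int(r), "atom": "H",
                         "shift_ppm": base_h[i] + bump_h + eps[0]})
            rows.append({"residue": int(r), "atom": "N",
                         "shift_ppm": base_n[i] + bump_n + eps[1]})
        return ShiftTable(complex_label=label, shifts=pd.DataFrame(rows))

    out = {reference_label: table(reference_label, 0.0)}
    for label, mag in magnitudes.items():
        out[label] = table(label, float(mag))
    return out
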