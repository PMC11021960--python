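"""Readers and writers: PDB structures, OpenDX volumetric grids, isotherm
CSV with embedded titration schemes, interferogram JSON and the toy
water-trajectory JSON format."""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from .geometry import AtomRecord, StructureModel
from .gist import SolventTrajectory, VoxelGrid
from .itc import Isotherm, TitrationScheme
from .nmr import Interferogram

__all__ = [
    "read_pdb",
    "write_pdb",
    "write_dx",
    "read_dx",
    "write_isotherm_csv",
    "read_isotherm_csv",
    "write_interferogram_json",
    "read_interferogram_json",
    "write_traj_json",
    "read_traj_json",
]


def read_pdb(path: str | Path) -> StructureModel:
    """Read ATOM/HETATM records into a `StructureModel`.

    Element symbols come from columns 77-78 with a fallback to the atom
    name.  Alternate locations are collapsed to the highest-occupancy
    conformer (ties resolved in favour of altloc 'A'); waters with occupancy
    below 0.5 are retained but flagged.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: dict[tuple, AtomRecord] = {}
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = atom.element.name.upper()
                    if not element or element == "X":
                        element = "".join(c for c in atom.name if c.isalpha())[:2].upper()
                    rec = AtomRecord(
                        element=element,
                        name=atom.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                        altloc=atom.altloc.strip() if atom.altloc else "",
                    )
                    rec.low_occupancy_water = rec.is_water and rec.occupancy < 0.5
                    key = (chain.name, residue.seqid.num, residue.name, atom.name)
                    prev = atoms.get(key)
                    if prev is None:
                        atoms[key] = rec
                    elif (rec.occupancy, -ord(rec.altloc or "Z")) > (
                            prev.occupancy, -ord(prev.altloc or "Z")):
                        atoms[key] = rec
        break  # first model only
    if not atoms:
        raise ValueError(f"no atoms found in {path}")
    return StructureModel(list(atoms.values()), title=st.name)


def write_pdb(structure: StructureModel, path: str | Path,
              provenance: str | None = None) -> None:
    """Write a minimal fixed-width PDB (3-decimal coordinates)."""
    lines = []
    if provenance:
        for chunk in provenance.splitlines():
            lines.append(f"REMARK 999 {chunk}")
    for serial, a in enumerate(structure.atoms, 1):
        rec = "HETATM" if (a.is_water or a.residue_name in {"LIG"}) else "ATOM  "
        name = a.name if len(a.name) >= 4 or len(a.element) > 1 else f" {a.name}"
        x, y, z = a.position
        lines.append(
            f"{rec}{serial:>5d} {name:<4s}{(a.altloc or ' '):1s}{a.residue_name:<3s} "
            f"{a.chain[:1]:1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dx(field: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write one scalar field as an OpenDX regular grid (z fastest)."""
    field = np.asarray(field, dtype=float)
    if field.shape != grid.dims:
        raise ValueError(f"field shape {field.shape} incongruent with grid {grid.dims}")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    head = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {field.size} data follows",
    ]
    flat = field.ravel(order="C")
    body = ["\n".join(
        " ".join(f"{v:.6e}" for v in flat[i:i + 3]) for i in range(0, flat.size, 3))]
    Path(path).write_text("\n".join(head + body) + "\n")


def read_dx(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read the OpenDX dialect produced by `write_dx`."""
    counts = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    in_data = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            values.extend(float(tok) for tok in line.split())
            continue
        if line.startswith("object 1"):
            counts = tuple(int(tok) for tok in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(tok) for tok in line.split()[1:4])
        elif line.startswith("delta"):
            deltas.append([float(tok) for tok in line.split()[1:4]])
        elif line.startswith("object 3"):
            n_items = int(line.split()[-3])
            in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular-grid OpenDX file")
    d = np.asarray(deltas)
    if not np.allclose(d, np.diag(np.diag(d))) or not np.allclose(
            np.diag(d), d[0, 0]):
        raise ValueError("only cubic axis-aligned grids are supported")
    grid = VoxelGrid(origin=origin, spacing=float(d[0, 0]), dims=counts)
    arr = np.asarray(values, dtype=float)
    if n_items is not None and arr.size != n_items:
        raise ValueError(f"expected {n_items} data values, found {arr.size}")
    return arr.reshape(counts, order="C"), grid


def write_isotherm_csv(iso: Isotherm, path: str | Path) -> None:
    """One replicate per file; the titration scheme rides in comment lines."""
    sch = iso.scheme
    lines = [
        f"# replicate_id = {iso.replicate_id}",
        f"# cell_volume_uL = {sch.cell_volume_uL}",
        f"# syringe_conc_M = {sch.syringe_conc_M}",
        f"# cell_conc0_M = {sch.cell_conc0_M}",
        f"# temperature_K = {sch.temperature_K}",
        "injection_index,volume_uL,heat_uJ",
    ]
    for i, (v, q) in enumerate(zip(sch.injection_volumes_uL, iso.heats_uJ), 1):
        lines.append(f"{i},{v},{float(q)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_isotherm_csv(path: str | Path) -> Isotherm:
    meta: dict[str, str] = {}
    vols: list[float] = []
    heats: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
        elif not line.startswith("injection_index"):
            _, v, q = line.split(",")
            vols.append(float(v))
            heats.append(float(q))
    scheme = TitrationScheme(
        cell_volume_uL=float(meta["cell_volume_uL"]),
        injection_volumes_uL=tuple(vols),
        syringe_conc_M=float(meta["syringe_conc_M"]),
        cell_conc0_M=float(meta["cell_conc0_M"]),
        temperature_K=float(meta.get("temperature_K", 301.0)),
    )
    return Isotherm(heats_uJ=np.asarray(heats), scheme=scheme,
                    replicate_id=meta.get("replicate_id", "r1"))


def write_interferogram_json(ifg: Interferogram, path: str | Path) -> None:
    payload = {
        "t": ifg.t.tolist(),
        "re": ifg.samples.real.tolist(),
        "im": ifg.samples.imag.tolist(),
        "mask": ifg.mask.tolist(),
        "mode": ifg.mode,
        "accordion_scale": ifg.accordion_scale,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_interferogram_json(path: str | Path) -> Interferogram:
    payload = json.loads(Path(path).read_text())
    return Interferogram(
        t=np.asarray(payload["t"]),
        samples=np.asarray(payload["re"]) + 1j * np.asarray(payload["im"]),
        mask=np.asarray(payload["mask"], dtype=int),
        mode=payload.get("mode", "forward"),
        accordion_scale=float(payload.get("accordion_scale", 1.0)),
    )


def write_traj_json(traj: SolventTrajectory, path: str | Path,
                    provenance: str | None = None) -> None:
    payload: dict = {
        "box": traj.box.tolist(),
        "temperature_K": traj.temperature_K,
        "water_positions": traj.water_positions.tolist(),
        "water_quats": traj.water_quats.tolist(),
    }
    if provenance:
        payload["provenance"] = provenance
    if traj.solute_positions is not None:
        payload["solute"] = {
            "positions": traj.solute_positions.tolist(),
            "charges": None if traj.solute_charges is None else list(traj.solute_charges),
            "lj_eps": None if traj.solute_lj_eps is None else list(traj.solute_lj_eps),
            "lj_sigma": None if traj.solute_lj_sigma is None else list(traj.solute_lj_sigma),
        }
    Path(path).write_text(json.dumps(payload))


def read_traj_json(path: str | Path) -> SolventTrajectory:
    payload = json.loads(Path(path).read_text())
    solute = payload.get("solute") or {}
    return SolventTrajectory(
        water_positions=np.asarray(payload["water_positions"]),
        water_quats=np.asarray(payload["water_quats"]),
        box=np.asarray(payload["box"]),
        temperature_K=float(payload.get("temperature_K", 300.0)),
        solute_positions=(np.asarray(solute["positions"]) if solute else None),
        solute_charges=(np.asarray(solute["charges"])
                        if solute.get("charges") is not None else None),
        solute_lj_eps=(np.asarray(solute["lj_eps"])
                       if solute.get("lj_eps") is not None else None),
        solute_lj_sigma=(np.asarray(solute["lj_sigma"])
                         if solute.get("lj_sigma") is not None else None),
    )
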