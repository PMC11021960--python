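"""Halogen-bond and water-bridge geometry in protein-ligand structures.

A halogen bond (XB) is scored on heavy atoms only: a carbon-bound halogen X
(Cl, Br, I; F is geometrically screened but has no sigma-hole) approaching an
acceptor oxygen with d(X...O) at or below the van der Waals radius sum and a
near-linear C-X...O angle.  A hydrogen-bond-enhanced XB (He-XB) is flagged
when a water oxygen bridges the halogen's electronegative belt and the XB
acceptor (C-X...H-O-H...O-Y).  Belt hydrogen bonds from protein N/O donors to
the halogen are detected by distance plus a C-X...D angle window on the side
of the belt (roughly perpendicular to the C-X axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "VdwTable",
    "HalogenBondHit",
    "WaterBridgeHit",
    "BeltHBondHit",
    "vdw_contact_sum",
    "angle_deg",
    "detect_halogen_bonds",
    "detect_water_bridges",
    "detect_belt_hbonds",
]

WATER_RESNAMES = {"HOH", "WAT", "H2O", "TIP", "SOL"}
HALOGEN_ELEMENTS = ("CL", "BR", "I")
#: Maximum C-X covalent bond length used to find the donor carbon.
COVALENT_CX_MAX = 2.2


@dataclass
class AtomRecord:
    """One atom of a crystal-structure model (author numbering, Cartesian A)."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    low_occupancy_water: bool = False

    def __post_init__(self) -> None:
        self.element = self.element.strip().upper()
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bad coordinates for atom {self.name}")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESNAMES


class StructureModel:
    """A flat list of atoms with simple selection helpers."""

    def __init__(self, atoms: Iterable[AtomRecord], title: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.title = title

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)

    def select(self, *, elements: Sequence[str] | None = None,
               water: bool | None = None) -> list[AtomRecord]:
        elems = {e.upper() for e in elements} if elements is not None else None
        out = []
        for a in self.atoms:
            if elems is not None and a.element not in elems:
                continue
            if water is not None and a.is_water != water:
                continue
            out.append(a)
        return out

    def water_oxygens(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_water and a.element == "O"]


@dataclass
class VdwTable:
    """Van der Waals radii (A).  Halogen radii follow the electrostatic-surface
    values for Cl/Br/I; the remainder are Bondi radii, chosen so that the
    standard contact sums (e.g. Cl+O = 1.75+1.52 = 3.27 A) are exact."""

    radii: dict[str, float] = field(default_factory=lambda: {
        "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
        "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "P": 1.80,
    })

    def __post_init__(self) -> None:
        self.radii = {k.upper(): float(v) for k, v in self.radii.items()}
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"implausible vdW radius {r} A for {el}")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element.strip().upper()]
        except KeyError:
            raise KeyError(f"no vdW radius for element {element!r}") from None


@dataclass
class HalogenBondHit:
    donor_carbon: AtomRecord
    halogen: AtomRecord
    acceptor: AtomRecord
    d_XO: float
    angle_CXO: float
    vdw_sum: float
    is_short_contact: bool


@dataclass
class WaterBridgeHit:
    halogen: AtomRecord
    water_oxygen: AtomRecord
    acceptor: AtomRecord
    d_X_Ow: float
    d_Ow_O: float
    forms_hexb: bool


@dataclass
class BeltHBondHit:
    donor_carbon: AtomRecord
    halogen: AtomRecord
    donor: AtomRecord
    d_XD: float
    angle_CXD: float


def vdw_contact_sum(elem_a: str, elem_b: str, table: VdwTable | None = None) -> float:
    """Sum of the two vdW radii in A (symmetric in its arguments)."""
    table = table or VdwTable()
    return table.radius(elem_a) + table.radius(elem_b)


def angle_deg(a, b, c) -> float:
    """Interior angle at ``b`` of the triple (a, b, c), in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate (zero-length) vector in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _halogen_carbon_pairs(
    structure: StructureModel, halogens: Sequence[str]
) -> list[tuple[AtomRecord, AtomRecord]]:
    """Each halogen atom with its covalently bonded carbon (nearest C within
    the covalent cutoff); halogens without one are skipped with a warning."""
    halo_set = {h.upper() for h in halogens}
    carbons = structure.select(elements=["C"], water=False)
    pairs = []
    for x in structure.atoms:
        if x.element not in halo_set or x.is_water:
            continue
        best, best_d = None, COVALENT_CX_MAX
        for c in carbons:
            d = float(np.linalg.norm(c.position - x.position))
            if d <= best_d:
                best, best_d = c, d
        if best is None:
            logger.warning("halogen %s/%s%d has no covalent carbon within %.1f A; skipped",
                           x.name, x.residue_name, x.residue_number, COVALENT_CX_MAX)
            continue
        pairs.append((best, x))
    return pairs


def _default_acceptors(structure: StructureModel, halogen: AtomRecord) -> list[AtomRecord]:
    """Non-water oxygens outside the halogen's own residue."""
    return [
        a for a in structure.select(elements=["O"], water=False)
        if not (a.residue_number == halogen.residue_number and a.chain == halogen.chain
                and a.residue_name == halogen.residue_name)
    ]


def detect_halogen_bonds(
    structure: StructureModel,
    halogens: Sequence[str] = HALOGEN_ELEMENTS,
    acceptors: Sequence[AtomRecord] | None = None,
    table: VdwTable | None = None,
    slack: float = 0.3,
    min_angle: float = 140.0,
) -> list[HalogenBondHit]:
    """Geometric XB scan.

    A hit requires d(X...O) <= vdW sum + ``slack`` and a C-X...O angle of at
    least ``min_angle`` degrees; ``is_short_contact`` marks sub-vdW-sum
    contacts (the defining XB criterion).  Hits are sorted by distance.
    """
    table = table or VdwTable()
    hits: list[HalogenBondHit] = []
    for carbon, x in _halogen_carbon_pairs(structure, halogens):
        cand = acceptors if acceptors is not None else _default_acceptors(structure, x)
        vsum_cache: dict[str, float] = {}
        for acc in cand:
            vsum = vsum_cache.setdefault(
                acc.element, vdw_contact_sum(x.element, acc.element, table))
            d = float(np.linalg.norm(acc.position - x.position))
            if d > vsum + slack:
                continue
            ang = angle_deg(carbon.position, x.position, acc.position)
            if ang < min_angle:
                continue
            hits.append(HalogenBondHit(
                donor_carbon=carbon, halogen=x, acceptor=acc,
                d_XO=d, angle_CXO=ang, vdw_sum=vsum,
                is_short_contact=d < vsum,
            ))
    hits.sort(key=lambda h: h.d_XO)
    return hits


def detect_water_bridges(
    structure: StructureModel,
    xb_hits: Sequence[HalogenBondHit],
    d_max: float = 3.5,
    halogens: Sequence[str] = ("F",) + HALOGEN_ELEMENTS,
) -> list[WaterBridgeHit]:
    """He-XB water bridges: a water oxygen within ``d_max`` of a carbon-bound
    halogen and within ``d_max`` of an XB acceptor oxygen.  ``forms_hexb``
    is set when the same halogen-acceptor pair also appears in ``xb_hits``.
    Bridges are scanned for all halogens (including F, which hydrogen-bonds
    through its belt without forming an XB)."""
    waters = structure.water_oxygens()
    if not waters:
        return []
    hit_pairs = {(id(h.halogen), id(h.acceptor)) for h in xb_hits}
    acceptor_pool: list[tuple[AtomRecord, AtomRecord]] = []
    for _, x in _halogen_carbon_pairs(structure, halogens):
        for acc in _default_acceptors(structure, x):
            acceptor_pool.append((x, acc))
    bridges = []
    for x, acc in acceptor_pool:
        for w in waters:
            d_xw = float(np.linalg.norm(w.position - x.position))
            d_wo = float(np.linalg.norm(w.position - acc.position))
            if d_xw <= d_max and d_wo <= d_max:
                bridges.append(WaterBridgeHit(
                    halogen=x, water_oxygen=w, acceptor=acc,
                    d_X_Ow=d_xw, d_Ow_O=d_wo,
                    forms_hexb=(id(x), id(acc)) in hit_pairs,
                ))
    bridges.sort(key=lambda b: b.d_X_Ow + b.d_Ow_O)
    return bridges


def detect_belt_hbonds(
    structure: StructureModel,
    halogens: Sequence[str] = ("F",) + HALOGEN_ELEMENTS,
    donors: Sequence[AtomRecord] | None = None,
    d_max: float = 3.6,
    angle_window: tuple[float, float] = (90.0, 150.0),
) -> list[BeltHBondHit]:
    """Hydrogen bonds donated into the halogen's electronegative belt.

    Heavy-atom criterion: donor N/O within ``d_max`` of X with the C-X...D
    angle inside ``angle_window`` (belt side; near-180 degrees would be the
    sigma-hole side and is excluded)."""
    hits = []
    for carbon, x in _halogen_carbon_pairs(structure, halogens):
        cand = donors if donors is not None else [
            a for a in structure.select(elements=["N", "O"], water=False)
            if not (a.residue_number == x.residue_number and a.chain == x.chain
                    and a.residue_name == x.residue_name)
        ]
        for d_atom in cand:
            d = float(np.linalg.norm(d_atom.position - x.position))
            if d > d_max:
                continue
            ang = angle_deg(carbon.position, x.position, d_atom.position)
            if angle_window[0] <= ang <= angle_window[1]:
                hits.append(BeltHBondHit(
                    donor_carbon=carbon, halogen=x, donor=d_atom,
                    d_XD=d, angle_CXD=ang,
                ))
    hits.sort(key=lambda h: h.d_XD)
    return hits
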