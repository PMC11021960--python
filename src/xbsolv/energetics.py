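"""QM-energy bookkeeping, sigma-hole extra-point placement, and correlation
of calculated energy terms with calorimetric thermodynamics.

Interaction energies follow the supermolecular convention
``dE = E_complex - E_residue - E_ligand`` per ligand-residue pair; the
composite score ``Sum`` is the sum of the three residue interactions minus
the ligand solvation free energy (an estimate of the desolvation penalty),
approximating the binding free energy of the halogenated aglycon.  The
extra point (EP) is an off-atom charge placed beyond the halogen on the C-X
axis to mimic the sigma-hole in fixed-charge force fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIGAND_SERIES",
    "QmEnergyRecord",
    "ExtraPointSpec",
    "EP_DISTANCES_A",
    "interaction_energy",
    "sum_minus_solv",
    "pearson",
    "place_extra_point",
    "load_itc_table",
    "load_qm_table",
    "load_gist_table",
    "build_ledger",
    "LigandLedger",
]

LIGAND_SERIES = ("H", "F", "Cl", "Br", "I")
#: Default halogen-to-extra-point distances (A), calibrated against QM
#: halogen-backbone interaction scans.
EP_DISTANCES_A = {"Cl": 1.95, "Br": 2.02, "I": 2.15}
#: Tolerance for the integer-rounded published Sum column (kJ/mol).
SUM_ROUNDING_TOL = 1.5


@dataclass(frozen=True)
class QmEnergyRecord:
    """Per-ligand QM energy terms, all in kJ/mol."""

    ligand: str
    dE_Asn174: float
    dE_Gly182: float
    dE_Glu184: float
    solv: float
    sum_published: float | None = None


@dataclass(frozen=True)
class ExtraPointSpec:
    """Sigma-hole extra point: distance beyond the halogen on the C-X axis."""

    halogen: str
    distance_A: float
    charge_e: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_A < 0:
            raise ValueError("X-EP distance must be non-negative")

    @classmethod
    def default(cls, halogen: str, charge_e: float = 0.0) -> "ExtraPointSpec":
        try:
            return cls(halogen, EP_DISTANCES_A[halogen], charge_e)
        except KeyError:
            raise KeyError(f"no default EP distance for {halogen!r} "
                           f"(defaults exist for {sorted(EP_DISTANCES_A)})") from None


def interaction_energy(e_comp: float, e_res: float, e_lig: float) -> float:
    """Supermolecular interaction energy dE = E_comp - E_res - E_lig."""
    return float(e_comp) - float(e_res) - float(e_lig)


def sum_minus_solv(record: QmEnergyRecord, check: bool = True) -> float:
    """Composite free-energy score: sum of the three residue interaction
    energies minus the ligand solvation free energy.

    With ``check`` and a stored published value, deviations beyond the
    integer-rounding tolerance raise ``ValueError``.
    """
    total = record.dE_Asn174 + record.dE_Gly182 + record.dE_Glu184 - record.solv
    if check and record.sum_published is not None:
        if abs(total - record.sum_published) > SUM_ROUNDING_TOL:
            raise ValueError(
                f"{record.ligand}: recomputed Sum {total:.2f} deviates from the "
                f"stored value {record.sum_published:.2f} by more than "
                f"{SUM_ROUNDING_TOL} kJ/mol"
            )
    return total


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient (two-pass, unweighted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in correlation input")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def place_extra_point(c_pos, x_pos, spec: ExtraPointSpec) -> np.ndarray:
    """EP position beyond the halogen on the C->X axis, |EP - X| = distance."""
    c = np.asarray(c_pos, dtype=float)
    x = np.asarray(x_pos, dtype=float)
    axis = x - c
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ValueError("carbon and halogen positions coincide")
    return x + spec.distance_A * axis / norm


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("xbsolv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_itc_table() -> pd.DataFrame:
    """Packaged per-ligand ITC thermodynamics (Kd in uM, energies kJ/mol)."""
    return _load_packaged("table1_itc.csv")


def load_qm_table(as_records: bool = False):
    """Packaged per-ligand QM interaction/solvation energies (kJ/mol)."""
    df = _load_packaged("table2_qm.csv")
    if not as_records:
        return df
    return [
        QmEnergyRecord(r.ligand, r.dE_Asn174, r.dE_Gly182, r.dE_Glu184,
                       r.Solv, r.Sum)
        for r in df.itertuples()
    ]


def load_gist_table() -> pd.DataFrame:
    """Packaged per-ligand GIST regional water entropies (kJ/mol)."""
    return _load_packaged("table3_gist.csv")


@dataclass
class LigandLedger:
    """Joined per-ligand table of calculated and experimental terms, plus the
    Pearson correlations between each calculated/experimental pairing."""

    table: pd.DataFrame
    correlations: dict[str, float]

    def summary(self) -> str:
        lines = ["Ligand energy ledger", "=" * 60, self.table.to_string(index=False), ""]
        lines.append("Pearson correlations (calculated vs experimental):")
        for k, v in self.correlations.items():
            lines.append(f"  {k:34s} R = {v:+.3f}")
        return "\n".join(lines)


def build_ledger(
    thermo: pd.DataFrame | None = None,
    qm: pd.DataFrame | None = None,
    gist: pd.DataFrame | None = None,
) -> LigandLedger:
    """Join per-ligand QM terms, ITC thermodynamics and (optionally) GIST
    entropies, and correlate calculated against experimental quantities.

    Correlations reported (5-point unweighted Pearson):

    * sum of the three residue dE vs experimental dH,
    * Sum (= sum dE - Solv) vs experimental dG,
    * Sum - Solv (second subtraction, the composite with the desolvation
      penalty applied twice) vs experimental dG -- both variants are reported
      because published composite-vs-dG correlations are ambiguous about
      whether Solv is subtracted once or twice,
    * Sum + GIST -TdS vs experimental dG (when GIST input present),
    * GIST -TdS_tot vs ITC -TdS (when GIST input present).
    """
    thermo = load_itc_table() if thermo is None else thermo
    qm = load_qm_table() if qm is None else qm
    merged = qm.merge(thermo, on="ligand", how="inner", validate="1:1")
    if len(merged) < len(qm) or len(merged) < len(thermo):
        raise ValueError("ligand labels do not match between QM and ITC tables")
    if merged["ligand"].duplicated().any():
        raise ValueError("duplicate ligand labels")
    merged["dE_sum"] = merged[["dE_Asn174", "dE_Gly182", "dE_Glu184"]].sum(axis=1)
    merged["sum_minus_solv"] = merged["dE_sum"] - merged["Solv"]
    corr = {
        "dE_sum vs dH": pearson(merged["dE_sum"], merged["dH"]),
        "Sum vs dG": pearson(merged["sum_minus_solv"], merged["dG"]),
        "Sum-Solv vs dG": pearson(merged["sum_minus_solv"] - merged["Solv"], merged["dG"]),
    }
    if gist is not None:
        merged = merged.merge(gist, on="ligand", how="inner", validate="1:1")
        corr["Sum+GIST(-TdS_water) vs dG"] = pearson(
            merged["sum_minus_solv"] + merged["mTdS_water"], merged["dG"])
        corr["GIST -TdS_tot vs ITC -TdS"] = pearson(merged["mTdS_tot"], merged["mTdS"])
    return LigandLedger(table=merged, correlations=corr)
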