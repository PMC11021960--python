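"""Single-site ITC isotherm modelling and global multi-replicate fitting.

The heat content of a 1:1 binding cell after the i-th injection follows the
Wiseman closed form

    Q_i = (dH * V0 / 2) * [alpha - sqrt(alpha^2 - 4 n M_i X_i)],
    alpha = n M_i + X_i + Kd,

where ``M_i`` is the total titrant (here: protein) concentration in the cell,
``X_i`` the total cell-species (ligand) concentration, ``n`` the fraction of
binding-competent titrant, ``Kd`` the dissociation constant and ``dH`` the
molar binding enthalpy.  Observed per-injection heats are finite differences
of ``Q_i`` corrected for the displaced, half-reacted injection volume plus a
per-replicate heat-of-mixing offset.

Concentrations follow the standard exponential-displacement convention for a
perfusion cell of constant volume ``V0``: after a cumulative injected volume
``dV``, ``X = X0 * exp(-dV/V0)`` and ``M = C_syr * (1 - exp(-dV/V0))``.

The global fit (`SingleSiteITCModel`) shares ``n``, ``Kd`` (log-parameterised)
and ``dH`` across replicates with one offset per replicate, and reports
residual-bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_GAS",
    "TitrationScheme",
    "Isotherm",
    "BindingParams",
    "ThermoResult",
    "concentrations_after_injection",
    "cumulative_heat",
    "injection_heats",
    "thermo_decompose",
    "SingleSiteITCModel",
    "ITCFitResults",
    "fit_global",
]

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314


@dataclass(frozen=True)
class TitrationScheme:
    """Injection protocol of one titration.

    Parameters
    ----------
    cell_volume_uL : float
        Active cell volume V0 in microlitres.
    injection_volumes_uL : tuple of float
        Volume of each injection, in order, in microlitres.
    syringe_conc_M : float
        Molar concentration of the titrant in the syringe.
    cell_conc0_M : float
        Initial molar concentration of the cell species.
    temperature_K : float
        Experiment temperature in kelvin.
    """

    cell_volume_uL: float
    injection_volumes_uL: tuple[float, ...]
    syringe_conc_M: float
    cell_conc0_M: float
    temperature_K: float = 301.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes_uL", tuple(float(v) for v in self.injection_volumes_uL)
        )
        if self.cell_volume_uL <= 0:
            raise ValueError("cell volume must be positive")
        if len(self.injection_volumes_uL) == 0 or any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("all injection volumes must be positive")
        if self.syringe_conc_M <= 0 or self.cell_conc0_M <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)

    def cumulative_volumes_uL(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes_uL)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (M_i, X_i) in the cell after every injection (1..N)."""
        frac = np.exp(-self.cumulative_volumes_uL() / self.cell_volume_uL)
        return self.syringe_conc_M * (1.0 - frac), self.cell_conc0_M * frac

    @classmethod
    def reverse_galectin(cls) -> "TitrationScheme":
        """Protein-into-ligand scheme used throughout this package's examples:
        287 uM titrant into 28.7 uM cell species, 200 uL cell, 15 injections
        (0.4 uL first, then 14 x 2.5 uL), 301 K."""
        return cls(
            cell_volume_uL=200.0,
            injection_volumes_uL=(0.4,) + (2.5,) * 14,
            syringe_conc_M=287e-6,
            cell_conc0_M=28.7e-6,
            temperature_K=301.0,
        )


@dataclass
class Isotherm:
    """Per-injection heats of one replicate titration (microjoules)."""

    heats_uJ: np.ndarray
    scheme: TitrationScheme
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
        if self.heats_uJ.shape != (self.scheme.n_injections,):
            raise ValueError(
                f"{self.heats_uJ.size} heats for {self.scheme.n_injections} injections"
            )


@dataclass(frozen=True)
class BindingParams:
    """Single-site model parameters.

    n is the fraction of binding-competent titrant (dimensionless), Kd the
    dissociation constant in molar, dH the binding enthalpy in kJ/mol and
    Qoff a per-replicate heat-of-mixing offset in the heat unit (uJ).
    """

    n: float
    Kd_M: float
    dH_kJmol: float
    Qoff_uJ: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd_M <= 0:
            raise ValueError("Kd must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic decomposition dG = dH + (-TdS), energies in kJ/mol."""

    dG_kJmol: float
    dH_kJmol: float
    minus_TdS_kJmol: float
    Kd_M: float
    temperature_K: float


def concentrations_after_injection(scheme: TitrationScheme, i: int) -> tuple[float, float]:
    """Total titrant and cell-species concentrations (M_i, X_i) after injection i.

    ``i`` is 1-based; ``i = 0`` returns the pre-titration state ``(0, X_0)``.
    """
    if not 0 <= i <= scheme.n_injections:
        raise IndexError(f"injection index {i} out of range 0..{scheme.n_injections}")
    if i == 0:
        return 0.0, scheme.cell_conc0_M
    M, X = scheme.concentrations()
    return float(M[i - 1]), float(X[i - 1])


def cumulative_heat(M_i, X_i, params: BindingParams, cell_volume_uL: float):
    """Wiseman cumulative heat content Q_i in microjoules.

    Vectorised over ``M_i``/``X_i``.  The bracket is evaluated as
    ``4 n M X / (alpha + sqrt(alpha^2 - 4 n M X))`` to avoid cancellation at
    low saturation; the discriminant is non-negative for every ``Kd >= 0`` by
    the AM-GM inequality.
    """
    M = np.asarray(M_i, dtype=float)
    X = np.asarray(X_i, dtype=float)
    if np.any(M < 0) or np.any(X < 0):
        raise ValueError("concentrations must be non-negative")
    alpha = params.n * M + X + params.Kd_M
    disc = alpha * alpha - 4.0 * params.n * M * X
    if np.any(disc < 0):  # cannot happen for valid inputs
        raise FloatingPointError("negative discriminant in Wiseman closed form")
    bracket = 4.0 * params.n * M * X / (alpha + np.sqrt(disc))
    q_J = params.dH_kJmol * 1e3 * (cell_volume_uL * 1e-6) / 2.0 * bracket
    q = q_J * 1e6  # -> uJ
    return float(q) if np.isscalar(M_i) and np.isscalar(X_i) else q


def injection_heats(
    scheme: TitrationScheme,
    params: BindingParams,
    displacement: str = "mean",
) -> np.ndarray:
    """Predicted per-injection heats (uJ), including the offset.

    The observed heat of injection i is the increment of the cumulative heat
    corrected for the heat carried out with the displaced volume:

        dQ_i = Q_i - Q_{i-1} + (V_i/V0) * [Q_i + Q_{i-1}]/2 + Qoff

    ``displacement="printed"`` switches the bracket to the difference form
    ``[Q_i - Q_{i-1}]/2`` (a transcription variant found in the literature).
    """
    if displacement not in ("mean", "printed"):
        raise ValueError("displacement must be 'mean' or 'printed'")
    M, X = scheme.concentrations()
    Q = cumulative_heat(M, X, params, scheme.cell_volume_uL)
    Qprev = np.concatenate([[0.0], Q[:-1]])  # Q_0 = 0 convention
    v = np.asarray(scheme.injection_volumes_uL) / scheme.cell_volume_uL
    carried = (Q + Qprev) / 2.0 if displacement == "mean" else (Q - Qprev) / 2.0
    return Q - Qprev + v * carried + params.Qoff_uJ


def thermo_decompose(Kd_M: float, dH_kJmol: float, temperature_K: float) -> ThermoResult:
    """Decompose binding thermodynamics: dG = RT ln Kd, -TdS = dG - dH."""
    if Kd_M <= 0 or temperature_K <= 0:
        raise ValueError("Kd and T must be positive")
    dG = R_GAS * temperature_K * np.log(Kd_M) / 1e3  # kJ/mol, Kd in molar
    return ThermoResult(
        dG_kJmol=float(dG),
        dH_kJmol=float(dH_kJmol),
        minus_TdS_kJmol=float(dG - dH_kJmol),
        Kd_M=float(Kd_M),
        temperature_K=float(temperature_K),
    )


class SingleSiteITCModel:
    """Global single-site model for one or more replicate isotherms.

    ``n``, ``log Kd`` and ``dH`` are shared across replicates; each replicate
    carries its own heat-of-mixing offset.  The first (small) injection is
    excluded from the objective by default, as is universal ITC practice.

    Parameters
    ----------
    isotherms : sequence of Isotherm
        Replicates; schemes must agree in temperature.
    skip_first : bool
        Exclude each replicate's first injection from the fit objective.
    displacement : {"mean", "printed"}
        Displaced-volume correction variant, see `injection_heats`.
    """

    def __init__(
        self,
        isotherms: Sequence[Isotherm],
        *,
        skip_first: bool = True,
        displacement: str = "mean",
    ):
        if len(isotherms) == 0:
            raise ValueError("need at least one isotherm")
        temps = {iso.scheme.temperature_K for iso in isotherms}
        if max(temps) - min(temps) > 1e-9:
            raise ValueError("replicate schemes differ in temperature")
        self.isotherms = list(isotherms)
        self.skip_first = skip_first
        self.displacement = displacement
        self.temperature_K = self.isotherms[0].scheme.temperature_K
        self._mask = [
            np.arange(1 if skip_first else 0, iso.scheme.n_injections)
            for iso in self.isotherms
        ]

    # -- parameter vector: [ln Kd, dH, n, Qoff_1 .. Qoff_R] --------------
    def _predict(self, theta: np.ndarray) -> list[np.ndarray]:
        lnKd, dH, n = theta[:3]
        out = []
        for k, iso in enumerate(self.isotherms):
            p = BindingParams(n=n, Kd_M=float(np.exp(lnKd)), dH_kJmol=dH, Qoff_uJ=theta[3 + k])
            out.append(injection_heats(iso.scheme, p, self.displacement))
        return out

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        pred = self._predict(theta)
        return np.concatenate(
            [iso.heats_uJ[m] - pr[m] for iso, pr, m in zip(self.isotherms, pred, self._mask)]
        )

    def _initial_guess(self, init: BindingParams | None) -> np.ndarray:
        R = len(self.isotherms)
        if init is not None:
            base = [np.log(init.Kd_M), init.dH_kJmol, init.n]
            return np.array(base + [init.Qoff_uJ] * R)
        iso = self.isotherms[0]
        sch = iso.scheme
        first = 1 if (self.skip_first and sch.n_injections > 1) else 0
        # dH from the first large injection: all injected titrant binds there.
        mol_inj = sch.syringe_conc_M * sch.injection_volumes_uL[first] * 1e-6  # L*M = mol
        dH0 = (iso.heats_uJ[first] * 1e-6) / mol_inj / 1e3  # kJ/mol
        if not np.isfinite(dH0) or abs(dH0) < 1e-6:
            dH0 = -40.0
        # n from the molar ratio at the steepest drop of the heat series.
        M, X = sch.concentrations()
        d = np.abs(np.diff(iso.heats_uJ[first:]))
        infl = first + int(np.argmax(d)) if d.size else first
        n0 = float(np.clip(X[infl] / max(M[infl], 1e-12), 0.2, 2.0))
        Kd0 = sch.cell_conc0_M / 10.0
        return np.array([np.log(Kd0), dH0, n0] + [float(iso2.heats_uJ[-1]) for iso2 in self.isotherms])

    def fit(
        self,
        init: BindingParams | None = None,
        *,
        n_boot: int = 1000,
        seed: int | None = 0,
    ) -> "ITCFitResults":
        """Damped least-squares global fit.

        ``n_boot`` residual-bootstrap refits provide standard errors (0 skips
        the bootstrap).  Raises ``RuntimeError`` with solver diagnostics when
        the optimiser fails to converge.
        """
        theta0 = self._initial_guess(init)
        sol = least_squares(self._residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(f"ITC global fit did not converge: {sol.message}")
        boot = None
        if n_boot > 0:
            boot = self._bootstrap(sol.x, n_boot, seed)
        return ITCFitResults(self, sol, boot)

    def _bootstrap(self, theta_hat: np.ndarray, n_boot: int, seed: int | None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        pred = self._predict(theta_hat)
        resid = [iso.heats_uJ[m] - pr[m] for iso, pr, m in zip(self.isotherms, pred, self._mask)]
        pooled = np.concatenate(resid)
        samples = np.empty((n_boot, theta_hat.size))
        originals = [iso.heats_uJ.copy() for iso in self.isotherms]
        try:
            for b in range(n_boot):
                for iso, pr, m in zip(self.isotherms, pred, self._mask):
                    iso.heats_uJ = pr.copy()
                    iso.heats_uJ[m] = pr[m] + rng.choice(pooled, size=m.size, replace=True)
                sb = least_squares(self._residuals, theta_hat, method="lm")
                samples[b] = sb.x
        finally:
            for iso, orig in zip(self.isotherms, originals):
                iso.heats_uJ = orig
        return samples


class ITCFitResults:
    """Converged global-fit estimates with uncertainties and diagnostics."""

    def __init__(self, model: SingleSiteITCModel, sol, boot: np.ndarray | None):
        self.model = model
        self._sol = sol
        self._boot = boot
        self.theta = sol.x
        self.cost = float(2.0 * sol.cost)  # sum of squared residuals

    @property
    def params(self) -> BindingParams:
        """Shared (n, Kd, dH); Qoff of the first replicate."""
        return BindingParams(
            n=float(self.theta[2]),
            Kd_M=float(np.exp(self.theta[0])),
            dH_kJmol=float(self.theta[1]),
            Qoff_uJ=float(self.theta[3]),
        )

    @property
    def qoffs_uJ(self) -> np.ndarray:
        return self.theta[3:]

    @property
    def bse(self) -> dict[str, float] | None:
        """Bootstrap standard errors (Kd via the delta spread of exp(ln Kd))."""
        if self._boot is None:
            return None
        se = self._boot.std(axis=0, ddof=1)
        return {
            "Kd_M": float(np.exp(self._boot[:, 0]).std(ddof=1)),
            "dH_kJmol": float(se[1]),
            "n": float(se[2]),
            "Qoff_uJ": [float(s) for s in se[3:]],
        }

    @property
    def residuals(self) -> np.ndarray:
        return self._sol.fun

    def predicted(self) -> list[np.ndarray]:
        """Model heats per replicate at the fitted parameters."""
        return self.model._predict(self.theta)

    @property
    def thermo(self) -> ThermoResult:
        p = self.params
        return thermo_decompose(p.Kd_M, p.dH_kJmol, self.model.temperature_K)

    def summary(self) -> str:
        p, t = self.params, self.thermo
        bse = self.bse

        def fmt(value: float, se: float | None) -> str:
            return f"{value:12.6g}" if se is None else f"{value:12.6g} +/- {se:.3g}"

        kd_se = bse["Kd_M"] * 1e6 if bse else None
        lines = [
            "Single-site ITC global fit",
            "=" * 44,
            f"replicates:  {len(self.model.isotherms)}",
            f"temperature: {self.model.temperature_K:.1f} K",
            "Kd:          " + fmt(p.Kd_M * 1e6, kd_se) + " uM",
            "dH:          " + fmt(p.dH_kJmol, bse["dH_kJmol"] if bse else None) + " kJ/mol",
            "n:           " + fmt(p.n, bse["n"] if bse else None),
            f"dG:          {t.dG_kJmol:12.6g} kJ/mol",
            f"-TdS:        {t.minus_TdS_kJmol:12.6g} kJ/mol",
            "Qoff (uJ):   " + ", ".join(f"{q:.4g}" for q in self.qoffs_uJ),
            f"SSR:         {self.cost:12.6g} uJ^2",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured heats and fitted model vs titrant/cell molar ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predicted()
        for iso, pr in zip(self.model.isotherms, pred):
            M, X = iso.scheme.concentrations()
            ratio = self.params.n * M / X
            ax.plot(ratio, iso.heats_uJ, "o", ms=4, label=iso.replicate_id)
            ax.plot(ratio, pr, "-", color="0.3", lw=1)
        ax.set_xlabel("molar ratio n·M/X")
        ax.set_ylabel("heat per injection (µJ)")
        ax.legend(frameon=False)
        return ax

    def to_dict(self) -> dict:
        p, t = self.params, self.thermo
        out = {
            "n": p.n,
            "Kd_uM": p.Kd_M * 1e6,
            "dH_kJmol": p.dH_kJmol,
            "dG_kJmol": t.dG_kJmol,
            "minus_TdS_kJmol": t.minus_TdS_kJmol,
            "Qoff_uJ": [float(q) for q in self.qoffs_uJ],
            "ssr_uJ2": self.cost,
        }
        if self.bse is not None:
            out["bse"] = self.bse
        return out


def fit_global(
    isotherms: Sequence[Isotherm],
    init: BindingParams | None = None,
    *,
    skip_first: bool = True,
    displacement: str = "mean",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> tuple[BindingParams, dict | None, np.ndarray]:
    """Functional wrapper: returns (shared params, bootstrap SEs, residuals)."""
    res = SingleSiteITCModel(
        isotherms, skip_first=skip_first, displacement=displacement
    ).fit(init, n_boot=n_boot, seed=seed)
    return res.params, res.bse, res.residuals
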