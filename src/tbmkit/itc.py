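"""Single-site (1:1) binding model for isothermal titration calorimetry.

Implements the standard mass-action closed form for complex concentration,
forward simulation of an injection series with perfusion-cell dilution
bookkeeping, nonlinear least-squares fitting of (N, Kd, dH, baseline), and
derivation of dG/dS from (Kd, dH) at a stated temperature.

Units: concentrations molar, volumes litres, heats kcal per mole of
injectant, temperature kelvin.  Dissociation constants are handled on the
natural scale in the API and on a log scale inside the fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Gas constant in kcal/(mol.K).
R_KCAL = 1.9872e-3
#: Default experiment temperature (20 C), configurable per call.
DEFAULT_TEMPERATURE = 293.15


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection series geometry: what is injected into what.

    The syringe holds the titrant (peptide) at ``syringe_conc``; the cell of
    fixed volume ``cell_volume`` initially holds the titrand (receptor) at
    ``cell_conc``.
    """

    cell_volume: float  # litres
    injection_volumes: tuple[float, ...]  # litres
    syringe_conc: float  # molar
    cell_conc: float  # molar
    temperature: float = DEFAULT_TEMPERATURE  # kelvin

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.syringe_conc <= 0 or self.cell_conc <= 0:
            raise ValueError("volumes and concentrations must be > 0")
        if len(self.injection_volumes) < 2:
            raise ValueError("at least 2 injections required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")

    @classmethod
    def uniform(
        cls,
        n_injections: int = 19,
        injection_volume: float = 2e-6,
        cell_volume: float = 200e-6,
        syringe_conc: float = 0.45e-3,
        cell_conc: float = 0.06e-3,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "TitrationProtocol":
        """Equal-volume injection series (defaults: 19 x 2 uL into 200 uL)."""
        return cls(
            cell_volume=cell_volume,
            injection_volumes=(injection_volume,) * n_injections,
            syringe_conc=syringe_conc,
            cell_conc=cell_conc,
            temperature=temperature,
        )


@dataclass
class Isotherm:
    """Per-injection heats in kcal per mole of injectant."""

    heats: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)


@dataclass
class BindingParams:
    """Single-site model parameters with standard errors from the fit."""

    n: float  # stoichiometry (sites)
    kd: float  # molar
    dh: float  # kcal/mol
    q_dil: float = 0.0  # kcal/mol baseline offset
    n_se: float = math.nan
    kd_se: float = math.nan
    dh_se: float = math.nan
    q_dil_se: float = math.nan
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n <= 0:
            raise ValueError("kd and n must be > 0")


@dataclass(frozen=True)
class ThermoDerived:
    """Derived free energy and entropy at a temperature.

    ``dg`` in kcal/mol, ``ds`` in cal/(K.mol); by construction
    ``dg == dh - temperature * ds / 1000`` to machine precision.
    """

    dg: float
    ds: float
    dh: float
    temperature: float


def complex_concentration(mt: float, xt: float, kd: float, n: float = 1.0) -> float:
    """Equilibrium complex concentration [PL] for the 1:1 mass-action model.

    ``mt`` is total titrand (receptor) and ``xt`` total titrant (ligand),
    with ``n`` binding sites per receptor.  Returns the physical root of
    the quadratic; always ``0 <= [PL] <= min(n*mt, xt)``.
    """
    if mt < 0 or xt < 0:
        raise ValueError("total concentrations must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    sites = n * mt
    b = sites + xt + kd
    disc = b * b - 4.0 * sites * xt
    # numerically stable form of the smaller quadratic root
    return 2.0 * sites * xt / (b + math.sqrt(max(disc, 0.0)))


def model_heats(
    n: float, kd: float, dh: float, q_dil: float, protocol: TitrationProtocol
) -> np.ndarray:
    """Noise-free per-injection heats (kcal/mol of injectant).

    Perfusion-cell convention: each injection displaces an equal volume of
    the pre-injection cell contents (which leaves the sensed volume), then
    both total concentrations are updated.  The heat of injection i is the
    enthalpy of the change in moles of complex inside the cell, normalized
    per mole injected, plus the dilution baseline.
    """
    v0 = protocol.cell_volume
    mt = protocol.cell_conc
    xt = 0.0
    pl_prev = 0.0
    heats = np.empty(len(protocol.injection_volumes))
    for i, v in enumerate(protocol.injection_volumes):
        f = 1.0 - v / v0
        mt *= f
        xt = xt * f + protocol.syringe_conc * v / v0
        pl = complex_concentration(mt, xt, kd, n)
        q = dh * v0 * (pl - pl_prev * f)  # kcal released in the cell
        heats[i] = q / (protocol.syringe_conc * v) + q_dil
        pl_prev = pl
    return heats


def simulate_isotherm(
    params: BindingParams,
    protocol: TitrationProtocol,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Isotherm:
    """Forward-simulate an isotherm, optionally with Gaussian heat noise.

    Deterministic for a fixed ``seed``; ``noise_sd`` is in kcal/mol of
    injectant, applied per injection.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heats = model_heats(params.n, params.kd, params.dh, params.q_dil, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(heats=heats, normalized=True)


def wiseman_c(n: float, kd: float, cell_conc: float) -> tuple[float, Optional[str]]:
    """Wiseman c-value ``n * cell_conc / kd`` with an interpretability note.

    Returns ``(c, warning)``; the warning is None for c in [1, 1000] and a
    short message outside that window (sigmoidal-shape diagnostic only).
    """
    if n <= 0 or kd <= 0 or cell_conc <= 0:
        raise ValueError("all arguments must be > 0")
    c = n * cell_conc / kd
    warning = None
    if not 1.0 <= c <= 1000.0:
        warning = (
            f"c = {c:.3g} outside [1, 1000]: isotherm shape weakly "
            "constrains Kd"
        )
    return c, warning


def fit_single_site(
    isotherm: Isotherm,
    protocol: TitrationProtocol,
    init: Optional[BindingParams] = None,
    skip_first: bool = False,
) -> BindingParams:
    """Least-squares fit of (n, Kd, dH, baseline) to an isotherm.

    Kd is parameterized as log(Kd) internally for positivity and reported on
    the natural scale.  Standard errors come from the curvature of the
    objective at the optimum (linearized covariance, residual-variance
    scaled); unidentifiable directions yield infinite standard errors.
    Non-convergence is flagged on the result, not raised.

    ``skip_first`` drops injection 1 from the residuals (common practice for
    the short first injection), while keeping its dilution bookkeeping.
    """
    heats = np.asarray(isotherm.heats, dtype=float)
    if heats.shape[0] != len(protocol.injection_volumes):
        raise ValueError("isotherm length != number of injections")
    if heats.shape[0] < 4:
        raise ValueError("need at least 4 injections to fit 4 parameters")

    if init is None:
        init = BindingParams(
            n=1.0,
            kd=protocol.cell_conc / 10.0,
            dh=float(heats[0]) if abs(heats[0]) > 1e-9 else -1.0,
            q_dil=float(heats[-1]),
        )

    mask = np.ones_like(heats, dtype=bool)
    if skip_first:
        mask[0] = False

    def residuals(x: np.ndarray) -> np.ndarray:
        n, log_kd, dh, q_dil = x
        model = model_heats(n, math.exp(log_kd), dh, q_dil, protocol)
        return (model - heats)[mask]

    x0 = np.array([init.n, math.log(init.kd), init.dh, init.q_dil])
    lower = np.array([1e-6, math.log(1e-15), -1e4, -1e4])
    upper = np.array([1e3, math.log(10.0), 1e4, 1e4])
    result = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-12,
                           ftol=1e-12, gtol=1e-12)

    n_hat, log_kd_hat, dh_hat, q_dil_hat = result.x
    kd_hat = math.exp(log_kd_hat)
    warnings: list[str] = []
    converged = bool(result.success)
    if not converged:
        warnings.append(f"fit did not converge: {result.message}")

    # curvature-based standard errors
    m = int(mask.sum())
    dof = m - 4
    ses = np.full(4, math.inf)
    if dof > 0:
        jtj = result.jac.T @ result.jac
        s2 = 2.0 * result.cost / dof
        try:
            cond = np.linalg.cond(jtj)
            if not np.isfinite(cond) or cond > 1e14:
                raise np.linalg.LinAlgError("ill-conditioned")
            cov = s2 * np.linalg.inv(jtj)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            warnings.append("parameters poorly identified; standard errors "
                            "unreliable (reported as inf)")

    c_value, c_warning = wiseman_c(n_hat, kd_hat, protocol.cell_conc)
    if c_warning:
        warnings.append(c_warning)

    return BindingParams(
        n=float(n_hat),
        kd=float(kd_hat),
        dh=float(dh_hat),
        q_dil=float(q_dil_hat),
        n_se=float(ses[0]),
        kd_se=float(kd_hat * ses[1]),  # delta method from log scale
        dh_se=float(ses[2]),
        q_dil_se=float(ses[3]),
        converged=converged,
        warnings=warnings,
    )


def derive_thermo(
    kd: float, dh: float, temperature: float = DEFAULT_TEMPERATURE
) -> ThermoDerived:
    """Derive dG and dS from (Kd, dH) at a temperature.

    ``dG = R * T * ln(Kd)`` (standard state 1 M, R = 1.9872e-3
    kcal/(mol.K)) and ``dS = 1000 * (dH - dG) / T`` in cal/(K.mol).
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    dg = R_KCAL * temperature * math.log(kd)
    ds = 1000.0 * (dh - dg) / temperature
    return ThermoDerived(dg=dg, ds=ds, dh=dh, temperature=temperature)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_isotherm_tsv(
    isotherm: Isotherm,
    protocol: TitrationProtocol,
    target: Union[str, Path, IO[str]],
) -> None:
    """Isotherm TSV: injection_index, injection_volume_uL, heat_kcal_per_mol."""
    frame = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(isotherm.heats) + 1),
            "injection_volume_uL": np.array(protocol.injection_volumes) * 1e6,
            "heat_kcal_per_mol": isotherm.heats,
        }
    )
    frame.to_csv(target, sep="\t", index=False, float_format="%.6g")


def read_isotherm_tsv(source: Union[str, Path, IO[str]]) -> tuple[Isotherm, np.ndarray]:
    """Read an isotherm TSV; returns (isotherm, injection volumes in litres)."""
    frame = pd.read_csv(source, sep="\t", comment="#")
    return (
        Isotherm(heats=frame["heat_kcal_per_mol"].to_numpy()),
        frame["injection_volume_uL"].to_numpy() * 1e-6,
    )


def fit_report(params: BindingParams, protocol: TitrationProtocol) -> dict:
    """JSON-ready fit summary with parameters, errors and the c-value."""
    c_value, _ = wiseman_c(params.n, params.kd, protocol.cell_conc)
    return {
        "n": params.n, "n_se": params.n_se,
        "kd_M": params.kd, "kd_se_M": params.kd_se,
        "dh_kcal_per_mol": params.dh, "dh_se": params.dh_se,
        "q_dil_kcal_per_mol": params.q_dil, "q_dil_se": params.q_dil_se,
        "c_value": c_value,
        "converged": params.converged,
        "warnings": params.warnings,
    }
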