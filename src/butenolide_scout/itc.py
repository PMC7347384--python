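"""One-site isothermal titration calorimetry: model, simulator, and fit.

An ITC experiment titrates ligand (syringe concentration X0) into a cell of
macromolecule (M0, volume V0) and records the heat of each injection.  For a
single class of n independent sites with dissociation constant Kd and molar
enthalpy dH, the free/bound equilibrium after injection i gives the complex
concentration as the smaller root of

    c^2 - c*(n*Mt + Xt + Kd) + n*Mt*Xt = 0,

with Mt, Xt the displacement-corrected total concentrations.  Cumulative
heat is Q_i = c_i * V0 * dH and the differential heat of injection i,
corrected for the liquid expelled from the overfilled cell, is

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2,

normalized per mole of injected ligand.  The shape of the normalized
isotherm against molar ratio Xt/Mt is governed by the Wiseman parameter
c = n * M0 / Kd: for c >> 1 the curve is sigmoidal with its inflection at
molar ratio ~ n.

Units: concentrations in M, volumes in L, dH in cal/mol internally,
normalized heats in kcal per mol of injectant, dG in kcal/mol,
dS in cal/(mol*K).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ItcProtocol",
    "ThermoParams",
    "Isotherm",
    "BindingFit",
    "PAPER_PROTOCOL",
    "GAS_CONSTANT_CAL",
    "model_heats",
    "simulate",
    "fit_one_site",
    "thermo_derive",
    "wiseman_c",
    "write_isotherm",
    "read_isotherm",
    "FitDegenerateError",
]

GAS_CONSTANT_CAL = 1.987  # cal / (mol K)


class FitDegenerateError(ValueError):
    """The isotherm cannot constrain a one-site fit (e.g. truncated curve)."""


@dataclass(frozen=True)
class ItcProtocol:
    """Instrument protocol: cell volume/conc, syringe conc, injections, T."""

    cell_volume: float  # L
    cell_conc: float  # M (macromolecule)
    syringe_conc: float  # M (ligand)
    injection_volumes: tuple[float, ...]  # L each
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        vals = (self.cell_volume, self.cell_conc, self.temperature)
        if any(v <= 0 for v in vals) or self.syringe_conc < 0:
            raise ValueError("protocol quantities must be positive")
        if len(self.injection_volumes) < 2 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("need >= 2 positive injection volumes")


#: VP-ITC protocol used for the avenolide/AvaR1 titration: 1.8 mL cell at
#: 8 uM protein, 80 uM ligand syringe, 35 injections (one 2 uL pre-injection
#: then 34 x 7 uL), 25 C.
PAPER_PROTOCOL = ItcProtocol(
    cell_volume=1.8e-3,
    cell_conc=8e-6,
    syringe_conc=80e-6,
    injection_volumes=(2e-6,) + (7e-6,) * 34,
    temperature=298.15,
)


@dataclass(frozen=True)
class ThermoParams:
    n: float  # sites per macromolecule
    kd: float  # M
    dh: float  # cal per mol of ligand

    def __post_init__(self) -> None:
        if self.n <= 0 or self.kd <= 0:
            raise ValueError("n and kd must be positive")


@dataclass
class Isotherm:
    molar_ratio: np.ndarray  # Xt/Mt per injection
    heat: np.ndarray  # kcal per mol of injectant

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat = np.asarray(self.heat, dtype=float)
        if self.molar_ratio.shape != self.heat.shape:
            raise ValueError("molar_ratio and heat must have equal length")
        # strictly increasing whenever ligand is actually titrated; a
        # zero-syringe control collapses every ratio to the same value
        if np.any(np.diff(self.molar_ratio) < 0):
            raise ValueError("molar_ratio must be non-decreasing")


@dataclass
class BindingFit:
    params: ThermoParams
    dg: float  # kcal/mol
    ds: float  # cal/(mol K)
    se_n: float
    se_kd: float
    se_dh: float
    residual_norm: float
    converged: bool
    message: str = ""


def _total_concentrations(protocol: ItcProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Displacement-corrected Mt and Xt after each injection.

    Each injection expels liquid from the overfilled cell; the standard
    correction treats the expelled aliquot as having the average of the pre-
    and post-injection composition, giving with cumulative volume v:
    Mt = M0*(1 - v/2V0)/(1 + v/2V0) and Xt = X0*(v/V0)/(1 + v/2V0).
    """
    v = np.cumsum(protocol.injection_volumes)
    v0 = protocol.cell_volume
    f = v / (2.0 * v0)
    mt = protocol.cell_conc * (1.0 - f) / (1.0 + f)
    xt = protocol.syringe_conc * (v / v0) / (1.0 + f)
    return mt, xt


def _complex_concentration(n: float, kd: float, mt: np.ndarray, xt: np.ndarray) -> np.ndarray:
    """Smaller root of c^2 - c(n*Mt + Xt + Kd) + n*Mt*Xt = 0, clipped at 0."""
    b = n * mt + xt + kd
    disc = b * b - 4.0 * n * mt * xt
    disc = np.maximum(disc, 0.0)
    # smaller root in a cancellation-safe form
    c = 2.0 * n * mt * xt / (b + np.sqrt(disc))
    return np.clip(c, 0.0, None)


def model_heats(
    params: ThermoParams,
    protocol: ItcProtocol,
    dilution_correction: bool = True,
) -> Isotherm:
    """Noise-free normalized heats (kcal/mol injectant) for each injection.

    ``dilution_correction=False`` drops the expelled-volume term in the
    differential heat, making cumulative heat exactly telescoping (useful
    for conservation checks).
    """
    mt, xt = _total_concentrations(protocol)
    c = _complex_concentration(params.n, params.kd, mt, xt)
    v0 = protocol.cell_volume
    q = c * v0 * params.dh  # cumulative heat, cal
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = np.asarray(protocol.injection_volumes)
    dq = q - q_prev
    if dilution_correction:
        dq = dq + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = protocol.syringe_conc * dv
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(moles_injected > 0, dq / moles_injected / 1000.0, 0.0)
    ratio = np.where(mt > 0, xt / mt, np.inf)
    return Isotherm(molar_ratio=ratio, heat=normalized)


def wiseman_c(params: ThermoParams, protocol: ItcProtocol) -> float:
    """Dimensionless sharpness parameter c = n * M0 / Kd."""
    return params.n * protocol.cell_conc / params.kd


def simulate(
    params: ThermoParams,
    protocol: ItcProtocol,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Isotherm:
    """Model heats plus i.i.d. Gaussian noise (sd in kcal/mol injectant)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    iso = model_heats(params, protocol)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        iso = Isotherm(
            molar_ratio=iso.molar_ratio,
            heat=iso.heat + rng.normal(0.0, noise_sd, size=iso.heat.shape),
        )
    return iso


def _initial_guess(iso: Isotherm, protocol: ItcProtocol, skip: int) -> ThermoParams:
    r = iso.molar_ratio[skip:]
    h = iso.heat[skip:]
    head = float(np.mean(h[:3]))
    tail = float(np.mean(h[-2:]))
    # a curve that still sits on its initial plateau never crossed n
    if abs(tail) > 0.5 * abs(head):
        raise FitDegenerateError(
            "isotherm does not bracket its inflection: heats have not decayed "
            f"over molar-ratio range [{r[0]:.3g}, {r[-1]:.3g}]"
        )
    slopes = np.diff(h) / np.diff(r)
    steepest = int(np.argmax(np.abs(slopes)))
    n0 = float(np.clip((r[steepest] + r[steepest + 1]) / 2.0, 0.05, None))
    dh0 = head * 1000.0  # cal/mol
    kd0 = n0 * protocol.cell_conc / 10.0  # c ~ 10 prior
    return ThermoParams(n=n0, kd=kd0, dh=dh0 if dh0 != 0 else -1000.0)


def fit_one_site(
    iso: Isotherm,
    protocol: ItcProtocol,
    init: ThermoParams | None = None,
    skip_first: int = 1,
) -> BindingFit:
    """Nonlinear least-squares fit of (n, Kd, dH) to a normalized isotherm.

    The first injection is excluded by default (small pre-injection,
    diffusion across the syringe tip corrupts its heat).  Kd is fitted on a
    log scale to enforce positivity; standard errors come from the Jacobian
    at the optimum (Gauss-Newton curvature), with the Kd error delta-mapped
    back to the linear scale.
    """
    if len(iso.heat) - skip_first < 5:
        raise FitDegenerateError("need >= 5 usable injections")
    if init is None:
        init = _initial_guess(iso, protocol, skip_first)
    obs = iso.heat[skip_first:]

    def residuals(theta: np.ndarray) -> np.ndarray:
        n, log_kd, dh = theta
        model = model_heats(ThermoParams(n=n, kd=math.exp(log_kd), dh=dh), protocol)
        return model.heat[skip_first:] - obs

    x0 = np.array([init.n, math.log(init.kd), init.dh])
    sol = least_squares(
        residuals,
        x0,
        bounds=([1e-3, math.log(1e-15), -1e7], [100.0, math.log(10.0), 1e7]),
        xtol=1e-12,
        ftol=1e-12,
    )
    n_fit, log_kd_fit, dh_fit = sol.x
    params = ThermoParams(n=float(n_fit), kd=float(math.exp(log_kd_fit)), dh=float(dh_fit))

    dof = max(1, len(obs) - 3)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_n, se_logkd, se_dh = se
    except np.linalg.LinAlgError:
        se_n = se_logkd = se_dh = math.nan
    dg, ds = thermo_derive(params, protocol.temperature)
    return BindingFit(
        params=params,
        dg=dg,
        ds=ds,
        se_n=float(se_n),
        se_kd=float(params.kd * se_logkd),
        se_dh=float(se_dh),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        message=sol.message,
    )


def recovery_experiment(
    truth: ThermoParams = ThermoParams(n=1.0, kd=42.5e-9, dh=-10000.0),
    protocol: ItcProtocol = PAPER_PROTOCOL,
    n_replicates: int = 100,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> list[BindingFit]:
    """Simulate-and-refit experiment: noisy isotherms fitted one by one.

    Each replicate draws fresh instrument noise from a child generator of
    ``seed``, so the whole experiment is reproducible.  Ground truth
    defaults to the avenolide/AvaR1 titration values (1:1, Kd 42.5 nM).
    """
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_replicates):
        iso = simulate(truth, protocol, noise_sd=noise_sd, seed=rng)
        fits.append(fit_one_site(iso, protocol))
    return fits


def thermo_derive(params: ThermoParams, temperature: float) -> tuple[float, float]:
    """Free energy and entropy from Kd and dH.

    dG = R*T*ln(Kd / 1 M) in kcal/mol (negative for sub-molar Kd);
    dS = (dH - dG) / T in cal/(mol*K).
    """
    dg_cal = GAS_CONSTANT_CAL * temperature * math.log(params.kd)
    ds = (params.dh - dg_cal) / temperature
    return dg_cal / 1000.0, ds


def write_isotherm(iso: Isotherm, protocol: ItcProtocol, path) -> None:
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(iso.heat) + 1),
            "volume_L": protocol.injection_volumes[: len(iso.heat)],
            "molar_ratio": iso.molar_ratio,
            "heat_kcal_per_mol": iso.heat,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_isotherm(path) -> Isotherm:
    df = pd.read_csv(path, sep="\t")
    return Isotherm(
        molar_ratio=df["molar_ratio"].to_numpy(),
        heat=df["heat_kcal_per_mol"].to_numpy(),
    )


def fit_report_json(fit: BindingFit, path=None) -> str:
    payload = {
        "n": fit.params.n,
        "kd_M": fit.params.kd,
        "dh_cal_per_mol": fit.params.dh,
        "dg_kcal_per_mol": fit.dg,
        "ds_cal_per_mol_K": fit.ds,
        "se_n": fit.se_n,
        "se_kd_M": fit.se_kd,
        "se_dh": fit.se_dh,
        "residual_norm": fit.residual_norm,
        "converged": fit.converged,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
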