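"""One-site ITC binding isotherm: forward simulation and nonlinear fit.

The model is the single-set-of-sites (Wiseman) isotherm used by standard
ITC fitting software.  With macromolecule (here: the DNA duplex, in the
cell) at ``Mt`` and titrant (the protein, in the syringe) at ``Xt`` after
injection *i*, the cumulative heat is

    Q_i = (n Mt dH V0 / 2) [ 1 + Xt/(n Mt) + 1/(n Ka Mt)
          - sqrt( (1 + Xt/(n Mt) + 1/(n Ka Mt))^2 - 4 Xt/(n Mt) ) ]

and the heat of injection *i* is the finite difference with the standard
displaced-volume correction

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) (Q_i + Q_{i-1}) / 2 + q0 .

Cell concentrations are diluted by injection using the symmetric
convention Mt = M0 (1 - v/2V0)/(1 + v/2V0), Xt = X0 (v/V0)/(1 + v/2V0)
with v the cumulative injected volume.

Units: volumes in µl, concentrations in µM, dH in cal/mol of injectant,
heats in µcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol: titrant in the syringe, macromolecule in the cell."""

    cell_volume: float = 200.0  # V0, µl (iTC200 nominal)
    cell_conc: float = 20.0  # M0, µM (DNA duplex)
    syringe_conc: float = 400.0  # X0, µM (protein)
    injection_volumes: Tuple[float, ...] = tuple([1.6] * 24)  # µl
    temperature: float = 25.0  # °C

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("cell_volume, cell_conc and syringe_conc must be > 0")
        if not self.injection_volumes or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class BindingParameters:
    """One-site isotherm parameters."""

    n: float  # stoichiometry, titrant per macromolecule
    kd: float  # µM
    dh: float  # cal/mol of injectant
    q0: float = 0.0  # per-injection baseline heat, µcal

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"stoichiometry must be > 0, got {self.n}")
        if self.kd <= 0:
            raise ValueError(f"Kd must be > 0, got {self.kd}")

    @property
    def ka(self) -> float:
        """Association constant, µM^-1."""
        return 1.0 / self.kd

    @property
    def kd_nm(self) -> float:
        return self.kd * 1000.0


@dataclass(frozen=True)
class Thermogram:
    """Per-injection molar ratio and observed injection heats (µcal)."""

    molar_ratio: Tuple[float, ...]  # Xt_i / Mt_i after each injection
    heats: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.molar_ratio) != len(self.heats):
            raise ValueError("molar_ratio and heats must have equal length")

    def __len__(self) -> int:
        return len(self.heats)


def _concentrations(protocol: TitrationProtocol) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative-volume-corrected Mt, Xt (µM) and dV (µl) per injection."""
    dv = np.asarray(protocol.injection_volumes, dtype=float)
    v = np.cumsum(dv)
    v0 = protocol.cell_volume
    mt = protocol.cell_conc * (1 - v / (2 * v0)) / (1 + v / (2 * v0))
    xt = protocol.syringe_conc * (v / v0) / (1 + v / (2 * v0))
    return mt, xt, dv


def _cumulative_heat(
    params: BindingParameters, mt: np.ndarray, xt: np.ndarray, v0: float
) -> np.ndarray:
    """Wiseman cumulative heat Q_i in µcal (quadratic-root bound fraction)."""
    n, ka, dh = params.n, params.ka, params.dh
    r = xt / (n * mt)
    term = 1.0 + r + 1.0 / (n * ka * mt)
    root = np.sqrt(np.maximum(term * term - 4.0 * r, 0.0))
    # µM * cal/mol * µl = 1e-6 mol/L * cal/mol * 1e-6 L = 1e-12 cal = 1e-6 µcal
    scale = 1e-6
    return (n * mt * dh * v0 / 2.0) * (term - root) * scale


def simulate_titration(
    params: BindingParameters,
    protocol: TitrationProtocol = TitrationProtocol(),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Thermogram:
    """Forward-simulate per-injection heats, optionally with Gaussian noise.

    ``noise_sd`` is the standard deviation of additive heat noise in µcal;
    with the same seed the thermogram is identical across runs.
    """
    mt, xt, dv = _concentrations(protocol)
    v0 = protocol.cell_volume
    q = _cumulative_heat(params, mt, xt, v0)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + params.q0
    if noise_sd:
        rng = np.random.default_rng(seed)
        dq = dq + rng.normal(0.0, noise_sd, size=dq.shape)
    ratio = xt / mt
    return Thermogram(tuple(ratio.tolist()), tuple(dq.tolist()))


@dataclass(frozen=True)
class FitResult:
    """One-site fit output: parameters, standard errors, diagnostics."""

    params: BindingParameters
    std_errors: Dict[str, float]
    residual_norm: float
    converged: bool
    identifiable: bool
    message: str = ""
    n_injections: int = 0


def _model_heats(theta: np.ndarray, protocol: TitrationProtocol) -> np.ndarray:
    n, kd, dh, q0 = theta
    params = BindingParameters(n=n, kd=kd, dh=dh, q0=q0)
    return np.asarray(simulate_titration(params, protocol, noise_sd=0.0).heats)


def fit_one_site(
    thermogram: Thermogram,
    protocol: TitrationProtocol = TitrationProtocol(),
    init: Optional[BindingParameters] = None,
) -> FitResult:
    """Nonlinear least-squares fit of (n, Kd, dH, q0) to observed heats.

    Default initialization: n = 1, Kd = M0/10, dH = sign of the
    largest-magnitude heat x 5000 cal/mol, q0 = mean of the last three
    heats.  Non-convergence is reported in the status flags with
    best-effort parameters, never silently.
    """
    heats = np.asarray(thermogram.heats, dtype=float)
    if len(heats) < 6:
        raise ValueError(f"need >= 6 injections to fit, got {len(heats)}")
    if len(heats) != len(protocol.injection_volumes):
        raise ValueError(
            "thermogram length does not match protocol injection count"
        )
    if init is None:
        peak = heats[np.argmax(np.abs(heats))]
        q0_init = float(np.mean(heats[-3:]))
        dh_init = float(np.sign(peak) * 5000.0) if peak != 0 else 5000.0
        init = BindingParameters(
            n=1.0, kd=protocol.cell_conc / 10.0, dh=dh_init, q0=q0_init
        )

    x0 = np.array([init.n, init.kd, init.dh, init.q0], dtype=float)
    lower = np.array([1e-6, 1e-9, -np.inf, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model_heats(theta, protocol) - heats

    sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    n, kd, dh, q0 = sol.x
    params = BindingParameters(n=float(n), kd=float(kd), dh=float(dh), q0=float(q0))

    # standard errors from the Jacobian at the solution
    dof = max(len(heats) - 4, 1)
    s2 = 2.0 * sol.cost / dof
    names = ("n", "kd", "dh", "q0")
    identifiable = True
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * s2
        se = {k: float(np.sqrt(max(cov[i, i], 0.0))) for i, k in enumerate(names)}
    except np.linalg.LinAlgError:
        se = {k: float("inf") for k in names}
        identifiable = False
    # wide relative SE on Kd, or a Kd the data are insensitive to
    # (degenerate Jacobian column, e.g. a flat thermogram), marks an
    # unidentifiable isotherm
    col_norms = np.linalg.norm(sol.jac, axis=0)
    if col_norms[1] <= 1e-8 * max(float(col_norms.max()), 1.0):
        identifiable = False
    if not np.isfinite(se["kd"]) or se["kd"] > 10.0 * params.kd:
        identifiable = False
    return FitResult(
        params=params,
        std_errors=se,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
        identifiable=identifiable,
        message=str(sol.message),
        n_injections=len(heats),
    )


def fold_change(kd_variant: float, kd_reference: float) -> float:
    """Affinity fold-change Kd_variant / Kd_reference (both > 0)."""
    if kd_variant <= 0 or kd_reference <= 0:
        raise ValueError("Kd values must be positive")
    return kd_variant / kd_reference


def c_value(
    params: BindingParameters, protocol: TitrationProtocol = TitrationProtocol()
) -> Tuple[float, bool]:
    """Wiseman c parameter n*M0/Kd and whether it lies in the fittable
    window 1 <= c <= 1000."""
    c = params.n * protocol.cell_conc / params.kd
    return c, 1.0 <= c <= 1000.0


def write_thermogram_tsv(
    thermogram: Thermogram,
    protocol: TitrationProtocol,
    path: Union[str, Path],
) -> None:
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(thermogram) + 1),
            "volume_ul": protocol.injection_volumes,
            "molar_ratio": thermogram.molar_ratio,
            "heat_ucal": thermogram.heats,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_thermogram_tsv(path: Union[str, Path]) -> Tuple[Thermogram, Tuple[float, ...]]:
    """Read a thermogram TSV; returns the thermogram and injection volumes."""
    df = pd.read_csv(path, sep="\t")
    required = {"injection", "volume_ul", "heat_ucal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    ratio = (
        tuple(df["molar_ratio"].tolist())
        if "molar_ratio" in df.columns
        else tuple([float("nan")] * len(df))
    )
    return Thermogram(ratio, tuple(df["heat_ucal"].tolist())), tuple(
        df["volume_ul"].tolist()
    )
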