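"""The facilitated-dissociation model of the albumin-mediated uptake effect.

Albumin-bound ligand interacting with the cell surface releases extra
unbound ligand next to the membrane, adding a second uptake path on top of
the free-drug one.  With [A] the albumin concentration (uM), K_d the
albumin-ligand dissociation constant (uM), K_d,m the albumin-membrane
dissociation constant (uM, a property of the cell line shared by all
ligands) and V_b,max (pmol/min/mg) the clearance capacity of the facilitated
path (the non-identifiable product B_max * CL_b,int), the full model reads

    CL_int,u(+A) = CL_int,u(-A) + V_b,max * [A] / (K_d * (K_d,m + [A]))

Dividing by the albumin-free clearance and assuming the ratio
V_b,max / CL_int,u(-A) is ligand-independent gives the reduced model for the
fold change R with a single transporter-specific constant EFD (uM), the
extent of facilitated dissociation:

    R = 1 + EFD * [A] / (K_d * (K_d,m + [A]))

Both forms are fitted by shared-parameter nonlinear least squares across
substrates: one K_d,m (and, for the reduced model, one EFD) jointly with
per-substrate V_b,max.  With few substrates on one cell line K_d,m may be
unidentifiable; the sequential strategy fits the better-populated line
first and freezes its K_d,m for the other (see :func:`sequential_fd_fit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FDSeries", "RatioSeries", "FDFit",
    "fd_predict_clint", "fd_predict_R",
    "fit_fd_full", "fit_fd_reduced", "sequential_fd_fit",
]


def fd_predict_clint(clint_free: float, vbmax: float, kdm: float,
                     kd: float, albumin) -> float:
    """Unbound intrinsic clearance in the presence of albumin (full model)."""
    if clint_free <= 0:
        raise ValueError("albumin-free clearance must be positive")
    for name, v in (("vbmax", vbmax), ("kdm", kdm), ("kd", kd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    albumin = np.asarray(albumin, dtype=float)
    out = clint_free + vbmax * albumin / (kd * (kdm + albumin))
    return float(out) if out.ndim == 0 else out


def fd_predict_R(efd: float, kdm: float, kd: float, albumin) -> float:
    """Fold change in active clearance (reduced model); 1 at zero albumin."""
    for name, v in (("efd", efd), ("kdm", kdm), ("kd", kd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    albumin = np.asarray(albumin, dtype=float)
    out = 1.0 + efd * albumin / (kd * (kdm + albumin))
    return float(out) if out.ndim == 0 else out


@dataclass
class FDSeries:
    """Active clearance of one substrate across albumin levels (full model).

    ``albumin`` (uM) must include the zero level; ``clint_active`` are the
    matching mean active clearances (uL/min/mg).  ``kd`` comes from the
    binding stage.
    """

    substrate: str
    kd: float
    albumin: np.ndarray
    clint_active: np.ndarray

    def __post_init__(self) -> None:
        self.albumin = np.asarray(self.albumin, dtype=float)
        self.clint_active = np.asarray(self.clint_active, dtype=float)
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if len(self.albumin) != len(self.clint_active):
            raise ValueError("albumin and clearance lengths differ")
        if not np.any(self.albumin == 0):
            raise ValueError("the albumin-free level is required")

    @property
    def clint_free(self) -> float:
        return float(self.clint_active[self.albumin == 0][0])


@dataclass
class RatioSeries:
    """Fold-change ratios R of one substrate at nonzero albumin levels."""

    substrate: str
    kd: float
    albumin: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.albumin = np.asarray(self.albumin, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if np.any(self.albumin <= 0):
            raise ValueError("ratio data are defined at nonzero albumin only")
        if np.any(self.r <= 0):
            raise ValueError("R must be positive")


@dataclass
class FDFit:
    """Result of a facilitated-dissociation fit."""

    kdm: float
    kdm_se: float | None
    kdm_fixed: bool
    vbmax: dict = field(default_factory=dict)     # substrate -> value (full model)
    vbmax_se: dict = field(default_factory=dict)
    efd: float | None = None                      # reduced model
    efd_se: float | None = None
    ssr: float = 0.0
    df: int = 0
    converged: bool = False
    residual_scale: str = "log"
    n_points: int = 0


_BOUNDS = (np.log(1e-3), np.log(1e6))


def _residual(pred: np.ndarray, obs: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log":
        return np.log(np.maximum(pred, 1e-300)) - np.log(obs)
    if scale == "relative":
        return (pred - obs) / pred
    if scale == "linear":
        return pred - obs
    raise ValueError(f"unknown residual scale {scale!r}")


def _multistart(residuals, n_params: int, n_starts: int = 8,
                rng: np.random.Generator | None = None):
    """Run bounded least squares from log-spaced starting points."""
    lo, hi = _BOUNDS
    grid = np.linspace(np.log(1.0), np.log(1e5), n_starts)
    best = None
    for g in grid:
        x0 = np.full(n_params, g)
        if rng is not None:
            x0 = x0 + rng.uniform(-0.1, 0.1, n_params)
        sol = least_squares(residuals, x0=x0, bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _param_se(sol, dof: int) -> np.ndarray | None:
    """Asymptotic SEs of the log-parameters from the Jacobian."""
    if dof <= 0:
        return None
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (2 * sol.cost / dof)
    except np.linalg.LinAlgError:
        return None
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def fit_fd_full(
    data: list[FDSeries],
    kdm_fixed: float | None = None,
    residual_scale: str = "log",
    rng: np.random.Generator | None = None,
) -> FDFit:
    """Joint fit of the full model: shared K_d,m, per-substrate V_b,max.

    The albumin-free clearance of each series is held at its measured value
    (it is a datum of the model, not a parameter).  Residuals default to the
    log scale — clearances span orders of magnitude with roughly constant
    CV, so multiplicative errors are the natural assumption.
    """
    if not data:
        raise ValueError("no substrate series supplied")
    if kdm_fixed is None and len(data) < 2:
        raise ValueError("a shared K_d,m cannot be identified from a single "
                         "substrate; supply kdm_fixed or more substrates")
    for s in data:
        if np.count_nonzero(s.albumin) < 2:
            raise ValueError(f"{s.substrate}: need >=2 nonzero albumin levels")

    n_sub = len(data)
    free_kdm = kdm_fixed is None
    offset = 1 if free_kdm else 0

    def residuals(p: np.ndarray) -> np.ndarray:
        kdm = np.exp(p[0]) if free_kdm else kdm_fixed
        out = []
        for j, s in enumerate(data):
            vb = np.exp(p[offset + j])
            pred = s.clint_free + vb * s.albumin / (s.kd * (kdm + s.albumin))
            out.append(_residual(pred, s.clint_active, residual_scale))
        return np.concatenate(out)

    sol = _multistart(residuals, offset + n_sub, rng=rng)
    n_points = sum(len(s.albumin) for s in data)
    df = n_points - (offset + n_sub)
    ses = _param_se(sol, df)

    kdm = float(np.exp(sol.x[0])) if free_kdm else float(kdm_fixed)
    fit = FDFit(kdm=kdm,
                kdm_se=(kdm * float(ses[0]) if (free_kdm and ses is not None) else None),
                kdm_fixed=not free_kdm, ssr=float(2 * sol.cost), df=df,
                converged=bool(sol.success), residual_scale=residual_scale,
                n_points=n_points)
    for j, s in enumerate(data):
        vb = float(np.exp(sol.x[offset + j]))
        fit.vbmax[s.substrate] = vb
        fit.vbmax_se[s.substrate] = (vb * float(ses[offset + j])
                                     if ses is not None else None)
    return fit


def fit_fd_reduced(
    data: list[RatioSeries],
    kdm_fixed: float | None = None,
    residual_scale: str = "log",
    rng: np.random.Generator | None = None,
) -> FDFit:
    """Joint fit of the reduced model: shared EFD (and K_d,m unless fixed)."""
    if not data:
        raise ValueError("no ratio series supplied")
    n_points = sum(len(s.albumin) for s in data)
    free_kdm = kdm_fixed is None
    n_params = 2 if free_kdm else 1
    if n_points <= n_params:
        raise ValueError("not enough ratio points to identify the model")
    if free_kdm and len(data) < 2 and n_points < 3:
        raise ValueError("EFD and K_d,m cannot both be identified from a "
                         "single two-point series; supply kdm_fixed")

    def residuals(p: np.ndarray) -> np.ndarray:
        efd = np.exp(p[0])
        kdm = np.exp(p[1]) if free_kdm else kdm_fixed
        out = []
        for s in data:
            pred = 1.0 + efd * s.albumin / (s.kd * (kdm + s.albumin))
            out.append(_residual(pred, s.r, residual_scale))
        return np.concatenate(out)

    sol = _multistart(residuals, n_params, rng=rng)
    df = n_points - n_params
    ses = _param_se(sol, df)

    efd = float(np.exp(sol.x[0]))
    kdm = float(np.exp(sol.x[1])) if free_kdm else float(kdm_fixed)
    return FDFit(
        kdm=kdm,
        kdm_se=(kdm * float(ses[1]) if (free_kdm and ses is not None) else None),
        kdm_fixed=not free_kdm,
        efd=efd,
        efd_se=(efd * float(ses[0]) if ses is not None else None),
        ssr=float(2 * sol.cost), df=df, converged=bool(sol.success),
        residual_scale=residual_scale, n_points=n_points,
    )


def sequential_fd_fit(
    primary: list[RatioSeries],
    secondary: list[RatioSeries],
    residual_scale: str = "log",
) -> tuple[FDFit, FDFit]:
    """Two-line strategy: joint fit on the substrate-rich line, then the
    other line with K_d,m frozen at the first estimate.

    The albumin-membrane interaction is a property of the cell surface, so
    sharing K_d,m across two lines of the same parental cell type is the
    assumption that makes the sparser line identifiable.
    """
    first = fit_fd_reduced(primary, residual_scale=residual_scale)
    second = fit_fd_reduced(secondary, kdm_fixed=first.kdm,
                            residual_scale=residual_scale)
    return first, second
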