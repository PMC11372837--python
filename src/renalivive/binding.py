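"""Albumin-ligand binding: the dissociation constant K_d from equilibrium
dialysis.

A single-site binding model with ligand in trace amounts relative to albumin
gives a hyperbolic fraction unbound

    f_u = K_d / (K_d + [A])

where [A] is the albumin molar concentration (uM).  K_d is estimated by
nonlinear least squares from measured fraction-unbound values at one or more
albumin levels.  Substrates that barely bind albumin (f_u near 1 at every
level) leave K_d unconstrained from above; such fits are flagged rather than
trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .domain import AlbuminCondition

__all__ = ["BindingMeasurement", "KdFit", "predict_fu", "fit_kd"]


@dataclass
class BindingMeasurement:
    """Fraction unbound of one substrate at one albumin condition."""

    substrate: str
    condition: AlbuminCondition
    fu_replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for fu in self.fu_replicates:
            if not (0 < fu <= 1):
                raise ValueError(f"fraction unbound must be in (0, 1], got {fu}")

    @property
    def fu_mean(self) -> float:
        return float(np.mean(self.fu_replicates))

    @property
    def fu_sd(self) -> float:
        if len(self.fu_replicates) < 2:
            return 0.0
        return float(np.std(self.fu_replicates, ddof=1))


@dataclass
class KdFit:
    """Fitted albumin-ligand dissociation constant for one substrate."""

    substrate: str
    kd: float                  # uM
    kd_se: float | None        # asymptotic SE, uM
    weighting: str
    converged: bool
    unbound_flag: bool         # binding too weak to constrain kd
    n_points: int = 0
    ssr: float = 0.0


def predict_fu(kd: float, albumin: float) -> float:
    """Fraction unbound at albumin concentration ``albumin`` (uM)."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if albumin < 0:
        raise ValueError(f"albumin concentration must be >= 0, got {albumin}")
    return kd / (kd + albumin)


_STARTS_UM = (1.0, 10.0, 100.0, 1000.0)


def fit_kd(
    measurements: list[BindingMeasurement],
    weighting: str = "relative",
    use_replicates: bool = True,
    unbound_kd_threshold: float = 10_000.0,
    unbound_fu_threshold: float = 0.95,
) -> KdFit:
    """Estimate K_d from fraction-unbound measurements.

    Parameters
    ----------
    measurements
        Measurements for a single substrate; conditions with zero albumin
        carry no information and are ignored.
    weighting
        ``"relative"`` (default) divides residuals by the model prediction
        (constant-CV error, keeps sub-percent f_u values from being swamped
        by weakly bound ones); ``"none"`` is unweighted.
    use_replicates
        Fit replicate-level points when available, otherwise condition means.
    unbound_kd_threshold, unbound_fu_threshold
        The fit is flagged ``unbound_flag`` when the fitted K_d exceeds the
        former or every mean f_u exceeds the latter.

    The optimiser works on log K_d with multi-start to be insensitive to the
    orders-of-magnitude range of plausible K_d.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    nonzero = [m for m in measurements if m.condition.molar_conc > 0]
    if not nonzero:
        raise ValueError(
            "all measurements at zero albumin: K_d is unidentifiable")
    substrate = nonzero[0].substrate

    albumin, fu = [], []
    for m in nonzero:
        if use_replicates and len(m.fu_replicates) > 1:
            for r in m.fu_replicates:
                albumin.append(m.condition.molar_conc)
                fu.append(r)
        else:
            albumin.append(m.condition.molar_conc)
            fu.append(m.fu_mean)
    albumin = np.asarray(albumin, dtype=float)
    fu = np.asarray(fu, dtype=float)

    def residuals(log_kd: np.ndarray) -> np.ndarray:
        pred = np.exp(log_kd[0]) / (np.exp(log_kd[0]) + albumin)
        r = fu - pred
        if weighting == "relative":
            r = r / pred
        return r

    best = None
    for start in _STARTS_UM:
        sol = least_squares(residuals, x0=[np.log(start)], xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = float(np.exp(best.x[0]))

    # delta method: var(kd) = kd^2 * var(log kd)
    kd_se = None
    dof = len(fu) - 1
    if dof > 0 and best.jac.size:
        jtj = float(np.squeeze(best.jac.T @ best.jac))
        if jtj > 0:
            sigma2 = 2 * best.cost / dof
            kd_se = kd * float(np.sqrt(sigma2 / jtj))

    all_high = all(m.fu_mean > unbound_fu_threshold for m in nonzero)
    unbound = kd > unbound_kd_threshold or all_high
    return KdFit(
        substrate=substrate, kd=kd, kd_se=kd_se, weighting=weighting,
        converged=bool(best.success), unbound_flag=bool(unbound),
        n_points=len(fu), ssr=float(2 * best.cost),
    )
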