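"""Uptake time courses to unbound intrinsic clearances.

The assay measures intracellular amount (pmol/mg lysate protein) at several
time points within the linear uptake window.  The slope of amount vs time,
divided by the unbound substrate concentration in the incubation (uM ==
pmol/uL), is the unbound intrinsic clearance CL_int,u in uL/min/mg.  The
probenecid condition (pan-OAT inhibition) isolates passive diffusion; the
transporter-mediated component is the difference

    CL_int,u,active = CL_int,u - CL_int,u,passive  (per replicate)

and the albumin-mediated effect size is the fold change

    R = CL_int,u,active(+HSA) / CL_int,u,active(-HSA)

computed per replicate pair and then averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "UptakeTimecourse", "SlopeFit", "ClearanceSet", "RatioResult",
    "fit_uptake_slope", "clint_u", "decompose_active", "albumin_ratio",
]


@dataclass
class UptakeTimecourse:
    """One replicate time course of intracellular uptake."""

    substrate: str
    transporter_line: str          # which cell line (OAT1 / OAT3)
    condition: str                 # control / hsa_1pct / hsa_4pct / probenecid
    replicate_id: int
    points: list                   # (time min, amount pmol/mg protein)
    unbound_conc: float            # unbound substrate concentration, uM

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a time course needs at least 3 points")
        times = [t for t, _ in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.unbound_conc <= 0:
            raise ValueError("unbound concentration must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([a for _, a in self.points], dtype=float)


@dataclass
class SlopeFit:
    slope: float            # pmol/min/mg
    slope_se: float
    intercept: float
    r_squared: float
    lack_of_fit: bool       # linear-phase assumption questionable


def fit_uptake_slope(
    timecourse: UptakeTimecourse,
    include_intercept: bool = True,
    r2_warn_threshold: float = 0.8,
) -> SlopeFit:
    """OLS slope of intracellular amount vs time.

    An intercept is included by default: nonzero intercepts arise from rapid
    surface binding at t=0.  Set ``include_intercept=False`` to force the
    regression through the origin.  A flat-line fit (zero amount variance)
    returns r_squared 1 by convention.  Poor linearity (r^2 below
    ``r2_warn_threshold``) sets ``lack_of_fit`` and emits a warning.
    """
    t = timecourse.times
    y = timecourse.amounts
    n = len(t)
    if np.var(t) == 0:
        raise ValueError("zero variance in time points")

    if include_intercept:
        X = np.column_stack([np.ones(n), t])
    else:
        X = t[:, None]
    beta, ssr_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    resid = y - pred
    ssr = float(resid @ resid)
    slope = float(beta[-1])
    intercept = float(beta[0]) if include_intercept else 0.0

    dof = n - X.shape[1]
    slope_se = 0.0
    if dof > 0:
        sigma2 = ssr / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        slope_se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))

    sst = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if sst == 0 else 1.0 - ssr / sst
    lack_of_fit = bool(sst > 0 and r_squared < r2_warn_threshold)
    if lack_of_fit:
        warnings.warn(
            f"{timecourse.substrate}/{timecourse.condition} replicate "
            f"{timecourse.replicate_id}: uptake vs time r^2 = {r_squared:.2f}; "
            "linear-phase assumption may not hold", stacklevel=2)
    return SlopeFit(slope, slope_se, intercept, r_squared, lack_of_fit)


def clint_u(slope: float, unbound_conc: float) -> float:
    """Unbound intrinsic clearance (uL/min/mg) from an uptake slope.

    pmol/min/mg divided by uM (= pmol/uL) gives uL/min/mg.
    """
    if unbound_conc <= 0:
        raise ValueError("unbound concentration must be positive")
    return slope / unbound_conc


@dataclass
class ClearanceSet:
    """Total, passive and active clearances for one substrate x cell line."""

    substrate: str
    transporter_line: str
    clint_u: dict = field(default_factory=dict)         # condition -> replicate array
    clint_u_passive: np.ndarray | None = None           # probenecid replicates
    clint_u_active: dict = field(default_factory=dict)  # condition -> replicate array
    non_substrate_flag: bool = False

    def mean_sd(self, condition: str, active: bool = True) -> tuple:
        vals = (self.clint_u_active if active else self.clint_u)[condition]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.mean(vals)), sd


def decompose_active(
    clint_total: dict,
    clint_passive,
    substrate: str = "",
    transporter_line: str = "",
    alpha: float = 0.05,
) -> ClearanceSet:
    """Split total clearances into passive and transporter-mediated parts.

    ``clint_total`` maps condition -> per-replicate total CL_int,u;
    ``clint_passive`` is the probenecid-condition replicate array.  When
    replicate counts match, passive is subtracted replicate-by-replicate;
    otherwise its mean is subtracted.  Negative active values are retained
    (excluding, not clamping, is the downstream policy).

    ``non_substrate_flag`` is set when the control-condition active clearance
    is not significantly greater than zero (one-sided t-test at ``alpha``) —
    the behaviour of a compound the transporter does not carry.
    """
    passive = np.asarray(clint_passive, dtype=float)
    cs = ClearanceSet(substrate=substrate, transporter_line=transporter_line,
                      clint_u_passive=passive)
    for cond, reps in clint_total.items():
        reps = np.asarray(reps, dtype=float)
        cs.clint_u[cond] = reps
        if len(reps) == len(passive):
            cs.clint_u_active[cond] = reps - passive
        else:
            cs.clint_u_active[cond] = reps - passive.mean()

    control = cs.clint_u_active.get("control")
    if control is not None:
        if len(control) > 1 and np.std(control) > 0:
            t_res = stats.ttest_1samp(control, 0.0, alternative="greater")
            cs.non_substrate_flag = bool(t_res.pvalue > alpha)
        else:
            # degenerate replicate scatter: decide on the sign alone
            cs.non_substrate_flag = bool(control.mean() <= 0)
    return cs


@dataclass
class RatioResult:
    """Albumin-effect ratio R for one substrate x line x HSA level."""

    substrate: str
    transporter_line: str
    hsa_level: str
    r_replicates: np.ndarray
    r_mean: float
    r_sd: float


def albumin_ratio(
    active_plus,
    active_minus,
    substrate: str = "",
    transporter_line: str = "",
    hsa_level: str = "",
    paired: bool = True,
) -> RatioResult:
    """Fold change R in active clearance with vs without albumin.

    Paired mode (default) divides replicate-by-replicate and averages the
    ratios — the mean of ratios, not the ratio of means, which matters when
    replicate scatter is large.  Unpaired mode returns the ratio of means
    with an SD from first-order error propagation.
    """
    plus = np.asarray(active_plus, dtype=float)
    minus = np.asarray(active_minus, dtype=float)
    if np.any(minus <= 0):
        raise ValueError("non-positive albumin-free active clearance: "
                         "ratio is degenerate")
    if paired:
        if len(plus) != len(minus):
            raise ValueError("paired mode needs equal replicate counts")
        ratios = plus / minus
        r_mean = float(ratios.mean())
        r_sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    else:
        r_mean = float(plus.mean() / minus.mean())
        cv_p = plus.std(ddof=1) / plus.mean() if len(plus) > 1 else 0.0
        cv_m = minus.std(ddof=1) / minus.mean() if len(minus) > 1 else 0.0
        r_sd = float(abs(r_mean) * np.sqrt(cv_p ** 2 + cv_m ** 2))
        ratios = np.array([r_mean])
    return RatioResult(substrate, transporter_line, hsa_level,
                       ratios, r_mean, r_sd)
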