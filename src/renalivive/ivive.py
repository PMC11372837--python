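"""Bottom-up extrapolation of in vitro active clearances to in vivo renal
secretion and renal clearance.

Two unitless scalers bridge the in vitro cell line and the kidney cortex:

* REF (relative expression factor) — ratio of transporter abundance in
  kidney cortex to that in the cell line (both pmol/mg protein);
* RAF (relative activity factor) — ratio of the in vivo back-calculated
  active clearance of a transporter-specific probe to its in vitro value.

The scaled intrinsic secretion clearance is

    CL_int,sec (mL/min) = CL_int,u,active [uL/min/mg]
                          * protein [mg/1e6 cells]      (per-cell units)
                          * scaler (REF or RAF)
                          * PTCPGK [1e6 cells/g] * KW_cortex [g] / 1000

summed over OAT1 and OAT3 for dual substrates.  The well-stirred kidney
model and the filtration term then give plasma clearances:

    CL_sec = Q_r * f_u,b * CL_int,sec / (Q_r + f_u,b * CL_int,sec)
    CL_r   = (f_u,p * GFR + CL_sec) * (1 - F_reabs)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain import PhysiologyConstants

__all__ = [
    "ScalerSet", "ClearancePrediction",
    "compute_ref", "compute_raf", "scale_to_invivo_clint",
    "well_stirred_cl_sec", "renal_clearance", "fraction_transported",
    "predict_renal_clearance",
]


def compute_ref(abundance_invivo: float, abundance_invitro: float) -> float:
    """Relative expression factor: cortex / cell-line abundance."""
    if abundance_invivo <= 0 or abundance_invitro <= 0:
        raise ValueError("abundances must be positive")
    return abundance_invivo / abundance_invitro


def compute_raf(clint_invivo_ref: float, clint_invitro_ref: float) -> float:
    """Relative activity factor: in vivo / in vitro probe active clearance."""
    if clint_invivo_ref <= 0 or clint_invitro_ref <= 0:
        raise ValueError("probe clearances must be positive")
    return clint_invivo_ref / clint_invitro_ref


@dataclass
class ScalerSet:
    """REF/RAF inputs and derived scalers for one transporter."""

    transporter: str
    abundance_invivo: float      # pmol/mg protein, kidney cortex
    abundance_invitro: float     # pmol/mg protein, cell line
    clint_invivo_ref: float      # uL/min/mg, probe, back-calculated in vivo
    clint_invitro_ref: float     # uL/min/mg, probe, measured in vitro
    reference_probe: str = ""

    @property
    def ref(self) -> float:
        return compute_ref(self.abundance_invivo, self.abundance_invitro)

    @property
    def raf(self) -> float:
        return compute_raf(self.clint_invivo_ref, self.clint_invitro_ref)

    def scaler(self, mode: str) -> float:
        if mode == "REF":
            return self.ref
        if mode == "RAF":
            return self.raf
        raise ValueError(f"unknown scaling mode {mode!r}")


def scale_to_invivo_clint(
    clint_active: float,
    scaler: float,
    protein_per_million_cells: float,
    phys: PhysiologyConstants,
) -> float:
    """One transporter's contribution to in vivo CL_int,sec (mL/min)."""
    if clint_active < 0:
        raise ValueError("active clearance must be >= 0")
    if protein_per_million_cells <= 0:
        raise ValueError("lysate protein content must be positive "
                         "(missing cell-line configuration?)")
    per_cell = clint_active * protein_per_million_cells  # uL/min/1e6 cells
    return per_cell * scaler * phys.ptcpgk * phys.kw_cortex / 1000.0


def well_stirred_cl_sec(clint_sec: float, fu_b: float, q_r: float) -> float:
    """Plasma secretion clearance from the well-stirred kidney model."""
    if not (0 < fu_b <= 1):
        raise ValueError("fu_b must be in (0, 1]")
    if q_r <= 0:
        raise ValueError("renal blood flow must be positive")
    if clint_sec < 0:
        raise ValueError("intrinsic secretion clearance must be >= 0")
    return q_r * fu_b * clint_sec / (q_r + fu_b * clint_sec)


def renal_clearance(cl_sec: float, fu_p: float,
                    phys: PhysiologyConstants) -> float:
    """Total plasma renal clearance: filtration + secretion, reabsorption
    applied to both."""
    if not (0 < fu_p <= 1):
        raise ValueError("fu_p must be in (0, 1]")
    return (fu_p * phys.gfr + cl_sec) * (1.0 - phys.f_reabs)


def fraction_transported(per_transporter_cl_sec: dict, cl_r: float) -> dict:
    """Share of total renal clearance carried by each transporter."""
    if cl_r <= 0:
        raise ValueError("cl_r must be positive")
    return {t: v / cl_r for t, v in per_transporter_cl_sec.items()}


@dataclass
class ClearancePrediction:
    """Bottom-up prediction for one substrate at one HSA level."""

    substrate: str
    scaling_mode: str            # REF or RAF
    hsa_level: str
    clint_sec: float             # mL/min
    cl_sec: float                # mL/min
    cl_r: float                  # mL/min
    per_transporter_cl_sec: dict = field(default_factory=dict)
    fraction_by_transporter: dict = field(default_factory=dict)
    fold_error: float | None = None   # predicted / observed CL_r

    @property
    def clint_sec_l_per_h(self) -> float:
        return self.clint_sec * 60.0 / 1000.0

    @property
    def cl_r_l_per_h(self) -> float:
        return self.cl_r * 60.0 / 1000.0


def predict_renal_clearance(
    substrate: str,
    clint_active_by_transporter: dict,
    scalers: dict,
    fu_p: float,
    phys: PhysiologyConstants,
    mode: str = "REF",
    hsa_level: str = "control",
    fu_b: float | None = None,
    blood_plasma_ratio: float = 1.0,
    observed_clr: float | None = None,
) -> ClearancePrediction:
    """Full chain for one substrate: scale, sum over transporters, apply the
    well-stirred model and the filtration term.

    ``clint_active_by_transporter`` maps transporter -> in vitro active
    clearance (uL/min/mg) at the chosen HSA level; ``scalers`` maps
    transporter -> :class:`ScalerSet`.  ``fu_b`` defaults to
    ``fu_p / blood_plasma_ratio`` when no measured blood value exists.
    """
    if fu_b is None:
        fu_b = fu_p / blood_plasma_ratio
    fu_b = min(fu_b, 1.0)

    per_clint = {}
    for transporter, clint in clint_active_by_transporter.items():
        sc = scalers[transporter]
        protein = phys.protein_per_million_cells.get(transporter)
        if protein is None:
            raise ValueError(f"no lysate protein content configured for "
                             f"{transporter}")
        per_clint[transporter] = scale_to_invivo_clint(
            max(clint, 0.0), sc.scaler(mode), protein, phys)

    clint_sec = sum(per_clint.values())
    cl_sec = well_stirred_cl_sec(clint_sec, fu_b, phys.q_r)
    cl_r = renal_clearance(cl_sec, fu_p, phys)

    # attribute secretion to transporters in proportion to scaled clint
    per_cl_sec = {
        t: (cl_sec * v / clint_sec if clint_sec > 0 else 0.0)
        for t, v in per_clint.items()
    }
    fractions = fraction_transported(per_cl_sec, cl_r) if cl_r > 0 else {}
    fe = (cl_r / observed_clr) if observed_clr else None
    return ClearancePrediction(
        substrate=substrate, scaling_mode=mode, hsa_level=hsa_level,
        clint_sec=clint_sec, cl_sec=cl_sec, cl_r=cl_r,
        per_transporter_cl_sec=per_cl_sec,
        fraction_by_transporter=fractions, fold_error=fe,
    )
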