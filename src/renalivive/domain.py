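"""Core typed records and unit conventions shared by all analysis stages.

Unit conventions used throughout the package:

* in vitro intrinsic clearances: uL/min/mg lysate protein
* per-cell clearances: uL/min/1e6 cells
* in vivo clearances: mL/min (L/h only at the report layer)
* albumin concentrations: mass scale g/dL ("x% HSA" = x g/dL), molar scale uM
* amounts in uptake time courses: pmol/mg lysate protein; time in minutes
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default molar mass of human serum albumin (g/mol). The molarity of an
#: "x% HSA" incubation depends on this value; it is a visible knob rather
#: than a hard-coded constant.
HSA_MOLAR_MASS = 66_500.0

OAT1 = "OAT1"
OAT3 = "OAT3"
TRANSPORTERS = (OAT1, OAT3)


def albumin_molar(mass_conc: float, molar_mass: float = HSA_MOLAR_MASS) -> float:
    """Convert an albumin mass concentration (g/dL) to a molar one (uM).

    g/dL * 10 = g/L; divided by g/mol gives mol/L; * 1e6 gives uM.
    """
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    if mass_conc < 0:
        raise ValueError(f"mass concentration must be >= 0, got {mass_conc}")
    return mass_conc * 10.0 / molar_mass * 1e6


def albumin_mass(molar_conc: float, molar_mass: float = HSA_MOLAR_MASS) -> float:
    """Inverse of :func:`albumin_molar`: uM back to g/dL."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return molar_conc / 1e6 * molar_mass / 10.0


@dataclass(frozen=True)
class AlbuminCondition:
    """One incubation condition: an albumin level expressed on both scales."""

    label: str
    mass_conc: float  # g/dL
    molar_mass: float = HSA_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.mass_conc < 0:
            raise ValueError("mass_conc must be >= 0")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")

    @property
    def molar_conc(self) -> float:
        """Albumin molar concentration (uM)."""
        return albumin_molar(self.mass_conc, self.molar_mass)

    @classmethod
    def control(cls) -> "AlbuminCondition":
        return cls("control", 0.0)

    @classmethod
    def hsa(cls, percent: float, molar_mass: float = HSA_MOLAR_MASS) -> "AlbuminCondition":
        """An "x% HSA" condition, interpreting x% as x g/dL."""
        label = f"hsa_{percent:g}pct"
        return cls(label, float(percent), molar_mass)


#: Canonical experimental conditions of the uptake assay.
CONDITION_CONTROL = "control"
CONDITION_HSA_1PCT = "hsa_1pct"
CONDITION_HSA_4PCT = "hsa_4pct"
CONDITION_PROBENECID = "probenecid"
CONDITIONS = (CONDITION_CONTROL, CONDITION_HSA_1PCT, CONDITION_HSA_4PCT,
              CONDITION_PROBENECID)

#: Albumin levels of the canonical conditions. Probenecid incubations are
#: albumin-free, so unbound fraction is taken as 1 there, as in the control.
CONDITION_ALBUMIN = {
    CONDITION_CONTROL: AlbuminCondition.control(),
    CONDITION_HSA_1PCT: AlbuminCondition.hsa(1),
    CONDITION_HSA_4PCT: AlbuminCondition.hsa(4),
    CONDITION_PROBENECID: AlbuminCondition("probenecid", 0.0),
}


@dataclass
class SubstrateRecord:
    """Identity and clinical reference data for one OAT1/3 substrate."""

    name: str
    transporters: frozenset = field(default_factory=frozenset)
    fu_p: float | None = None        # fraction unbound in plasma
    fu_b: float | None = None        # fraction unbound in blood
    observed_clr: float | None = None  # observed plasma renal clearance, mL/min
    reference_probe_for: str | None = None  # transporter this is a probe for

    def __post_init__(self) -> None:
        self.transporters = frozenset(self.transporters)
        bad = self.transporters - set(TRANSPORTERS)
        if bad:
            raise ValueError(f"unknown transporters {sorted(bad)}")
        if self.fu_p is not None and not (0 < self.fu_p <= 1):
            raise ValueError(f"fu_p must be in (0, 1], got {self.fu_p}")
        if self.fu_b is not None and self.fu_b <= 0:
            raise ValueError(f"fu_b must be positive, got {self.fu_b}")


@dataclass
class PhysiologyConstants:
    """Anatomical and physiological scalars of the kidney model.

    gfr
        glomerular filtration rate of a healthy adult (mL/min).
    q_r
        renal blood flow (mL/min).
    ptcpgk
        proximal tubular cells per gram of kidney cortex (1e6 cells/g).
    kw_cortex
        combined mass of both kidney cortexes (g).
    f_reabs
        fraction of drug reabsorbed from the tubule; zero for significantly
        secreted substrates.
    protein_per_million_cells
        lysate protein content of each cell line (mg/1e6 cells); converts
        per-mg-protein clearances to per-cell ones.
    """

    gfr: float = 120.0
    q_r: float = 1008.0
    ptcpgk: float = 99.4
    kw_cortex: float = 169.0
    f_reabs: float = 0.0
    protein_per_million_cells: dict = field(
        default_factory=lambda: {OAT1: 0.30, OAT3: 0.32})

    def __post_init__(self) -> None:
        for name in ("gfr", "q_r", "ptcpgk", "kw_cortex"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.f_reabs < 1):
            raise ValueError("f_reabs must lie in [0, 1)")
        for line, mg in self.protein_per_million_cells.items():
            if mg <= 0:
                raise ValueError(f"protein content for {line} must be positive")
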