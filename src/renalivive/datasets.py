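"""Packaged reference tables of the ciPTEC-OAT1/3 albumin study.

Three tables ship with the package:

* ``hsa_binding`` — measured fraction unbound in incubation at 1% and 4%
  HSA with the fitted albumin-ligand K_d (uM) per substrate;
* ``active_clearance`` — active unbound intrinsic clearances (uL/min/mg)
  in the control/1%/4% HSA conditions and the albumin-effect ratios R;
* ``scalers`` — transporter abundances (kidney cortex and cell line) and
  probe clearances from which REF and RAF derive;

plus the substrate panel (transporter specificity, plasma fraction
unbound, probe flags) as YAML.  Values are condition means with SDs;
replicate-level raw data were not published.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .domain import SubstrateRecord, albumin_molar
from .fdmodel import FDSeries, RatioSeries

__all__ = [
    "load_binding_table", "load_clearance_table", "load_scaler_table",
    "load_substrate_panel", "binding_measurement_frame",
    "fd_series_from_tables", "ratio_series_from_tables",
    "BOUND_SUBSTRATES", "WEAKLY_BOUND_SUBSTRATES", "HSA_LEVELS_PCT",
]

#: The six substrates with appreciable albumin binding, and the two
#: weakly bound negative controls / reference probes.
BOUND_SUBSTRATES = (
    "olmesartan", "bumetanide", "furosemide", "rivaroxaban",
    "4-pyridoxic acid", "rosuvastatin",
)
WEAKLY_BOUND_SUBSTRATES = ("adefovir", "oseltamivir carboxylate")

#: HSA mass levels (g/dL) of the two albumin-containing conditions.
HSA_LEVELS_PCT = (1.0, 4.0)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("renalivive.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_binding_table() -> pd.DataFrame:
    return _read_csv("hsa_binding.csv")


def load_clearance_table() -> pd.DataFrame:
    return _read_csv("active_clearance.csv")


def load_scaler_table() -> pd.DataFrame:
    return _read_csv("scalers.csv")


def load_substrate_panel() -> dict:
    """Substrate panel as ``name -> SubstrateRecord``."""
    with resources.files("renalivive.data").joinpath("substrates.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    panel = {}
    for name, spec in raw["substrates"].items():
        panel[name] = SubstrateRecord(
            name=name,
            transporters=frozenset(spec.get("transporters", [])),
            fu_p=spec.get("fu_p"),
            fu_b=spec.get("fu_b"),
            observed_clr=spec.get("observed_clr"),
            reference_probe_for=spec.get("reference_probe_for"),
        )
    return panel


def binding_measurement_frame() -> pd.DataFrame:
    """Binding table in long form: one row per substrate x HSA level."""
    tbl = load_binding_table()
    rows = []
    for _, row in tbl.iterrows():
        for pct in HSA_LEVELS_PCT:
            key = f"fu_{pct:g}pct"
            rows.append({
                "substrate": row["substrate"],
                "albumin_g_per_dl": pct,
                "albumin_um": albumin_molar(pct),
                "fu_mean": row[f"{key}_mean"],
                "fu_sd": row[f"{key}_sd"],
            })
    return pd.DataFrame(rows)


def _kd_map(kd_source: str) -> dict:
    tbl = load_binding_table()
    if kd_source == "printed":
        return dict(zip(tbl["substrate"], tbl["kd_um"]))
    raise ValueError(f"unknown kd source {kd_source!r}")


def fd_series_from_tables(
    transporter: str,
    substrates=BOUND_SUBSTRATES,
    kd: dict | None = None,
) -> list[FDSeries]:
    """Full-model input: active clearances at 0/1/4% HSA with K_d.

    ``kd`` maps substrate -> K_d (uM); defaults to the packaged fitted
    values.  Substrates absent from the requested transporter's panel are
    skipped.
    """
    kd = kd or _kd_map("printed")
    cl = load_clearance_table()
    cl = cl[cl["transporter"] == transporter]
    albumin = np.array([0.0] + [albumin_molar(p) for p in HSA_LEVELS_PCT])
    series = []
    for sub in substrates:
        row = cl[cl["substrate"] == sub]
        if row.empty:
            continue
        row = row.iloc[0]
        series.append(FDSeries(
            substrate=sub, kd=float(kd[sub]), albumin=albumin,
            clint_active=np.array([row["clint_control_mean"],
                                   row["clint_1pct_mean"],
                                   row["clint_4pct_mean"]]),
        ))
    return series


def ratio_series_from_tables(
    transporter: str,
    substrates=BOUND_SUBSTRATES,
    kd: dict | None = None,
) -> list[RatioSeries]:
    """Reduced-model input: R at 1% and 4% HSA with K_d."""
    kd = kd or _kd_map("printed")
    cl = load_clearance_table()
    cl = cl[cl["transporter"] == transporter]
    albumin = np.array([albumin_molar(p) for p in HSA_LEVELS_PCT])
    series = []
    for sub in substrates:
        row = cl[cl["substrate"] == sub]
        if row.empty:
            continue
        row = row.iloc[0]
        series.append(RatioSeries(
            substrate=sub, kd=float(kd[sub]), albumin=albumin,
            r=np.array([row["r_1pct_mean"], row["r_4pct_mean"]]),
        ))
    return series
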