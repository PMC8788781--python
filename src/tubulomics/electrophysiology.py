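"""Electrophysiological phenotyping of microperfused tubules.

A single cortical collecting duct, perfused in a double-barreled system, is
treated as a leaky finite cable sealed at the collection end. A constant
current pulse ``I0`` injected at the perfusion end produces voltage
deflections at both ends (``dV0``, ``dVL``); their ratio and magnitude fix
the cable length constant, the luminal diameter, and the specific
transepithelial resistance R_te. The equivalent short-circuit current
follows from Ohm's law, the amiloride-sensitive voltage from the difference
of basal and amiloride-inhibited transepithelial voltage, and the
paracellular Na+/Cl- permeability ratio from the NaCl dilution potential via
the bi-ionic Goldman-Hodgkin-Katz (GHK) voltage equation.

Sign convention throughout: transepithelial voltage is lumen minus bath, so
an ENaC-dominated tubule is lumen-negative at rest and basolateral NaCl
dilution generates a positive diffusion potential when the shunt is
Cl-selective.

Units at the API surface are the ones used at the rig: um, nA, mV,
Ohm-cm and Ohm-cm2; all conversions to SI are internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np
import pandas as pd

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

#: luminal fluid resistivity of physiological saline at 37 C, Ohm-cm
DEFAULT_RHO = 60.0
#: bath temperature, K
DEFAULT_TEMPERATURE = 310.15
#: injected current pulse amplitude, nA
DEFAULT_CURRENT_NA = 13.0
#: NaCl concentration of the control and dilute bath solutions, mM
DEFAULT_CONC_CONTROL = 145.0
DEFAULT_CONC_LOW = 30.0


class CableInversionError(ValueError):
    """The recorded deflections are incompatible with the finite-cable model."""


class PermeabilityRangeError(ValueError):
    """The dilution potential lies outside the range any P_Na/P_Cl can produce."""


@dataclass(frozen=True)
class ElectroRecording:
    """Raw per-tubule perfusion measurements.

    Voltages are lumen minus bath (mV); ``Vdp`` is the junction-corrected
    diffusion potential under basolateral low-NaCl with transcellular
    transport blocked.
    """

    tubule_id: str
    L: float                # tubule length, um
    I0: float               # injected current, nA
    dV0: float              # deflection at perfusion end, mV
    dVL: float              # deflection at collection end, mV
    Vte_basal: float        # basal transepithelial voltage, mV
    Vte_amil: float         # V_te under luminal amiloride + HCTZ, mV
    Vdp: float              # NaCl dilution potential, mV
    rho: float = DEFAULT_RHO
    T: float = DEFAULT_TEMPERATURE
    conc_control: float = DEFAULT_CONC_CONTROL
    conc_low: float = DEFAULT_CONC_LOW

    def __post_init__(self) -> None:
        for name in ("L", "I0", "rho", "T"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not (self.conc_control > self.conc_low > 0):
            raise ValueError(
                "require conc_control > conc_low > 0, got "
                f"{self.conc_control!r} / {self.conc_low!r}"
            )
        if self.dV0 * self.dVL <= 0:
            raise ValueError("dV0 and dVL must be finite, nonzero and share sign")


@dataclass(frozen=True)
class TubulePhenotype:
    """Derived electrophysiological phenotype of one tubule."""

    tubule_id: str
    lam: float          # cable length constant, um
    diameter: float     # luminal diameter, um
    Rte: float          # specific transepithelial resistance, Ohm cm2
    Isc: float          # equivalent short-circuit current, uA/cm2
    dVte_amil: float    # amiloride-sensitive voltage, mV (signed)
    pna_pcl: float      # paracellular P_Na/P_Cl
    length: float       # tubule length, um


class CableFit(NamedTuple):
    lam: float                  # um
    core_resistance: float      # Ohm/cm
    diameter: float             # um
    Rte: float                  # Ohm cm2


def invert_cable(
    L: float,
    I0: float,
    dV0: float,
    dVL: float,
    rho: float = DEFAULT_RHO,
) -> CableFit:
    """Invert the sealed-end finite-cable model from two voltage deflections.

    With current injected at x=0 and the far end sealed, the deflection
    profile is ``V(x) = I0 r_c lam cosh((L-x)/lam)/sinh(L/lam)``, so the
    end-to-end ratio fixes the length constant,

        lam = L / acosh(dV0/dVL),

    the input resistance ``|dV0|/I0`` fixes the core resistance per unit
    length ``r_c``, the luminal resistivity converts that to a diameter,
    and ``R_te = lam^2 r_c pi d``.

    Parameters in um / nA / mV / Ohm-cm; returns um, Ohm/cm, um, Ohm-cm2.
    """
    for name, v in (("L", L), ("I0", I0), ("rho", rho)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    if not (np.isfinite(dV0) and np.isfinite(dVL)) or dV0 * dVL <= 0:
        raise ValueError("dV0 and dVL must be finite, nonzero and share sign")
    ratio = dV0 / dVL
    if ratio <= 1.0:
        raise CableInversionError(
            f"cable not invertible: |dV0| must exceed |dVL| (ratio {ratio:.4g})"
        )
    L_cm = L * 1e-4
    lam_cm = L_cm / math.acosh(ratio)
    x = L_cm / lam_cm
    r_in = abs(dV0) * 1e-3 / (I0 * 1e-9)          # Ohm
    r_c = r_in * math.tanh(x) / lam_cm            # Ohm/cm
    d_cm = math.sqrt(4.0 * rho / (math.pi * r_c))
    rte = lam_cm**2 * r_c * math.pi * d_cm        # Ohm cm2
    return CableFit(lam_cm * 1e4, r_c, d_cm * 1e4, rte)


def forward_cable(
    L: float,
    diameter: float,
    Rte: float,
    rho: float = DEFAULT_RHO,
    I0: float = DEFAULT_CURRENT_NA,
) -> tuple[float, float]:
    """Forward sealed-end cable model: deflection magnitudes (dV0, dVL) in mV.

    Exact algebraic inverse of :func:`invert_cable`; used by the cohort
    simulator and as the round-trip oracle.
    """
    for name, v in (
        ("L", L), ("diameter", diameter), ("Rte", Rte), ("rho", rho), ("I0", I0)
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    L_cm = L * 1e-4
    d_cm = diameter * 1e-4
    r_c = 4.0 * rho / (math.pi * d_cm**2)            # Ohm/cm
    lam_cm = math.sqrt(Rte / (math.pi * d_cm * r_c))  # cm
    x = L_cm / lam_cm
    dv0 = I0 * 1e-9 * r_c * lam_cm / math.tanh(x)    # V
    dvl = dv0 / math.cosh(x)
    return dv0 * 1e3, dvl * 1e3


def short_circuit_current(Vte: float, Rte: float) -> float:
    """Equivalent short-circuit current I'sc = V_te / R_te in uA/cm2.

    Sign is preserved: a lumen-negative V_te gives a negative I'sc.
    """
    if not np.isfinite(Rte) or Rte <= 0:
        raise ValueError(f"Rte must be positive, got {Rte!r}")
    # mV / (Ohm cm2) = 1e-3 A/cm2 / Ohm... -> uA/cm2 carries a factor 1000
    return 1000.0 * Vte / Rte


def amiloride_delta(Vte_basal: float, Vte_amil: float) -> float:
    """Amiloride-sensitive voltage: basal minus amiloride-inhibited V_te (mV)."""
    if not (np.isfinite(Vte_basal) and np.isfinite(Vte_amil)):
        raise ValueError("voltages must be finite")
    return Vte_basal - Vte_amil


def _thermal_voltage_mV(T: float) -> float:
    if not np.isfinite(T) or T <= 0:
        raise ValueError(f"temperature must be positive, got {T!r}")
    return GAS_CONSTANT * T / FARADAY * 1e3


def ghk_dp(
    pna_pcl: float,
    conc_control: float = DEFAULT_CONC_CONTROL,
    conc_low: float = DEFAULT_CONC_LOW,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Bi-ionic GHK dilution potential (mV) for a given P_Na/P_Cl.

    Lumen holds the control NaCl solution, the bath the dilute one;
    with beta = P_Na/P_Cl,

        Vdp = (RT/F) ln[(beta*Na_bath + Cl_lumen) / (beta*Na_lumen + Cl_bath)].

    A pure Cl- shunt (beta = 0) gives the positive limit (RT/F) ln(c_c/c_l);
    beta = 1 gives exactly 0; the function is strictly decreasing in beta.
    """
    if not np.isfinite(pna_pcl) or pna_pcl < 0:
        raise ValueError(f"pna_pcl must be >= 0, got {pna_pcl!r}")
    if not (conc_control > conc_low > 0):
        raise ValueError("require conc_control > conc_low > 0")
    vt = _thermal_voltage_mV(T)
    return vt * math.log(
        (pna_pcl * conc_low + conc_control) / (pna_pcl * conc_control + conc_low)
    )


def pnapcl_from_dp(
    Vdp: float,
    conc_control: float = DEFAULT_CONC_CONTROL,
    conc_low: float = DEFAULT_CONC_LOW,
    T: float = DEFAULT_TEMPERATURE,
    boundary_tol: float = 1e-9,
) -> float:
    """Invert the GHK dilution potential to the permeability ratio P_Na/P_Cl.

    Closed form: with ``a = exp(Vdp F / RT)``,

        beta = (Cl_lumen - a*Cl_bath) / (a*Na_lumen - Na_bath).

    ``Vdp`` exactly at the pure-ion bounds +/- (RT/F) ln(c_c/c_l) returns the
    boundary solutions 0.0 and ``inf``; outside them no ratio can produce the
    measured potential and :class:`PermeabilityRangeError` is raised.
    """
    if not np.isfinite(Vdp):
        raise ValueError("Vdp must be finite")
    if not (conc_control > conc_low > 0):
        raise ValueError("require conc_control > conc_low > 0")
    vt = _thermal_voltage_mV(T)
    vmax = vt * math.log(conc_control / conc_low)
    if Vdp > vmax + boundary_tol or Vdp < -vmax - boundary_tol:
        raise PermeabilityRangeError(
            f"permeability not representable: Vdp {Vdp:.4g} mV outside "
            f"attainable interval +/- {vmax:.4g} mV"
        )
    if Vdp >= vmax - boundary_tol:
        return 0.0
    if Vdp <= -vmax + boundary_tol:
        return math.inf
    a = math.exp(Vdp / vt)
    return (conc_control - a * conc_low) / (a * conc_control - conc_low)


def derive_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Derive a :class:`TubulePhenotype` table from an ElectroRecording table.

    ``records`` has one row per tubule with the ElectroRecording fields as
    columns; unspecified rig constants fall back to the module defaults.
    """
    defaults = {
        "rho": DEFAULT_RHO,
        "T": DEFAULT_TEMPERATURE,
        "conc_control": DEFAULT_CONC_CONTROL,
        "conc_low": DEFAULT_CONC_LOW,
    }
    required = [
        f.name for f in fields(ElectroRecording) if f.name not in defaults
    ]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"recording table is missing columns: {missing}")
    out = []
    for row in records.itertuples(index=False):
        rec = {c: getattr(row, c) for c in records.columns}
        for k, v in defaults.items():
            rec.setdefault(k, v)
        fit = invert_cable(rec["L"], rec["I0"], rec["dV0"], rec["dVL"], rec["rho"])
        out.append(
            {
                "tubule_id": rec["tubule_id"],
                "lam": fit.lam,
                "diameter": fit.diameter,
                "Rte": fit.Rte,
                "Isc": short_circuit_current(rec["Vte_basal"], fit.Rte),
                "dVte_amil": amiloride_delta(rec["Vte_basal"], rec["Vte_amil"]),
                "pna_pcl": pnapcl_from_dp(
                    rec["Vdp"], rec["conc_control"], rec["conc_low"], rec["T"]
                ),
                "length": rec["L"],
            }
        )
    return pd.DataFrame(out)
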