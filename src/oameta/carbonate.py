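"""Seawater carbonate-system solver: pH (any common scale) plus one of total
alkalinity or DIC, with temperature and salinity, to pCO2 in μatm.

The solver reproduces the classic CO2-system calculation used to harmonise
CO2 treatment levels across ocean-acidification experiments that report pH
rather than pCO2.  Equilibrium constants follow the standard literature
parameterisations:

* K0 (CO2 solubility): Weiss (1974).
* K1/K2 (carbonic acid): Mehrbach et al. (1973) as refit by Dickson &
  Millero (1987) on the seawater scale (default), or Lueker et al. (2000)
  on the total scale.
* KB (boric acid): Dickson (1990b); total boron from salinity per
  Uppström (1974).
* KW (water): Millero (1995), seawater scale.
* KS (bisulfate): Dickson (1990a), free scale.
* KF (hydrogen fluoride): Perez & Fraga (1987), total scale.

All internal thermodynamics run on the seawater pH scale; input pH on the
total, free or NBS scale is converted first.  Surface pressure only — no
pressure corrections are applied.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.optimize import brentq

__all__ = [
    "CarbonateState",
    "equilibrium_constants",
    "solve_pco2",
    "solve_ph_from_pco2",
    "CONSTANT_SETS",
    "PH_SCALES",
]

CONSTANT_SETS = ("mehrbach_dm87", "lueker2000")
PH_SCALES = ("total", "seawater", "nbs", "free")

GAS_CONSTANT_BAR = 83.14462618  # cm3 bar / (mol K), for the fugacity virial


class CarbonateState(BaseModel):
    """Inputs sufficient to solve the carbonate system for pCO2.

    Exactly one of ``alkalinity`` or ``dic`` must accompany ``ph``.
    ``pressure`` is carried for provenance; only surface values (< 10 dbar)
    are accepted because no pressure corrections are applied.
    """

    temperature: float
    salinity: float
    pressure: float = 0.0
    ph: float
    ph_scale: Literal["total", "seawater", "nbs", "free"] = "total"
    alkalinity: Optional[float] = None  # μmol/kg-SW
    dic: Optional[float] = None  # μmol/kg-SW
    constants_set: Literal["mehrbach_dm87", "lueker2000"] = "mehrbach_dm87"

    @model_validator(mode="after")
    def _check(self) -> "CarbonateState":
        if (self.alkalinity is None) == (self.dic is None):
            raise ValueError("exactly one of alkalinity or dic must be given")
        if not (0.0 <= self.salinity <= 45.0):
            raise ValueError(f"salinity {self.salinity} outside [0, 45] PSU")
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"temperature {self.temperature} outside [-2, 40] °C"
            )
        if self.pressure > 10.0:
            raise ValueError(
                "only surface pressures (< 10 dbar) are supported; "
                "no pressure corrections are applied"
            )
        return self


def _check_ts(temperature: float, salinity: float) -> None:
    if not (-2.0 <= temperature <= 40.0):
        raise ValueError(f"temperature {temperature} outside [-2, 40] °C")
    if not (0.0 <= salinity <= 45.0):
        raise ValueError(f"salinity {salinity} outside [0, 45] PSU")


def equilibrium_constants(
    temperature: float,
    salinity: float,
    pressure: float = 0.0,
    constants_set: str = "mehrbach_dm87",
) -> dict:
    """Evaluate the equilibrium constants at (T, S).

    Returns a dict with K0 (mol/kg-SW/atm), K1, K2, KB, KW (all on the
    seawater pH scale, mol/kg-SW), KS (free scale), KF (free scale), and the
    salinity-proportional totals boron_total, sulfate_total, fluoride_total
    (mol/kg-SW).
    """
    _check_ts(temperature, salinity)
    if constants_set not in CONSTANT_SETS:
        raise ValueError(f"unknown constants_set {constants_set!r}")

    t_k = temperature + 273.15
    s = salinity
    sqrt_s = math.sqrt(s)
    ln_t = math.log(t_k)

    # Weiss (1974) CO2 solubility, mol/kg-SW/atm.
    t100 = t_k / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 * t100)
    )
    k0 = math.exp(ln_k0)

    # Salinity-proportional totals (mol/kg-SW): Uppström (1974) boron,
    # Morris & Riley (1966) sulfate, Riley (1965) fluoride.
    bt = 0.000232 / 10.811 * s / 1.80655
    st = 0.14 / 96.062 * s / 1.80655
    ft = 0.000067 / 18.998 * s / 1.80655

    # Dickson (1990a) bisulfate, free scale.  Ionic strength from salinity.
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ks = (
        -4276.1 / t_k
        + 141.328
        - 23.093 * ln_t
        + (-13856.0 / t_k + 324.57 - 47.986 * ln_t) * math.sqrt(ion)
        + (35474.0 / t_k - 771.54 + 114.723 * ln_t) * ion
        - 2698.0 / t_k * ion**1.5
        + 1776.0 / t_k * ion * ion
        + math.log(1.0 - 0.001005 * s)
    )
    ks = math.exp(ln_ks)

    # Perez & Fraga (1987) HF, total scale -> converted to free below.
    kf_total = math.exp(874.0 / t_k - 9.68 + 0.111 * sqrt_s)

    free_to_total = 1.0 + st / ks
    kf = kf_total / free_to_total  # free scale
    free_to_sws = 1.0 + st / ks + ft / kf
    total_to_sws = free_to_sws / free_to_total

    # Dickson (1990b) boric acid, total scale -> seawater scale.
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s)
        / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_t
        + 0.053105 * sqrt_s * t_k
    )
    kb = math.exp(ln_kb) * total_to_sws

    # Millero (1995) water, seawater scale.
    ln_kw = (
        148.9802
        - 13847.26 / t_k
        - 23.6521 * ln_t
        + (-5.977 + 118.67 / t_k + 1.0495 * ln_t) * sqrt_s
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    if constants_set == "mehrbach_dm87":
        # Mehrbach refit by Dickson & Millero (1987), seawater scale.
        pk1 = 3670.7 / t_k - 62.008 + 9.7944 * ln_t - 0.0118 * s + 0.000116 * s * s
        pk2 = 1394.7 / t_k + 4.777 - 0.0184 * s + 0.000118 * s * s
        k1 = 10.0**-pk1
        k2 = 10.0**-pk2
    else:
        # Lueker et al. (2000), total scale -> seawater scale.
        pk1 = 3633.86 / t_k - 61.2172 + 9.6777 * ln_t - 0.011555 * s + 0.0001152 * s * s
        pk2 = 471.78 / t_k + 25.929 - 3.16967 * ln_t - 0.01781 * s + 0.0001122 * s * s
        k1 = 10.0**-pk1 * total_to_sws
        k2 = 10.0**-pk2 * total_to_sws

    return {
        "K0": k0,
        "K1": k1,
        "K2": k2,
        "KB": kb,
        "KW": kw,
        "KS": ks,
        "KF": kf,
        "boron_total": bt,
        "sulfate_total": st,
        "fluoride_total": ft,
    }


def _h_sws_from_ph(ph: float, scale: str, ks: dict, temperature: float, salinity: float) -> float:
    """[H+] on the seawater scale from a pH reading on any supported scale."""
    h = 10.0**-ph
    st, ft = ks["sulfate_total"], ks["fluoride_total"]
    free_to_total = 1.0 + st / ks["KS"]
    free_to_sws = free_to_total + ft / ks["KF"]
    if scale == "seawater":
        return h
    if scale == "total":
        return h / free_to_total * free_to_sws
    if scale == "free":
        return h * free_to_sws
    if scale == "nbs":
        # Takahashi et al. (1982) activity coefficient of H+.
        t_k = temperature + 273.15
        f_h = 1.29 - 0.00204 * t_k + (4.61e-4 - 1.48e-6 * t_k) * salinity**2
        return h / f_h
    raise ValueError(f"unknown pH scale {scale!r}")


def _ph_sws_to_scale(ph_sws: float, scale: str, ks: dict, temperature: float, salinity: float) -> float:
    h_sws = 10.0**-ph_sws
    st, ft = ks["sulfate_total"], ks["fluoride_total"]
    free_to_total = 1.0 + st / ks["KS"]
    free_to_sws = free_to_total + ft / ks["KF"]
    if scale == "seawater":
        h = h_sws
    elif scale == "total":
        h = h_sws / free_to_sws * free_to_total
    elif scale == "free":
        h = h_sws / free_to_sws
    elif scale == "nbs":
        t_k = temperature + 273.15
        f_h = 1.29 - 0.00204 * t_k + (4.61e-4 - 1.48e-6 * t_k) * salinity**2
        h = h_sws * f_h
    else:
        raise ValueError(f"unknown pH scale {scale!r}")
    return -math.log10(h)


def _non_carbonate_alkalinity(h_sws: float, ks: dict) -> float:
    """Borate + hydroxide - free H+ - bisulfate - HF, mol/kg-SW."""
    st, ft, bt = ks["sulfate_total"], ks["fluoride_total"], ks["boron_total"]
    free_to_sws = 1.0 + st / ks["KS"] + ft / ks["KF"]
    h_free = h_sws / free_to_sws
    b_alk = bt * ks["KB"] / (ks["KB"] + h_sws)
    oh = ks["KW"] / h_sws
    hso4 = st / (1.0 + ks["KS"] / h_free)
    hf = ft / (1.0 + ks["KF"] / h_free)
    return b_alk + oh - h_free - hso4 - hf


def solve_pco2(state: CarbonateState, fugacity: bool = False) -> float:
    """pCO2 (μatm) from pH plus alkalinity or DIC.

    With pH known the system is closed-form on either branch: the
    non-carbonate alkalinity terms are evaluated at [H+] and subtracted to
    give carbonate alkalinity (TA branch), or DIC is speciated directly
    (DIC branch); [CO2*]/K0 is then the partial pressure.  Set
    ``fugacity=True`` to apply the Weiss (1974) virial correction and
    return fCO2 instead.
    """
    ks = equilibrium_constants(
        state.temperature, state.salinity, state.pressure, state.constants_set
    )
    h = _h_sws_from_ph(state.ph, state.ph_scale, ks, state.temperature, state.salinity)
    k1, k2 = ks["K1"], ks["K2"]
    if state.alkalinity is not None:
        ta = state.alkalinity * 1e-6
        ca = ta - _non_carbonate_alkalinity(h, ks)
        if ca <= 0.0:
            raise ArithmeticError(
                f"non-positive carbonate alkalinity ({ca:.3e} mol/kg) at "
                f"pH={state.ph}, TA={state.alkalinity} μmol/kg: inputs are "
                "outside the physical regime"
            )
        co2_star = ca / (k1 / h + 2.0 * k1 * k2 / (h * h))
    else:
        dic = state.dic * 1e-6
        co2_star = dic * h * h / (h * h + k1 * h + k1 * k2)
    pco2_uatm = co2_star / ks["K0"] * 1e6
    if fugacity:
        pco2_uatm *= _fugacity_factor(state.temperature)
    return pco2_uatm


def _fugacity_factor(temperature: float) -> float:
    # Weiss (1974) virial coefficients for CO2 at 1 atm total pressure.
    t_k = temperature + 273.15
    b = -1636.75 + 12.0408 * t_k - 3.27957e-2 * t_k**2 + 3.16528e-5 * t_k**3
    delta = 57.7 - 0.118 * t_k
    return math.exp((b + 2.0 * delta) * 1.01325 / (GAS_CONSTANT_BAR * t_k))


def solve_ph_from_pco2(
    pco2_uatm: float,
    alkalinity: float,
    temperature: float,
    salinity: float,
    ph_scale: str = "total",
    constants_set: str = "mehrbach_dm87",
) -> float:
    """Invert the TA branch: pH (on ``ph_scale``) from pCO2 and alkalinity.

    Bracketed root-finding on pH(SWS) in [2, 12]; used for round-trip
    checks and for back-solving reported pH values in synthetic data.
    """
    if pco2_uatm <= 0:
        raise ValueError("pco2_uatm must be positive")
    ks = equilibrium_constants(temperature, salinity, 0.0, constants_set)
    co2_star = ks["K0"] * pco2_uatm * 1e-6
    ta = alkalinity * 1e-6
    k1, k2 = ks["K1"], ks["K2"]

    def residual(ph_sws: float) -> float:
        h = 10.0**-ph_sws
        ca = co2_star * (k1 / h + 2.0 * k1 * k2 / (h * h))
        return ca + _non_carbonate_alkalinity(h, ks) - ta

    try:
        ph_sws = brentq(residual, 2.0, 12.0, xtol=1e-12, rtol=8.9e-16)
    except ValueError as exc:  # no sign change in bracket
        raise ArithmeticError(
            f"no pH root in [2, 12] for pCO2={pco2_uatm} μatm, "
            f"TA={alkalinity} μmol/kg, T={temperature} °C, S={salinity}"
        ) from exc
    return _ph_sws_to_scale(ph_sws, ph_scale, ks, temperature, salinity)


def convert_ph_records(df, constants_set: str = "mehrbach_dm87", default_scale: str = "total"):
    """Vectorised helper: add a ``pco2_uatm`` column to a DataFrame of
    (ph, ph_scale, temperature_c, salinity_psu, alkalinity_umol_kg or
    dic_umol_kg) rows.  Rows with missing pH are passed through untouched.
    """
    import pandas as pd

    out = df.copy()
    if "pco2_uatm" not in out:
        out["pco2_uatm"] = np.nan
    for idx, row in out.iterrows():
        if pd.isna(row.get("ph")):
            continue
        scale = row.get("ph_scale")
        if scale is None or (isinstance(scale, float) and pd.isna(scale)) or scale == "":
            scale = default_scale
        alk = row.get("alkalinity_umol_kg")
        dic = row.get("dic_umol_kg")
        alk_val = None if (alk is None or pd.isna(alk)) else float(alk)
        dic_val = None if (dic is None or pd.isna(dic)) else float(dic)
        if alk_val is not None:
            dic_val = None  # prefer the TA branch when both are reported
        state = CarbonateState(
            temperature=row["temperature_c"],
            salinity=row["salinity_psu"],
            ph=row["ph"],
            ph_scale=scale,
            alkalinity=alk_val,
            dic=dic_val,
            constants_set=constants_set,
        )
        out.loc[idx, "pco2_uatm"] = solve_pco2(state)
    return out
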