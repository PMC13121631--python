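"""Gas-side uptake model and CO2 loading/speciation arithmetic.

A vapour–liquid equilibrium (VLE) rig meters CO2 from a high-pressure burette
into the headspace above a stirred capture solution.  The low-pressure
headspace is treated as an ideal gas (PV = nRT); the ~30 bar burette needs a
real-gas equation of state, the five-constant Beattie–Bridgeman form

    P = (RT / v²) (1 − c / (v T³)) (v + B) − A / v²
    A = A0 (1 − a / v),   B = B0 (1 − b / v)

with the accepted CO2 constants A0 = 507.2836 kPa·L²/mol², a = 0.07132 L/mol,
B0 = 0.10476 L/mol, b = 0.07235 L/mol, c = 6.60e5 L³·K³/mol, and
R = 8.314 L·kPa/(mol·K).  Moles absorbed by the solution at any time are the
initial burette inventory minus what remains in the burette and headspace.

Chemistry-side bookkeeping: each absorbed CO2 consumes two glycinate anions,
producing one glycine-carbamate and one glycine zwitterion, which fixes the
composition of a loaded simulation box at a given loading in equivalents
(mol CO2 per mol glycinate; 0.5 is the carbamate-stoichiometry ceiling,
beyond which the avoided bicarbonate channel would open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

R_GAS = 8.314  # L kPa / (mol K)


@dataclass(frozen=True)
class EOSParams:
    """Beattie–Bridgeman constants; defaults are the accepted CO2 values."""

    A0: float = 507.2836   # kPa L²/mol²
    a: float = 0.07132     # L/mol
    B0: float = 0.10476    # L/mol
    b: float = 0.07235     # L/mol
    c: float = 6.60e5      # L³ K³/mol
    R: float = R_GAS       # L kPa/(mol K)

    def __post_init__(self) -> None:
        if min(self.A0, self.a, self.B0, self.b, self.c, self.R) < 0:
            raise ValueError("Beattie–Bridgeman constants must be non-negative")

    @classmethod
    def ideal(cls) -> "EOSParams":
        return cls(A0=0.0, a=0.0, B0=0.0, b=0.0, c=0.0)


def bb_pressure(nu: float, T: float, p: EOSParams = EOSParams()) -> float:
    """Beattie–Bridgeman pressure (kPa) at molar volume nu (L/mol) and T (K)."""
    if nu <= 0 or T <= 0:
        raise ValueError("molar volume and temperature must be positive")
    if nu <= max(p.b, p.a):
        raise ValueError(f"unphysical molar volume {nu} L/mol for these constants")
    A = p.A0 * (1.0 - p.a / nu)
    B = p.B0 * (1.0 - p.b / nu)
    return (p.R * T / nu ** 2) * (1.0 - p.c / (nu * T ** 3)) * (nu + B) - A / nu ** 2


class ConvergenceError(RuntimeError):
    """No physical molar-volume root bracketed for the requested pressure."""


def bb_molar_volume(P: float, T: float, p: EOSParams = EOSParams()) -> float:
    """Invert the Beattie–Bridgeman equation for molar volume (L/mol).

    Starts from the ideal-gas guess RT/P and solves on the bracket
    [0.1 RT/P, 10 RT/P]; the round-trip pressure residual is below 1e-10
    relative for CO2-like constants at laboratory conditions.
    """
    if P <= 0 or T <= 0:
        raise ValueError("pressure and temperature must be positive")
    nu0 = p.R * T / P
    lo, hi = 0.1 * nu0, 10.0 * nu0
    lo = max(lo, 1.001 * max(p.a, p.b, 1e-12))

    def resid(nu: float) -> float:
        return bb_pressure(nu, T, p) - P

    try:
        f_lo, f_hi = resid(lo), resid(hi)
    except ValueError as err:
        raise ConvergenceError(str(err)) from err
    if f_lo * f_hi > 0:
        raise ConvergenceError(
            f"no molar-volume root bracketed in [{lo:.3g}, {hi:.3g}] L/mol"
        )
    nu = brentq(resid, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return float(nu)


def moles_in_vessel(P: float, V: float, T: float, R: float = R_GAS) -> float:
    """Ideal-gas moles in the low-pressure vessel headspace: n = PV/RT."""
    if min(P, V, T) <= 0:
        raise ValueError("P, V, T must be positive")
    return P * V / (R * T)


def syringe_volume(n_co2: float, T: float, P: float, R: float = R_GAS) -> float:
    """Ideal-gas volume (L) of a CO2 charge: V = nRT/P."""
    if min(n_co2, T, P) <= 0:
        raise ValueError("n, T, P must be positive")
    return n_co2 * R * T / P


@dataclass
class UptakeSeries:
    """Time-resolved burette and vessel-headspace state of a VLE run.

    Pressures in kPa, volumes in L, temperatures in K, time in s.  Volumes
    and temperatures may be scalars (constant) or per-sample arrays.
    """

    time_s: np.ndarray
    p_burette: np.ndarray
    p_vessel: np.ndarray
    v_burette: float | np.ndarray
    v_vessel: float | np.ndarray
    t_burette: float | np.ndarray
    t_vessel: float | np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.p_burette = np.asarray(self.p_burette, dtype=float)
        self.p_vessel = np.asarray(self.p_vessel, dtype=float)
        n = self.time_s.size
        if self.p_burette.size != n or self.p_vessel.size != n:
            raise ValueError("pressure series must match the time grid")

    def _per_sample(self, x) -> np.ndarray:
        return np.broadcast_to(np.asarray(x, dtype=float), self.time_s.shape)

    @classmethod
    def from_csv(
        cls, path: str, v_burette: float, v_vessel: float,
        t_burette: float, t_vessel: float,
    ) -> "UptakeSeries":
        """Load a CSV with columns time_s, P_burette_kPa, P_vessel_kPa."""
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            p_burette=df["P_burette_kPa"].to_numpy(),
            p_vessel=df["P_vessel_kPa"].to_numpy(),
            v_burette=v_burette, v_vessel=v_vessel,
            t_burette=t_burette, t_vessel=t_vessel,
        )


class InconsistentRecordError(ValueError):
    """The series implies significantly negative absorption."""


def absorbed_moles(
    series: UptakeSeries,
    p: EOSParams = EOSParams(),
    tolerance: float = 1e-9,
) -> np.ndarray:
    """Absorbed CO2 (mol) at each time point.

    n_abs(t) = n_burette(0) − n_burette(t) − n_headspace(t), with the burette
    inventory from the Beattie–Bridgeman equation and the headspace from the
    ideal gas law.  The vessel headspace is evacuated at t = 0, so a series
    whose headspace pressure starts at 0 and whose burette never refills
    yields a non-negative, conservation-obeying record.
    """
    vb = series._per_sample(series.v_burette)
    vv = series._per_sample(series.v_vessel)
    tb = series._per_sample(series.t_burette)
    tv = series._per_sample(series.t_vessel)
    n_bur = np.array([
        v / bb_molar_volume(pb, t, p)
        for pb, v, t in zip(series.p_burette, vb, tb)
    ])
    n_head = np.where(
        series.p_vessel > 0,
        series.p_vessel * vv / (p.R * tv),
        0.0,
    )
    n_abs = n_bur[0] - n_bur - n_head
    if np.any(n_abs < -max(tolerance, 1e-12 * n_bur[0])):
        raise InconsistentRecordError(
            f"negative absorbed moles (min {n_abs.min():.3g}); "
            "burette refill or sensor inconsistency?"
        )
    return n_abs


def plan_loading(salt_molality: float, equivalents: float) -> float:
    """CO2 molality (mol/kg H2O) at a loading in equivalents of the salt."""
    if salt_molality < 0 or equivalents < 0:
        raise ValueError("inputs must be non-negative")
    return salt_molality * equivalents


class StoichiometryError(ValueError):
    """Loading beyond the 0.5-equivalent carbamate ceiling."""


def speciate_box(
    n_glycinate_total: int, equivalents: float
) -> tuple[int, int, int]:
    """Split a glycinate inventory into (anion, zwitterion, carbamate) counts.

    Each CO2 converts two glycinate anions into one carbamate plus one
    zwitterion; n_CO2 is rounded to the nearest whole molecule.  Loadings
    above 0.5 equivalents would require the (excluded) bicarbonate channel.
    """
    if n_glycinate_total < 0:
        raise ValueError("glycinate count must be non-negative")
    if not 0.0 <= equivalents <= 0.5:
        raise StoichiometryError(
            "equivalents must lie in [0, 0.5]: beyond 0.5 the carbamate "
            "stoichiometry is exhausted (bicarbonate channel out of scope)"
        )
    # nearest-integer molecule count, clamped so rounding at the 0.5 ceiling
    # (odd inventories) cannot overdraw the anions
    n_co2 = min(int(np.rint(n_glycinate_total * equivalents)),
                n_glycinate_total // 2)
    n_anion = n_glycinate_total - 2 * n_co2
    return n_anion, n_co2, n_co2
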