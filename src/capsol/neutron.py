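"""Isotope-weighted neutron structure factors from partial g(r)s.

Neutron diffraction on H/D isotopically substituted solutions measures a
total interference function F(Q) that is a concentration- and
scattering-length-weighted sum of Faber–Ziman partial structure factors:

    S_ab(Q) - 1 = (4 pi rho / Q) ∫ r (g_ab(r) - 1) sin(Qr) M(r) dr
    F(Q)        = sum_{a<=b} (2 - delta_ab) c_a c_b <b_a> <b_b> (S_ab(Q) - 1)

with M(r) a Lorch window damping finite-range truncation ripple, c_a the site
concentration of atom type a, and <b_a> its isotope-fraction-weighted coherent
scattering length.  Because b_H and b_D have opposite signs, H/D substitution
re-weights the same partials into independent observables — including "null"
mixtures whose mean hydrogen scattering length vanishes.

F(Q) here is the distinct (interference) term only; self-scattering and
inelasticity corrections belong to data reduction, not to this forward model.
Agreement between curves is scored with an R factor: the mean squared
residual normalised by the mean squared data magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# Coherent neutron scattering lengths, fm (standard Sears tabulation)
COHERENT_B_FM = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
    "Na": 3.63,
    "K": 3.67,
}


def mean_scattering_length(isotope_fractions: dict[str, float]) -> float:
    """Isotope-fraction-weighted coherent scattering length, fm."""
    total = sum(isotope_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("isotope fractions must sum to 1")
    return float(
        sum(f * COHERENT_B_FM[iso] for iso, f in isotope_fractions.items())
    )


def null_water_h_fraction() -> float:
    """H fraction of the H/D mix with zero mean hydrogen scattering length."""
    bh, bd = COHERENT_B_FM["H"], COHERENT_B_FM["D"]
    return bd / (bd - bh)


@dataclass
class IsotopomerComposition:
    """Site concentrations and mean scattering lengths of one isotopomer.

    ``concentrations`` maps atom-type label -> fraction of all sites (sums
    to 1); ``b_fm`` maps the same labels to mean coherent scattering lengths
    in fm, already averaged over any isotope mixture on that site.
    """

    concentrations: dict[str, float]
    b_fm: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.concentrations.values()) - 1.0) > 1e-6:
            raise ValueError("site concentrations must sum to 1")
        missing = set(self.concentrations) - set(self.b_fm)
        if missing:
            raise ValueError(f"missing scattering lengths for {sorted(missing)}")

    @classmethod
    def from_isotopes(
        cls,
        concentrations: dict[str, float],
        isotopes: dict[str, dict[str, float]],
    ) -> "IsotopomerComposition":
        """Build from per-type isotope fractions, e.g. HW: {H: 0.641, D: 0.359}."""
        return cls(
            concentrations=dict(concentrations),
            b_fm={lab: mean_scattering_length(fr) for lab, fr in isotopes.items()},
        )


@dataclass
class StructureFactor:
    """A total interference function on a Q grid."""

    q: np.ndarray      # Å^-1
    f: np.ndarray      # barns/sr/atom-scale weighted interference function

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.q.shape != self.f.shape:
            raise ValueError("Q grid and F(Q) must have equal length")


def partial_sq(
    rdf,
    rho_total: float,
    q_grid: np.ndarray,
    lorch: bool = True,
    tail_tolerance: float = 0.1,
) -> np.ndarray:
    """Fourier-transform g(r) − 1 into a partial structure factor S(Q) − 1.

    ``rho_total`` is the total atomic number density (Å^-3) of the system,
    per Faber–Ziman convention.  A Lorch window sin(pi r/R)/(pi r/R) tapers
    the finite-range truncation.  If the g(r) tail has not converged to 1
    within ``tail_tolerance`` a warning is issued and the taper proceeds.
    """
    r = rdf.r_mid
    h = rdf.g - 1.0
    k = max(1, int(round(0.1 * r.size)))
    if abs(h[-k:].mean()) > tail_tolerance:
        warnings.warn(
            "g(r) tail has not converged to 1; transform will be tapered "
            "but may ring", stacklevel=2,
        )
    r_max = rdf.bin_edges[-1]
    # np.sinc(x) = sin(pi x)/(pi x), so this is the Lorch window with R = r_max
    window = np.sinc(r / r_max) if lorch else np.ones_like(r)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q grid must be positive")
    # (4 pi rho / Q) ∫ r h(r) sin(Qr) M(r) dr, trapezoid on the bin centers
    integrand = r[None, :] * h[None, :] * window[None, :] * np.sin(
        q[:, None] * r[None, :]
    )
    integral = np.trapezoid(integrand, r, axis=1)
    return 4.0 * np.pi * rho_total / q * integral


class IncompletePartialsError(KeyError):
    """A required partial structure factor is missing."""


def total_fq(
    partials: dict[tuple[str, str], np.ndarray],
    comp: IsotopomerComposition,
    q_grid: np.ndarray,
) -> StructureFactor:
    """Faber–Ziman weighted sum of partials for one isotopomer.

    ``partials`` maps unordered atom-type label pairs to S_ab(Q) − 1 arrays on
    the common ``q_grid``.  Scattering lengths in fm are converted so F is on
    the conventional barns-scale (1 barn = 100 fm²).
    """
    q = np.asarray(q_grid, dtype=float)
    f = np.zeros_like(q)
    labels = sorted(comp.concentrations)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            s = partials.get((a, b), partials.get((b, a)))
            if s is None:
                raise IncompletePartialsError(f"missing partial for {(a, b)}")
            s = np.asarray(s, dtype=float)
            if s.shape != q.shape:
                raise ValueError(f"partial {(a, b)} not on the common Q grid")
            mult = 1.0 if a == b else 2.0
            weight = (
                mult
                * comp.concentrations[a] * comp.concentrations[b]
                * comp.b_fm[a] * comp.b_fm[b]
            ) / 100.0  # fm² -> barns
            f += weight * s
    return StructureFactor(q=q, f=f)


def weight_sum_identity(comp: IsotopomerComposition) -> tuple[float, float]:
    """Both sides of sum_ab w_ab = (sum_a c_a b_a)² − checkable identity.

    Returns (sum of the (2 − delta) c c b b weights over unordered pairs,
    square of the concentration-weighted mean scattering length), in fm².
    """
    labels = sorted(comp.concentrations)
    total = 0.0
    for i, a in enumerate(labels):
        for b in labels[i:]:
            mult = 1.0 if a == b else 2.0
            total += (
                mult * comp.concentrations[a] * comp.concentrations[b]
                * comp.b_fm[a] * comp.b_fm[b]
            )
    mean_b = sum(comp.concentrations[a] * comp.b_fm[a] for a in labels)
    return total, mean_b ** 2


class NoOverlapError(ValueError):
    """Simulated and experimental curves share no Q range."""


def r_factor(f_sim: StructureFactor, f_exp: StructureFactor) -> float:
    """Goodness of fit: mean squared residual over mean squared data.

    The experimental curve is linearly interpolated onto the simulated grid
    over the overlapping Q range.  Identical curves score 0; residual
    contributions are quadratic.
    """
    lo = max(f_sim.q.min(), f_exp.q.min())
    hi = min(f_sim.q.max(), f_exp.q.max())
    if lo >= hi:
        raise NoOverlapError("curves share no Q range")
    sel = (f_sim.q >= lo) & (f_sim.q <= hi)
    exp_on_sim = np.interp(f_sim.q[sel], f_exp.q, f_exp.f)
    denom = float(np.mean(exp_on_sim ** 2))
    if denom == 0:
        raise ValueError("reference curve is identically zero on the overlap")
    return float(np.mean((f_sim.f[sel] - exp_on_sim) ** 2) / denom)


def read_fq(path: str) -> StructureFactor:
    """Read a two-column Q, F(Q) text file (comments with #)."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    return StructureFactor(q=data[:, 0], f=data[:, 1])


def write_fq(sf: StructureFactor, path: str) -> None:
    header = "Q_inv_angstrom  F_Q_barns"
    np.savetxt(path, np.column_stack([sf.q, sf.f]), header=header)
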