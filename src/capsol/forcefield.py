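"""Force-field model, molecular topology and the pairwise interaction potential.

Everything downstream — the Monte Carlo sampler, the radial distribution
functions, the molecule-pair energetics — consumes the types defined here.

Units are Å, kJ/mol, elementary charge and Kelvin throughout.  The Coulomb
prefactor ``COULOMB_K`` converts e²/Å to kJ/mol (CODATA-derived).  Interatomic
potentials are the standard 12-6 Lennard-Jones plus point-charge Coulomb term,
with unlike-pair LJ parameters from Lorentz–Berthelot mixing:

    sigma_ij = (sigma_i + sigma_j) / 2
    eps_ij   = sqrt(eps_i * eps_j)
    u(r)     = 4 eps_ij [ (sigma_ij/r)^12 - (sigma_ij/r)^6 ] + k_e q_i q_j / r

Molecules are rigid bodies: a :class:`MoleculeTemplate` carries the local-frame
site geometry and every instance in a :class:`Configuration` is a translated,
rotated copy.  Coulomb interactions are plain (non-Ewald) under the minimum
image convention; the pair-energy analysis sums site pairs with no distance
cutoff beyond minimum image, while the sampler truncates at a stated cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

# Coulomb constant k_e = e^2 N_A / (4 pi eps0), in kJ Å / (mol e^2)
COULOMB_K = 1389.35457644

# Gas constant in kJ/(mol K), used for Boltzmann factors
R_KJ_MOL_K = 8.314462618e-3

AVOGADRO = 6.02214076e23


class SingularSeparationError(ValueError):
    """Two interaction sites are (numerically) on top of each other."""


# ---------------------------------------------------------------------------
# force-field parameter model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceFieldSite:
    """One atom type: LJ parameters, partial charge, element identity.

    sigma in Å, epsilon in kJ/mol, charge in elementary charge units,
    mass in g/mol.
    """

    label: str
    sigma: float
    epsilon: float
    charge: float
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"site {self.label}: sigma must be >= 0")
        if self.epsilon < 0:
            raise ValueError(f"site {self.label}: epsilon must be >= 0")
        if abs(self.charge) > 2.0 + 1e-9:
            raise ValueError(f"site {self.label}: |charge| > 2 e is not supported")


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecular species: ordered sites with local-frame coordinates."""

    name: str
    site_labels: tuple[str, ...]
    local_coords: np.ndarray  # (n_sites, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.local_coords, dtype=float)
        if coords.shape != (len(self.site_labels), 3):
            raise ValueError(
                f"template {self.name}: coordinate array shape {coords.shape} "
                f"does not match {len(self.site_labels)} site labels"
            )
        object.__setattr__(self, "local_coords", coords)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def net_charge(self, ff: "ForceField") -> float:
        return float(sum(ff.sites[lab].charge for lab in self.site_labels))

    def mass(self, ff: "ForceField") -> float:
        return float(sum(ff.sites[lab].mass for lab in self.site_labels))

    def extent(self) -> float:
        """Largest intramolecular site-site distance, Å."""
        if self.n_sites == 1:
            return 0.0
        d = self.local_coords[:, None, :] - self.local_coords[None, :, :]
        return float(np.sqrt((d ** 2).sum(axis=-1)).max())


@dataclass
class ForceField:
    """Atom-type table plus molecule templates plus the Coulomb constant."""

    sites: dict[str, ForceFieldSite]
    templates: dict[str, MoleculeTemplate]
    coulomb_k: float = COULOMB_K

    def __post_init__(self) -> None:
        for tmpl in self.templates.values():
            for lab in tmpl.site_labels:
                if lab not in self.sites:
                    raise ValueError(
                        f"template {tmpl.name}: site label {lab!r} has no "
                        "force-field entry"
                    )

    def site_params(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sigma, epsilon, charge) arrays for a sequence of site labels."""
        sig = np.array([self.sites[l].sigma for l in labels])
        eps = np.array([self.sites[l].epsilon for l in labels])
        q = np.array([self.sites[l].charge for l in labels])
        return sig, eps, q


def combine_lj(site_a: ForceFieldSite, site_b: ForceFieldSite) -> tuple[float, float]:
    """Lorentz–Berthelot mixing: arithmetic-mean sigma, geometric-mean epsilon."""
    if site_a.epsilon < 0 or site_b.epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    sigma_ij = 0.5 * (site_a.sigma + site_b.sigma)
    epsilon_ij = float(np.sqrt(site_a.epsilon * site_b.epsilon))
    return sigma_ij, epsilon_ij


def pair_potential(
    r: float | np.ndarray,
    sigma_ij: float | np.ndarray,
    epsilon_ij: float | np.ndarray,
    qi: float | np.ndarray,
    qj: float | np.ndarray,
    coulomb_k: float = COULOMB_K,
) -> float | np.ndarray:
    """LJ 12-6 plus Coulomb energy of one site pair at separation r (Å)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularSeparationError("pair separation must be positive")
    sr6 = np.where(sigma_ij > 0, (np.asarray(sigma_ij) / r) ** 6, 0.0)
    e = 4.0 * np.asarray(epsilon_ij) * (sr6 ** 2 - sr6) + coulomb_k * np.asarray(qi) * np.asarray(qj) / r
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# configurations and trajectories
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap displacement vectors into the central image of a cubic box."""
    return d - box_length * np.round(d / box_length)


@dataclass
class Configuration:
    """A periodic cubic box of rigid molecules.

    Sites are stored flat; ``mol_start`` gives the slice boundaries of each
    molecule (``mol_start[m]:mol_start[m+1]``).  ``species[m]`` names molecule
    m's template; ``site_labels`` holds the per-site atom-type labels.
    """

    box_length: float
    temperature: float
    species: list[str]
    site_labels: np.ndarray      # (n_sites,) str
    coords: np.ndarray           # (n_sites, 3) Å
    mol_start: np.ndarray        # (n_molecules + 1,) int
    mol_index: np.ndarray = field(default=None)  # (n_sites,) int, derived

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        self.coords = np.asarray(self.coords, dtype=float)
        self.site_labels = np.asarray(self.site_labels)
        self.mol_start = np.asarray(self.mol_start, dtype=np.intp)
        if self.mol_index is None:
            self.mol_index = np.repeat(
                np.arange(self.n_molecules, dtype=np.intp), np.diff(self.mol_start)
            )

    @classmethod
    def from_molecules(
        cls,
        box_length: float,
        temperature: float,
        molecules: Iterable[tuple[str, Sequence[str], np.ndarray]],
    ) -> "Configuration":
        species, labels, coords, starts = [], [], [], [0]
        for name, labs, xyz in molecules:
            species.append(name)
            labels.extend(labs)
            coords.append(np.asarray(xyz, dtype=float))
            starts.append(starts[-1] + len(labs))
        return cls(
            box_length=box_length,
            temperature=temperature,
            species=species,
            site_labels=np.array(labels),
            coords=np.concatenate(coords, axis=0) if coords else np.empty((0, 3)),
            mol_start=np.array(starts, dtype=np.intp),
        )

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def mol_slice(self, m: int) -> slice:
        return slice(int(self.mol_start[m]), int(self.mol_start[m + 1]))

    def wrapped_coords(self) -> np.ndarray:
        """Coordinates folded into [0, L).

        Per-site wrapping; safe for distance queries (intramolecular pairs
        are matched by molecule index, not adjacency).  Stored coordinates
        keep each molecule contiguous — see :func:`wrap_molecules`.
        """
        return np.mod(self.coords, self.box_length)

    def wrap_molecules(self) -> None:
        """Shift whole molecules so each first site lies in [0, L).

        Keeps every molecule spatially contiguous (centroids and rigid-body
        rotations stay meaningful) while bounding the box content.
        """
        L = self.box_length
        for m in range(self.n_molecules):
            sl = self.mol_slice(m)
            shift = L * np.floor(self.coords[sl][0] / L)
            if np.any(shift):
                self.coords[sl] -= shift

    def select(self, label: str) -> np.ndarray:
        """Indices of all sites with the given atom-type label."""
        return np.flatnonzero(self.site_labels == label)

    def copy(self) -> "Configuration":
        return Configuration(
            box_length=self.box_length,
            temperature=self.temperature,
            species=list(self.species),
            site_labels=self.site_labels,
            coords=self.coords.copy(),
            mol_start=self.mol_start,
            mol_index=self.mol_index,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing box length, composition and temperature."""

    frames: list[Configuration]
    iteration_index: list[int]
    acceptance_fraction: float | None = None
    running_energies: list[float] | None = None
    recomputed_energies: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.iteration_index):
            raise ValueError("one iteration index per frame required")
        if self.frames:
            ref = self.frames[0]
            for k, fr in enumerate(self.frames[1:], start=1):
                if (
                    fr.box_length != ref.box_length
                    or fr.species != ref.species
                    or fr.temperature != ref.temperature
                ):
                    raise ValueError(f"frame {k} differs in box, composition or T")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# molecule-pair and whole-box energies
# ---------------------------------------------------------------------------

def molecule_pair_energy(
    config: Configuration, mol_a: int, mol_b: int, ff: ForceField
) -> float:
    """Summed LJ+Coulomb energy over every intermolecular site pair.

    Minimum-image separations; no distance cutoff.  Symmetric in its
    molecule arguments.
    """
    if mol_a == mol_b:
        raise ValueError("molecule paired with itself")
    if mol_a > mol_b:  # canonical order: bitwise-identical under swap
        mol_a, mol_b = mol_b, mol_a
    sa, sb = config.mol_slice(mol_a), config.mol_slice(mol_b)
    lab_a = config.site_labels[sa]
    lab_b = config.site_labels[sb]
    sig_a, eps_a, q_a = ff.site_params(lab_a)
    sig_b, eps_b, q_b = ff.site_params(lab_b)
    d = minimum_image(
        config.coords[sa][:, None, :] - config.coords[sb][None, :, :],
        config.box_length,
    )
    r = np.sqrt((d ** 2).sum(axis=-1))
    if np.any(r < 1e-6):
        raise SingularSeparationError(
            f"overlapping sites between molecules {mol_a} and {mol_b}"
        )
    sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])
    qq = q_a[:, None] * q_b[None, :]
    return float(np.sum(pair_potential(r, sig_ij, eps_ij, qq, 1.0, ff.coulomb_k)))


class PairTables:
    """Per-atom-type mixing tables for fast vectorised energy evaluation."""

    def __init__(self, config: Configuration, ff: ForceField):
        labels = sorted(set(config.site_labels.tolist()))
        self.label_index = {lab: i for i, lab in enumerate(labels)}
        self.type_index = np.array(
            [self.label_index[l] for l in config.site_labels], dtype=np.intp
        )
        sig, eps, q = ff.site_params(labels)
        self.sig = 0.5 * (sig[:, None] + sig[None, :])
        self.eps4 = 4.0 * np.sqrt(eps[:, None] * eps[None, :])
        self.qqk = ff.coulomb_k * (q[:, None] * q[None, :])


def _site_block_energy(
    r2: np.ndarray, sig: np.ndarray, eps4: np.ndarray, qqk: np.ndarray,
    active: np.ndarray,
) -> float:
    """Energy of a block of site pairs given squared distances and a mask."""
    r2m = np.where(active, r2, np.inf)
    if np.any(r2m < 1e-12):
        raise SingularSeparationError("overlapping sites in energy evaluation")
    inv_r2 = 1.0 / r2m
    sr6 = np.where(sig > 0, (sig * sig * inv_r2) ** 3, 0.0)
    e = eps4 * (sr6 * sr6 - sr6) + qqk * np.sqrt(inv_r2)
    return float(e.sum())


def molecule_environment_energy(
    config: Configuration,
    mol: int,
    tables: PairTables,
    cutoff: float | None = None,
    coords_override: np.ndarray | None = None,
) -> float:
    """Energy of one molecule with every other molecule in the box.

    ``cutoff`` (the sampler's truncation) acts on whole molecule pairs, keyed
    on the distance between the molecules' first sites: truncating individual
    site pairs would split neutral charge groups at the cutoff sphere and
    leave large monopole artifacts.
    """
    sl = config.mol_slice(mol)
    xi = config.coords[sl] if coords_override is None else coords_override
    ti = tables.type_index[sl]
    d = minimum_image(xi[:, None, :] - config.coords[None, :, :], config.box_length)
    r2 = (d ** 2).sum(axis=-1)
    if cutoff is None:
        active = (config.mol_index != mol)[None, :]
    else:
        refs = config.coords[config.mol_start[:-1]]
        dref = minimum_image(refs - xi[0], config.box_length)
        active_mol = (dref ** 2).sum(axis=-1) <= cutoff * cutoff
        active_mol[mol] = False
        active = active_mol[config.mol_index][None, :]
    tj = tables.type_index
    return _site_block_energy(
        r2, tables.sig[ti[:, None], tj], tables.eps4[ti[:, None], tj],
        tables.qqk[ti[:, None], tj], active,
    )


def total_box_energy(
    config: Configuration,
    ff: ForceField,
    cutoff: float | None = None,
    tables: PairTables | None = None,
) -> float:
    """Total intermolecular energy: half-sum of every molecule's environment."""
    if tables is None:
        tables = PairTables(config, ff)
    return 0.5 * sum(
        molecule_environment_energy(config, m, tables, cutoff)
        for m in range(config.n_molecules)
    )


# ---------------------------------------------------------------------------
# default embedded parameters
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _glycine_skeleton() -> dict[str, np.ndarray]:
    """Heavy-atom skeleton shared by the three glycine-derived species.

    CA at the origin, amine N along +x (C–N 1.47 Å), carboxyl C in the
    xy-plane (C–C 1.52 Å) with two C–O 1.25 Å at a split of ~126°.
    """
    ca = np.zeros(3)
    n = np.array([1.47, 0.0, 0.0])
    u_cg = _unit([-0.358, 0.934, 0.0])
    cg = 1.52 * u_cg
    w = _unit(np.cross(np.cross(u_cg, [0, 0, 1.0]), u_cg))  # in-plane normal
    o1 = cg + 1.25 * (0.454 * u_cg + 0.891 * w)
    o2 = cg + 1.25 * (0.454 * u_cg - 0.891 * w)
    # methylene hydrogens, C–H 1.09 Å, straddling the N/C plane
    h_base = -_unit(n / 1.47 + u_cg)
    ha1 = 1.09 * _unit(h_base + np.array([0, 0, 1.1]))
    ha2 = 1.09 * _unit(h_base - np.array([0, 0, 1.1]))
    return {"CA": ca, "N": n, "CG": cg, "O1": o1, "O2": o2, "HA1": ha1, "HA2": ha2}


# tetrahedral substituent directions around the amine N (pointing away from CA)
_N_SUBST_DIRS = [
    _unit([0.333, 0.943, 0.0]),
    _unit([0.333, -0.471, 0.816]),
    _unit([0.333, -0.471, -0.816]),
]


def _water_template() -> MoleculeTemplate:
    ang = np.deg2rad(109.47)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [np.cos(ang), np.sin(ang), 0.0],
    ])
    return MoleculeTemplate("water", ("OW", "HW", "HW"), coords)


def _glycinate_template() -> MoleculeTemplate:
    s = _glycine_skeleton()
    hn1 = s["N"] + 1.01 * _N_SUBST_DIRS[0]
    hn2 = s["N"] + 1.01 * _N_SUBST_DIRS[1]
    labels = ("NG", "HNG", "HNG", "CAG", "HAG", "HAG", "CG", "OG", "OG")
    coords = np.array([s["N"], hn1, hn2, s["CA"], s["HA1"], s["HA2"],
                       s["CG"], s["O1"], s["O2"]])
    return MoleculeTemplate("glycinate", labels, coords)


def _zwitterion_template() -> MoleculeTemplate:
    s = _glycine_skeleton()
    hs = [s["N"] + 1.01 * d for d in _N_SUBST_DIRS]
    labels = ("NZ", "HNZ", "HNZ", "HNZ", "CAZ", "HAZ", "HAZ", "CZ", "OZ", "OZ")
    coords = np.array([s["N"], *hs, s["CA"], s["HA1"], s["HA2"],
                       s["CG"], s["O1"], s["O2"]])
    return MoleculeTemplate("glycine_zwitterion", labels, coords)


def _carbamate_template() -> MoleculeTemplate:
    s = _glycine_skeleton()
    hn = s["N"] + 1.01 * _N_SUBST_DIRS[0]
    u = _N_SUBST_DIRS[1]
    cc = s["N"] + 1.40 * u  # carbamate carbon bound at the amine nitrogen
    w = _unit(np.cross(np.cross(u, [1.0, 0, 0]), u))
    oc1 = cc + 1.25 * (0.454 * u + 0.891 * w)
    oc2 = cc + 1.25 * (0.454 * u - 0.891 * w)
    labels = ("NC", "HNC", "CAC", "HAC", "HAC", "CXC", "OXC", "OXC",
              "CC", "OCC", "OCC")
    coords = np.array([s["N"], hn, s["CA"], s["HA1"], s["HA2"],
                       s["CG"], s["O1"], s["O2"], cc, oc1, oc2])
    return MoleculeTemplate("glycine_carbamate", labels, coords)


def _co2_template() -> MoleculeTemplate:
    coords = np.array([[0.0, 0.0, 0.0], [1.16, 0.0, 0.0], [-1.16, 0.0, 0.0]])
    return MoleculeTemplate("CO2", ("CO2C", "CO2O", "CO2O"), coords)


_DEFAULT_SITES = [
    # label, sigma, epsilon, charge, element, mass
    # SPC/E water
    ("OW", 3.166, 0.650, -0.8476, "O", 15.999),
    ("HW", 0.0, 0.0, 0.4238, "H", 1.008),
    # alkali cations (literature-style values for aqueous-solution work)
    ("Na", 2.32, 0.100, 1.0, "Na", 22.990),
    ("K", 3.10, 0.130, 1.0, "K", 39.098),
    # glycinate anion (OPLS-AA-style charges, net -1)
    ("NG", 3.25, 0.711, -0.90, "N", 14.007),
    ("HNG", 0.0, 0.0, 0.35, "H", 1.008),
    ("CAG", 3.50, 0.276, -0.10, "C", 12.011),
    ("HAG", 2.50, 0.126, 0.10, "H", 1.008),
    ("CG", 3.75, 0.439, 0.70, "C", 12.011),
    ("OG", 2.96, 0.879, -0.80, "O", 15.999),
    # glycine zwitterion (net 0)
    ("NZ", 3.25, 0.711, -0.30, "N", 14.007),
    ("HNZ", 0.0, 0.0, 0.33, "H", 1.008),
    ("CAZ", 3.50, 0.276, 0.01, "C", 12.011),
    ("HAZ", 2.50, 0.126, 0.10, "H", 1.008),
    ("CZ", 3.75, 0.439, 0.70, "C", 12.011),
    ("OZ", 2.96, 0.879, -0.80, "O", 15.999),
    # glycine carbamate dianion (net -2): amine-N-bound carboxylate added
    ("NC", 3.25, 0.711, -0.60, "N", 14.007),
    ("HNC", 0.0, 0.0, 0.30, "H", 1.008),
    ("CAC", 3.50, 0.276, -0.10, "C", 12.011),
    ("HAC", 2.50, 0.126, 0.10, "H", 1.008),
    ("CXC", 3.75, 0.439, 0.70, "C", 12.011),
    ("OXC", 2.96, 0.879, -0.80, "O", 15.999),
    ("CC", 3.75, 0.439, 0.80, "C", 12.011),
    ("OCC", 2.96, 0.879, -0.85, "O", 15.999),
    # CO2 (TraPPE-style)
    ("CO2C", 2.80, 0.224, 0.70, "C", 12.011),
    ("CO2O", 3.05, 0.657, -0.35, "O", 15.999),
    # structureless ideal-gas probe particle
    ("X", 0.0, 0.0, 0.0, "X", 1.0),
]

EXPECTED_NET_CHARGE = {
    "water": 0.0,
    "Na+": 1.0,
    "K+": 1.0,
    "glycinate": -1.0,
    "glycine_zwitterion": 0.0,
    "glycine_carbamate": -2.0,
    "CO2": 0.0,
    "ideal": 0.0,
}


def default_forcefield() -> ForceField:
    """Embedded default parameter set.

    SPC/E water, literature-style Na+/K+ LJ parameters, OPLS-AA-style charge
    sets for the three glycine-derived species, TraPPE-style CO2.  All values
    are overridable from a YAML parameter file (:func:`load_forcefield`).
    """
    sites = {
        lab: ForceFieldSite(lab, s, e, q, el, m)
        for lab, s, e, q, el, m in _DEFAULT_SITES
    }
    templates = {}
    for tmpl in (
        _water_template(),
        MoleculeTemplate("Na+", ("Na",), np.zeros((1, 3))),
        MoleculeTemplate("K+", ("K",), np.zeros((1, 3))),
        _glycinate_template(),
        _zwitterion_template(),
        _carbamate_template(),
        _co2_template(),
        MoleculeTemplate("ideal", ("X",), np.zeros((1, 3))),
    ):
        templates[tmpl.name] = tmpl
    ff = ForceField(sites=sites, templates=templates)
    for name, expected in EXPECTED_NET_CHARGE.items():
        got = ff.templates[name].net_charge(ff)
        if abs(got - expected) > 1e-6:
            raise AssertionError(f"default template {name}: net charge {got}")
    return ff


def load_forcefield(path: str) -> ForceField:
    """Read a force field from a YAML parameter file.

    Schema::

        coulomb_k: 1389.35457644        # optional
        atom_types:
          OW: {sigma: 3.166, epsilon: 0.650, charge: -0.8476,
               element: O, mass: 15.999}
        molecules:
          water:
            sites:
              - [OW, 0.0, 0.0, 0.0]
              - [HW, 1.0, 0.0, 0.0]

    Entries merge over the embedded defaults, so a file may override a single
    atom type without restating the rest.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_forcefield()
    sites = dict(base.sites)
    for lab, d in (raw.get("atom_types") or {}).items():
        sites[lab] = ForceFieldSite(
            lab, float(d["sigma"]), float(d["epsilon"]), float(d["charge"]),
            str(d.get("element", "?")), float(d.get("mass", 0.0)),
        )
    templates = dict(base.templates)
    for name, d in (raw.get("molecules") or {}).items():
        rows = d["sites"]
        labels = tuple(r[0] for r in rows)
        coords = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
        templates[name] = MoleculeTemplate(name, labels, coords)
    return ForceField(
        sites=sites, templates=templates,
        coulomb_k=float(raw.get("coulomb_k", base.coulomb_k)),
    )


def write_forcefield(ff: ForceField, path: str) -> None:
    """Dump a force field to the YAML schema read by :func:`load_forcefield`."""
    doc = {
        "coulomb_k": ff.coulomb_k,
        "atom_types": {
            s.label: {
                "sigma": s.sigma, "epsilon": s.epsilon, "charge": s.charge,
                "element": s.element, "mass": s.mass,
            }
            for s in ff.sites.values()
        },
        "molecules": {
            t.name: {
                "sites": [
                    [lab, float(x), float(y), float(z)]
                    for lab, (x, y, z) in zip(t.site_labels, t.local_coords)
                ]
            }
            for t in ff.templates.values()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
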