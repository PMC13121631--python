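"""Synthetic solution boxes and rigid-body Metropolis Monte Carlo sampling.

This is the data stage of the pipeline: it builds periodic cubic boxes of
water, alkali cations and glycine-derived solutes at stated compositions and
relaxes them with single-molecule Metropolis moves so that downstream analyses
(radial distribution functions, coordination shells, pair energetics) see
realistic short-range solvation structure.  It emulates the *output* of a
structure-refinement Monte Carlo engine — equilibrated molecular frames — not
the refinement itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .forcefield import (
    AVOGADRO,
    R_KJ_MOL_K,
    Configuration,
    ForceField,
    PairTables,
    Trajectory,
    minimum_image,
    molecule_environment_energy,
    total_box_energy,
)


class PackingError(RuntimeError):
    """Random insertion failed; the requested density is too high."""


@dataclass
class BoxRecipe:
    """Composition of a solution box.

    Exactly one of ``box_length`` (Å) or ``density`` (g/cm³) must be given;
    the other is derived from the total molecular mass.  The default density,
    used when neither is supplied, is 1.10 g/cm³ — a realistic value for
    molar-scale aqueous glycinate solutions.
    """

    counts: dict[str, int]
    box_length: float | None = None
    density: float | None = None
    temperature: float = 298.15
    seed: int = 0

    DEFAULT_DENSITY = 1.10

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("molecule counts must be non-negative")
        if self.box_length is not None and self.density is not None:
            raise ValueError("give box_length or density, not both")

    def resolve_box_length(self, ff: ForceField) -> float:
        if self.box_length is not None:
            return float(self.box_length)
        density = self.density if self.density is not None else self.DEFAULT_DENSITY
        mass_g = sum(
            n * ff.templates[name].mass(ff) for name, n in self.counts.items()
        ) / AVOGADRO
        volume_cm3 = mass_g / density
        return float(volume_cm3 ** (1.0 / 3.0) * 1e8)  # cm -> Å


@dataclass
class MCSettings:
    """Metropolis run schedule and move sizes.

    ``frame_interval`` defaults (when left at 0) to 100 moves per molecule so
    recorded frames are decorrelated, mirroring the analysis stride used
    downstream.  ``cutoff`` of 0 means half the box length.
    """

    n_equilibration: int = 10_000
    n_production: int = 100_000
    frame_interval: int = 0
    max_translation: float = 0.15
    max_rotation: float = 0.2
    cutoff: float = 0.0

    def resolved(self, config: Configuration) -> "MCSettings":
        fi = self.frame_interval or 100 * config.n_molecules
        cut = self.cutoff or 0.5 * config.box_length
        if cut > 0.5 * config.box_length + 1e-9:
            raise ValueError("cutoff must not exceed half the box length")
        if min(self.n_equilibration, self.n_production, fi) < 0 or fi <= 0:
            raise ValueError("schedule values must be positive")
        return MCSettings(
            self.n_equilibration, self.n_production, fi,
            self.max_translation, self.max_rotation, cut,
        )


# minimum site separation enforced at insertion regardless of LJ size, Å;
# keeps zero-sigma (charged hydrogen) sites off the top of other atoms
_HARD_FLOOR = 0.8


def build_box(recipe: BoxRecipe, ff: ForceField, max_retries: int = 20_000) -> Configuration:
    """Insert molecules at random positions/orientations without overlap.

    No two sites may end up closer than 0.8·sigma_ij (Lorentz-mixed) or the
    hard floor of 0.8 Å, under minimum image.  Reproducible from the recipe
    seed.  Raises :class:`PackingError` when insertion keeps failing.
    """
    rng = np.random.default_rng(recipe.seed)
    L = recipe.resolve_box_length(recipe_ff_check(recipe, ff))
    max_extent = max(
        (ff.templates[name].extent() for name, n in recipe.counts.items() if n > 0),
        default=0.0,
    )
    if L < 2.0 * max_extent:
        raise ValueError("box shorter than twice the largest molecule extent")

    placed: list[tuple[str, tuple[str, ...], np.ndarray]] = []
    occupied_xyz: list[np.ndarray] = []
    occupied_sig: list[np.ndarray] = []

    def clashes(xyz: np.ndarray, sig: np.ndarray) -> bool:
        if not occupied_xyz:
            return False
        other = np.concatenate(occupied_xyz, axis=0)
        osig = np.concatenate(occupied_sig, axis=0)
        d = minimum_image(xyz[:, None, :] - other[None, :, :], L)
        r = np.sqrt((d ** 2).sum(axis=-1))
        dmin = np.maximum(0.8 * 0.5 * (sig[:, None] + osig[None, :]), _HARD_FLOOR)
        return bool(np.any(r < dmin))

    for name in sorted(recipe.counts, key=lambda n: -ff.templates[n].n_sites):
        tmpl = ff.templates[name]
        sig = np.array([ff.sites[l].sigma for l in tmpl.site_labels])
        for _ in range(recipe.counts[name]):
            for attempt in range(max_retries):
                rot = Rotation.random(random_state=rng) if tmpl.n_sites > 1 else None
                local = rot.apply(tmpl.local_coords) if rot else tmpl.local_coords
                # molecules stay contiguous; only the anchor site is boxed
                xyz = local + rng.uniform(0.0, L, size=3)
                xyz = xyz - L * np.floor(xyz[0] / L)
                if not clashes(xyz, sig):
                    break
            else:
                raise PackingError(
                    f"could not insert {name} after {max_retries} attempts "
                    f"(box {L:.2f} Å too dense)"
                )
            placed.append((name, tmpl.site_labels, xyz))
            occupied_xyz.append(xyz)
            occupied_sig.append(sig)

    return Configuration.from_molecules(L, recipe.temperature, placed)


def recipe_ff_check(recipe: BoxRecipe, ff: ForceField) -> ForceField:
    for name in recipe.counts:
        if name not in ff.templates:
            raise KeyError(f"no molecule template named {name!r}")
    return ff


def run_mc(
    config: Configuration,
    ff: ForceField,
    settings: MCSettings,
    seed: int,
    external: "callable | None" = None,
) -> Trajectory:
    """Sample a configuration with rigid-body Metropolis Monte Carlo.

    One move = a random rigid translation (and, for multi-site molecules, a
    rotation about the centroid) of a single uniformly chosen molecule,
    accepted with probability min(1, exp(-dE / RT)).  Site pairs beyond the
    cutoff contribute zero energy.  Frames are recorded every
    ``frame_interval`` production moves; at each recorded frame the bookkept
    running energy is checked against a full recompute (mismatch beyond 1e-6
    relative raises).

    ``external`` is an optional callable mapping a molecule's (n, 3) site
    coordinates to an external-field energy in kJ/mol; it is included in the
    Metropolis criterion and the bookkeeping.  It exists so that simple
    analytic reference systems (e.g. one particle in a double well) can be
    sampled with the very same kernel.
    """
    st = settings.resolved(config)
    rng = np.random.default_rng(seed)
    config = config.copy()
    config.wrap_molecules()
    tables = PairTables(config, ff)
    beta = 1.0 / (R_KJ_MOL_K * config.temperature)
    n_mol = config.n_molecules
    L = config.box_length

    def ext_energy(m: int, coords: np.ndarray) -> float:
        return float(external(coords)) if external is not None else 0.0

    energy = total_box_energy(config, ff, cutoff=st.cutoff, tables=tables)
    energy += sum(
        ext_energy(m, config.coords[config.mol_slice(m)]) for m in range(n_mol)
    )
    if not math.isfinite(energy):
        raise FloatingPointError("non-finite initial energy; check the packing")

    n_total = st.n_equilibration + st.n_production
    n_accept = 0
    frames: list[Configuration] = []
    iteration_index: list[int] = []
    running: list[float] = []
    recomputed: list[float] = []

    # pre-drawn random streams (molecule choice, displacement, acceptance)
    for step in range(n_total):
        m = int(rng.integers(n_mol))
        sl = config.mol_slice(m)
        old = config.coords[sl]
        new = old
        if old.shape[0] > 1:
            centroid = old.mean(axis=0)
            rot = Rotation.from_rotvec(
                rng.uniform(-st.max_rotation, st.max_rotation)
                * _random_unit(rng)
            )
            new = rot.apply(old - centroid) + centroid
        new = new + rng.uniform(-st.max_translation, st.max_translation, size=3)
        new = new - L * np.floor(new[0] / L)  # rigid wrap keeps the body whole
        e_old = molecule_environment_energy(config, m, tables, st.cutoff)
        e_new = molecule_environment_energy(
            config, m, tables, st.cutoff, coords_override=new
        )
        d_e = (e_new - e_old) + (ext_energy(m, new) - ext_energy(m, old))
        if not math.isfinite(d_e):
            raise FloatingPointError(
                f"non-finite energy change moving molecule {m} "
                f"({config.species[m]}) at step {step}"
            )
        if d_e <= 0.0 or rng.random() < math.exp(-beta * d_e):
            config.coords[sl] = new
            energy += d_e
            n_accept += 1

        prod_step = step - st.n_equilibration + 1
        if prod_step > 0 and prod_step % st.frame_interval == 0:
            frames.append(config.copy())
            iteration_index.append(prod_step)
            running.append(energy)
            full = total_box_energy(config, ff, cutoff=st.cutoff, tables=tables)
            full += sum(
                ext_energy(k, config.coords[config.mol_slice(k)])
                for k in range(n_mol)
            )
            recomputed.append(full)
            scale = max(abs(full), 1e-10)
            if abs(energy - full) / scale > 1e-6:
                raise FloatingPointError(
                    f"energy bookkeeping drift at frame {len(frames) - 1}: "
                    f"running {energy:.10g} vs recomputed {full:.10g}"
                )

    return Trajectory(
        frames=frames,
        iteration_index=iteration_index,
        acceptance_fraction=n_accept / max(n_total, 1),
        running_energies=running,
        recomputed_energies=recomputed,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_ideal_gas_frames(
    n_particles: int, box_length: float, n_frames: int, seed: int,
    temperature: float = 298.15,
) -> Trajectory:
    """Uncorrelated uniform single-site frames — the analytic g(r)=1 fixture."""
    if n_particles <= 1:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    labels = np.array(["X"] * n_particles)
    mol_start = np.arange(n_particles + 1, dtype=np.intp)
    species = ["ideal"] * n_particles
    frames = [
        Configuration(
            box_length=box_length,
            temperature=temperature,
            species=species,
            site_labels=labels,
            coords=rng.uniform(0.0, box_length, size=(n_particles, 3)),
            mol_start=mol_start,
        )
        for _ in range(n_frames)
    ]
    return Trajectory(frames=frames, iteration_index=list(range(n_frames)))
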