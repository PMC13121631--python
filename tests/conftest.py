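"""Shared fixtures: force field, sampled water box, random mixed frames."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import capsol as cs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ff() -> cs.ForceField:
    return cs.default_forcefield()


@pytest.fixture(scope="session")
def water_traj(ff) -> cs.Trajectory:
    """64 SPC/E waters at 1.0 g/cm³, equilibrated and sampled (10 frames)."""
    box = cs.build_box(cs.BoxRecipe(counts={"water": 64}, density=1.0, seed=7), ff)
    settings = cs.MCSettings(
        n_equilibration=30_000, n_production=30_000, frame_interval=3_000
    )
    return cs.run_mc(box, ff, settings, seed=7)


@pytest.fixture(scope="session")
def ideal_traj() -> cs.Trajectory:
    """Small uniform ideal-gas fixture for flat-g(r) checks."""
    return cs.make_ideal_gas_frames(200, 15.0, 50, seed=3)


def random_mixed_frame(
    ff: cs.ForceField, seed: int, n_water: int = 60, n_ion: int = 4, n_gly: int = 4,
) -> cs.Configuration:
    """A loosely packed mixed frame (not equilibrated; for oracle tests)."""
    recipe = cs.BoxRecipe(
        counts={"water": n_water, "K+": n_ion, "glycinate": n_gly},
        density=0.8, seed=seed,
    )
    return cs.build_box(recipe, ff)


def brute_force_pair_energy(frame, i, j, ffield):
    """Independent all-site-pair sum via explicit Python loops."""
    e = 0.0
    si, sj = frame.mol_slice(i), frame.mol_slice(j)
    for a in range(si.start, si.stop):
        for b in range(sj.start, sj.stop):
            sa = ffield.sites[str(frame.site_labels[a])]
            sb = ffield.sites[str(frame.site_labels[b])]
            d = frame.coords[a] - frame.coords[b]
            d = d - frame.box_length * np.round(d / frame.box_length)
            r = float(np.sqrt((d ** 2).sum()))
            sig, eps = cs.combine_lj(sa, sb)
            e += cs.pair_potential(r, sig, eps, sa.charge, sb.charge)
    return e
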