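"""Associated-pair energetics, bulk water, H-bonds, dominance, robustness."""

import numpy as np
import pytest

import capsol as cs
from capsol.energetics import (
    BinningMismatchError,
    IncompleteCutoffError,
    fit_energy_histogram,
)
from capsol.structure import RDFResult

from conftest import random_mixed_frame


def _water_pair_frame(oo: float, L: float = 30.0):
    """Two waters, O–O along x: water 0's first H points at water 1's oxygen,
    while both of water 1's hydrogens point away from water 0."""
    ff = cs.default_forcefield()
    w = ff.templates["water"]
    a = w.local_coords + 0.0
    b = w.local_coords + [oo, 0.0, 0.0]
    return cs.Configuration.from_molecules(
        L, 298.15, [("water", w.site_labels, a), ("water", w.site_labels, b)]
    )


def _brute_pairs(frame, spec):
    idx_a, idx_b = frame.select(spec.atom_type_alpha), frame.select(spec.atom_type_beta)
    out = set()
    for i in idx_a:
        for j in idx_b:
            mi, mj = int(frame.mol_index[i]), int(frame.mol_index[j])
            if mi == mj:
                continue
            d = frame.coords[i] - frame.coords[j]
            d -= frame.box_length * np.round(d / frame.box_length)
            if np.sqrt((d ** 2).sum()) <= spec.cutoff:
                out.add((min(mi, mj), max(mi, mj)))
    return sorted(out)


class TestFindAssociatedPairs:
    def test_beyond_cutoff_empty(self):
        frame = _water_pair_frame(5.0)
        assert cs.find_associated_pairs(frame, cs.AssociationSpec("OW", "OW", 3.3)) == []

    def test_within_cutoff_one_pair(self):
        frame = _water_pair_frame(3.0)
        assert cs.find_associated_pairs(frame, cs.AssociationSpec("OW", "OW", 3.3)) == [(0, 1)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_double_loop(self, ff, seed):
        frame = random_mixed_frame(ff, seed=100 + seed, n_water=45, n_ion=3, n_gly=3)
        for spec in (
            cs.AssociationSpec("OW", "OW", 3.3),
            cs.AssociationSpec("NG", "OW", 4.08),
            cs.AssociationSpec("NG", "K", 3.5),
        ):
            assert cs.find_associated_pairs(frame, spec) == _brute_pairs(frame, spec)


class TestEnergyDistribution:
    def test_identical_geometry_collapses_to_one_bin(self, ff):
        frames = [_water_pair_frame(2.9) for _ in range(5)]
        traj = cs.Trajectory(frames=frames, iteration_index=list(range(5)))
        dist = cs.pair_energy_distribution(
            traj, cs.AssociationSpec("OW", "OW", 3.3), ff
        )
        assert (dist.counts > 0).sum() == 1
        e = cs.molecule_pair_energy(frames[0], 0, 1, ff)
        assert dist.fitted_mean == pytest.approx(e, abs=0.5)  # within half a bin
        assert not dist.fit_reliable  # 5 identical pairs cannot support a fit

    def test_gaussian_seam_recovers_injected_mean(self):
        rng = np.random.default_rng(17)
        sample = rng.normal(-17.0, 4.0, size=10_000)
        dist = fit_energy_histogram(sample, bin_width=1.0)
        assert dist.fit_reliable
        assert abs(dist.fitted_mean - (-17.0)) < 3 * max(dist.fitted_mean_se, 4 / 100)

    def test_few_pairs_flagged_unreliable(self):
        dist = fit_energy_histogram(np.array([-17.0, -15.0, -19.0]), bin_width=1.0)
        assert not dist.fit_reliable
        assert dist.n_pairs_total == 3

    def test_water_hbond_energies_are_attractive(self, water_traj, ff):
        dist = cs.pair_energy_distribution(
            water_traj, cs.AssociationSpec("OW", "OW", 3.3), ff
        )
        assert dist.fitted_mean < -5.0  # hydrogen-bonded neighbours are bound
        assert dist.n_pairs_total > 100


class TestBulkWater:
    def test_pure_water_all_bulk(self, ff):
        frame = random_mixed_frame(ff, seed=55, n_water=20, n_ion=0, n_gly=0)
        assert cs.identify_bulk_water(frame, {}) == list(range(20))

    def test_water_near_ion_excluded(self, ff):
        w = ff.templates["water"]
        frame = cs.Configuration.from_molecules(
            30.0, 298.15,
            [("water", w.site_labels, w.local_coords + 0.0),
             ("water", w.site_labels, w.local_coords + [8.0, 8.0, 8.0]),
             ("Na+", ("Na",), np.array([[2.0, 0.0, 0.0]]))],
        )
        assert cs.identify_bulk_water(frame, {"Na": 3.5}) == [1]

    def test_missing_cutoff_signals(self, ff):
        frame = random_mixed_frame(ff, seed=56, n_water=10, n_ion=1, n_gly=0)
        with pytest.raises(IncompleteCutoffError):
            cs.identify_bulk_water(frame, {})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, ff, seed):
        frame = random_mixed_frame(ff, seed=200 + seed, n_water=50, n_ion=4, n_gly=4)
        cutoffs = {
            lab: 3.4
            for lab in set(frame.site_labels.tolist())
            if lab not in ("OW", "HW")
        }
        got = cs.identify_bulk_water(frame, cutoffs)
        idx_o = frame.select("OW")
        expect = []
        for o in idx_o:
            bulk = True
            for s in range(frame.n_sites):
                lab = str(frame.site_labels[s])
                if lab in ("OW", "HW"):
                    continue
                d = frame.coords[o] - frame.coords[s]
                d -= frame.box_length * np.round(d / frame.box_length)
                if np.sqrt((d ** 2).sum()) <= cutoffs[lab]:
                    bulk = False
                    break
            if bulk:
                expect.append(int(frame.mol_index[o]))
        assert got == sorted(expect)


class TestHbondDonors:
    def test_donor_with_pointed_hydrogen_included(self):
        frame = _water_pair_frame(3.0)
        # donor water 1's O sits +3.0 along x; its H at +1.0 x from its O
        # points away; water 0's H at +1.0 x points toward water 1's O
        assert cs.hbond_donors(frame, acceptor_water=1) == [0]

    def test_distant_oxygen_excluded_regardless_of_h(self):
        frame = _water_pair_frame(3.5)
        assert cs.hbond_donors(frame, acceptor_water=1) == []

    def test_close_oo_but_no_pointed_h_excluded(self):
        # water 1's hydrogens both point away from water 0's oxygen
        frame = _water_pair_frame(3.0)
        assert cs.hbond_donors(frame, acceptor_water=0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_geometric_scan(self, ff, seed):
        frame = random_mixed_frame(ff, seed=300 + seed, n_water=60, n_ion=0, n_gly=0)
        for acc in range(0, 60, 13):
            got = cs.hbond_donors(frame, acc)
            sl = frame.mol_slice(acc)
            acc_o = frame.coords[sl][0]
            expect = []
            for m in range(frame.n_molecules):
                if m == acc:
                    continue
                sm = frame.mol_slice(m)
                xyz = frame.coords[sm]
                do = xyz[0] - acc_o
                do -= frame.box_length * np.round(do / frame.box_length)
                if np.sqrt((do ** 2).sum()) > 3.29:
                    continue
                for h in (1, 2):
                    dh = xyz[h] - acc_o
                    dh -= frame.box_length * np.round(dh / frame.box_length)
                    if np.sqrt((dh ** 2).sum()) <= 2.44:
                        expect.append(m)
                        break
            assert got == expect


class TestWeightedDominance:
    def test_unloaded_amine_shell_products(self):
        # printed shell statistics: water (-14.05, 7.05), cation (-318, 0.14)
        water = cs.weighted_dominance(-14.05, 7.05)
        cation = cs.weighted_dominance(-318.0, 0.14)
        assert water == pytest.approx(-99.0525)
        assert cation == pytest.approx(-44.52)
        assert water / cation == pytest.approx(2.2, abs=0.1)

    def test_loaded_carbamate_shell_products(self):
        water = cs.weighted_dominance(-29.4, 10.1)
        cation = cs.weighted_dominance(-420.0, 0.74)
        assert water == pytest.approx(-296.94)
        assert cation == pytest.approx(-310.8)
        assert 0.9 <= water / cation <= 1.1

    def test_zero_coordination_gives_zero(self):
        assert cs.weighted_dominance(-123.4, 0.0) == 0.0

    def test_bilinear(self):
        assert cs.weighted_dominance(-3.0, 2.0) == pytest.approx(
            2 * cs.weighted_dominance(-3.0, 1.0)
        )
        assert cs.weighted_dominance(-6.0, 2.0) == pytest.approx(
            2 * cs.weighted_dominance(-3.0, 2.0)
        )


class TestCutoffSensitivity:
    def test_hard_shell_toy_is_insensitive(self, ff):
        # all pairs well below 0.9×cutoff: no pairs gained or lost, and the
        # geometry (hence energies) is unchanged -> sensitivity exactly 0
        frames = [_water_pair_frame(2.8) for _ in range(3)]
        traj = cs.Trajectory(frames=frames, iteration_index=[0, 1, 2])
        s = cs.cutoff_sensitivity(traj, cs.AssociationSpec("OW", "OW", 3.5), ff)
        assert s == 0.0

    def test_matches_finite_difference_rerun(self, water_traj, ff):
        spec = cs.AssociationSpec("OW", "OW", 3.3)
        s = cs.cutoff_sensitivity(water_traj, spec, ff, perturbation=0.10)
        base = cs.pair_energy_distribution(water_traj, spec, ff).fitted_mean
        lo = cs.pair_energy_distribution(
            water_traj, cs.AssociationSpec("OW", "OW", 3.3 * 0.9), ff
        ).fitted_mean
        hi = cs.pair_energy_distribution(
            water_traj, cs.AssociationSpec("OW", "OW", 3.3 * 1.1), ff
        ).fitted_mean
        expect = 0.5 * (abs(lo - base) + abs(hi - base)) / abs(base)
        assert s == pytest.approx(expect, rel=1e-9)


class TestCoordinationSensitivity:
    def _flat(self, rho=0.05, r_max=5.0, bw=0.03):
        n = int(round(r_max / bw))
        edges = np.linspace(0, n * bw, n + 1)
        return RDFResult(edges, np.ones(n), rho, 1, 1)

    def test_closed_form_on_flat_g(self):
        rho = 0.05
        rdf = self._flat(rho)
        triple = cs.coordination_sensitivity(rdf, 3.0, delta=0.06)
        for n, r in zip(triple, (2.94, 3.0, 3.06)):
            assert n == pytest.approx(4 / 3 * np.pi * rho * r ** 3, rel=1e-3)

    def test_zero_delta_degenerates(self):
        rdf = self._flat()
        a, b, c = cs.coordination_sensitivity(rdf, 3.0, delta=0.0)
        assert a == b == c

    def test_monotone_and_matches_direct_count(self, water_traj):
        rdf = cs.compute_rdf(water_traj, "OW", "OW", r_max=4.5)
        lo, mid, hi = cs.coordination_sensitivity(rdf, 3.3, delta=0.06)
        assert lo <= mid <= hi
        for n, r_cut in zip((lo, mid, hi), (3.24, 3.3, 3.36)):
            counts = []
            for frame in water_traj.frames:
                idx = frame.select("OW")
                d = frame.coords[idx][:, None, :] - frame.coords[idx][None, :, :]
                d -= frame.box_length * np.round(d / frame.box_length)
                r = np.sqrt((d ** 2).sum(axis=-1))
                np.fill_diagonal(r, np.inf)
                counts.append((r < r_cut).sum(axis=1).mean())
            one_bin = 4 * np.pi * rdf.rho_beta * r_cut ** 2 * rdf.bin_width
            assert abs(n - float(np.mean(counts))) <= one_bin + 1e-9


class TestGrDifference:
    def _rdf(self, g, bw=0.03):
        n = len(g)
        edges = np.linspace(0, n * bw, n + 1)
        return RDFResult(edges, np.asarray(g, dtype=float), 0.05, 1, 1)

    def test_self_difference_zero(self):
        r = self._rdf(np.linspace(0, 2, 100))
        assert cs.gr_difference(r, r) == 0.0

    def test_constant_offset_closed_form(self):
        base = np.linspace(0.5, 1.5, 200)
        c = 0.3
        r1 = self._rdf(base + c)
        r2 = self._rdf(base)
        assert cs.gr_difference(r1, r2) == pytest.approx(
            c ** 2 / np.mean(base ** 2), rel=1e-12
        )

    def test_two_seeds_small_positive_and_hand_summed(self):
        a = cs.make_ideal_gas_frames(400, 15.0, 30, seed=1)
        b = cs.make_ideal_gas_frames(400, 15.0, 30, seed=2)
        ra = cs.compute_rdf(a, "X", "X", r_max=6.0)
        rb = cs.compute_rdf(b, "X", "X", r_max=6.0)
        d = cs.gr_difference(ra, rb)
        hand = np.mean((ra.g - rb.g) ** 2) / np.mean(rb.g ** 2)
        assert d == pytest.approx(hand, rel=1e-12)
        assert 0 < d < 0.2  # sampling noise only, dominated by small-r bins

    def test_binning_mismatch_signals(self):
        with pytest.raises(BinningMismatchError):
            cs.gr_difference(self._rdf(np.ones(100)), self._rdf(np.ones(80)))
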