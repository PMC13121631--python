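"""Radial distribution functions, coordination numbers and spatial density maps.

The radial distribution function g_ab(r) measures the local number density of
atom type b around atom type a, normalised to b's bulk density, so that 1
means no correlation.  Integrating it radially gives the coordination number

    N_ab(r_min, r_max) = 4 pi rho_b  ∫ r² g_ab(r) dr ,

the mean count of b atoms in the shell.  Spatial density functions resolve the
same information in three dimensions around an *oriented* central molecule and
are summarised by isosurface levels enclosing a stated fraction of the
probability mass (e.g. the 50% most probable positions).

All distances are minimum-image in a cubic box; histograms default to 0.03 Å
bins; intramolecular pairs are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import Configuration, Trajectory, minimum_image


class SelectorError(KeyError):
    """An atom-type selector matched no sites."""


@dataclass
class RDFResult:
    """Binned g_ab(r) with the densities needed to integrate it."""

    bin_edges: np.ndarray   # (n_bins + 1,), Å, uniform
    g: np.ndarray           # (n_bins,), dimensionless
    rho_beta: float         # number density of b sites, Å^-3
    n_centers: int          # number of a sites per frame
    n_frames: int
    counts: np.ndarray = None  # raw pair counts per bin (ordered a->b pairs)

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def tail_mean(self, fraction: float = 0.1) -> float:
        """Mean of g over the last ``fraction`` of bins (flatness check)."""
        k = max(1, int(round(fraction * len(self.g))))
        return float(self.g[-k:].mean())

    def first_peak(self) -> float:
        """r at the maximum of g — the modal nearest-neighbour distance."""
        return float(self.r_mid[int(np.argmax(self.g))])

    def first_minimum(self, after: float | None = None) -> float:
        """r at the first local minimum of g beyond the first peak.

        A light smoothing (3-bin boxcar) suppresses bin noise before the
        minimum search; ``after`` overrides the start of the search window.
        """
        g = np.convolve(self.g, np.ones(3) / 3.0, mode="same")
        start = int(np.argmax(g)) if after is None else int(
            np.searchsorted(self.r_mid, after)
        )
        for i in range(start + 1, len(g) - 1):
            if g[i] <= g[i - 1] and g[i] < g[i + 1]:
                return float(self.r_mid[i])
        return float(self.r_mid[-1])


def _frame_pair_distances(
    frame: Configuration,
    idx_alpha: np.ndarray,
    idx_beta: np.ndarray,
    r_max: float,
) -> np.ndarray:
    """Minimum-image a->b distances below r_max, intramolecular pairs excluded.

    Ordered pairs: when the two selections share sites, both (i, j) and (j, i)
    are produced, which is what the per-center normalisation expects.
    """
    pos = frame.wrapped_coords()
    L = frame.box_length
    tree_a = cKDTree(pos[idx_alpha], boxsize=L)
    tree_b = cKDTree(pos[idx_beta], boxsize=L)
    coo = tree_a.sparse_distance_matrix(tree_b, r_max, output_type="coo_matrix")
    mol_a = frame.mol_index[idx_alpha][coo.row]
    mol_b = frame.mol_index[idx_beta][coo.col]
    keep = mol_a != mol_b
    return coo.data[keep]


def compute_rdf(
    traj: Trajectory,
    type_alpha: str,
    type_beta: str,
    r_max: float,
    bin_width: float = 0.03,
) -> RDFResult:
    """Histogram minimum-image a-b distances into g_ab(r).

    Normalisation: raw ordered-pair counts per bin, divided by
    n_frames * N_a * 4 pi r² dr * rho_b — the ideal-gas shell expectation per
    center.  Self pairs and intramolecular pairs are excluded.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    frame0 = traj.frames[0]
    if r_max > 0.5 * frame0.box_length + 1e-9:
        raise ValueError("r_max must not exceed half the box length")
    idx_a = frame0.select(type_alpha)
    idx_b = frame0.select(type_beta)
    if idx_a.size == 0:
        raise SelectorError(f"no sites of type {type_alpha!r}")
    if idx_b.size == 0:
        raise SelectorError(f"no sites of type {type_beta!r}")

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    for frame in traj.frames:
        d = _frame_pair_distances(frame, idx_a, idx_b, edges[-1])
        d = d[d > 1e-9]
        counts += np.histogram(d, bins=edges)[0]

    volume = frame0.box_length ** 3
    rho_beta = idx_b.size / volume
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_mid ** 2 * bin_width * rho_beta
    g = counts / (len(traj.frames) * idx_a.size * shell)
    return RDFResult(
        bin_edges=edges, g=g, rho_beta=rho_beta,
        n_centers=int(idx_a.size), n_frames=len(traj.frames), counts=counts,
    )


def coordination_number(rdf: RDFResult, r_min: float, r_max: float) -> float:
    """Shell-integrate the RDF: N = 4 pi rho_b sum r² g(r) dr (midpoint rule).

    Bins whose centers fall in [r_min, r_max) contribute.
    """
    if r_min >= r_max:
        raise ValueError("require r_min < r_max")
    if r_max > rdf.bin_edges[-1] + 1e-9 or r_min < rdf.bin_edges[0] - 1e-9:
        raise ValueError("integration window outside the binned domain")
    # midpoint rule with fractional coverage of the edge bins, so windows
    # not aligned to bin edges do not overshoot by half a bin
    lo = np.maximum(rdf.bin_edges[:-1], r_min)
    hi = np.minimum(rdf.bin_edges[1:], r_max)
    cover = np.clip(hi - lo, 0.0, None)
    return float(
        4.0 * np.pi * rdf.rho_beta * np.sum(rdf.r_mid ** 2 * rdf.g * cover)
    )


def subsample_frames(n_iterations: int, stride: int = 100) -> list[int]:
    """Decorrelation stride: indices 0, stride, 2*stride, ... below n_iterations."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    return list(range(0, n_iterations, stride))


# ---------------------------------------------------------------------------
# spatial density functions
# ---------------------------------------------------------------------------

class DegenerateFrameError(ValueError):
    """The three frame-defining sites are collinear."""


@dataclass
class VolumetricMap:
    """Probability density of a target type in a central molecule's local frame.

    ``density`` is in Å^-3 per central molecule per frame, on a cubic voxel
    grid spanning [-extent, extent] on each local axis; its integral equals
    the mean number of target sites inside the cube per central molecule.
    """

    density: np.ndarray  # (n, n, n)
    voxel: float         # Å
    extent: float        # Å
    n_central: int
    n_frames: int

    @property
    def voxel_volume(self) -> float:
        return self.voxel ** 3

    def total_mass(self) -> float:
        return float(self.density.sum() * self.voxel_volume)

    def voxel_centers_radius(self) -> np.ndarray:
        n = self.density.shape[0]
        c = -self.extent + (np.arange(n) + 0.5) * self.voxel
        xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
        return np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)

    def radial_mass(self, r_min: float, r_max: float) -> float:
        """Mass in the spherical shell [r_min, r_max) by voxel-center binning."""
        r = self.voxel_centers_radius()
        sel = (r >= r_min) & (r < r_max)
        return float(self.density[sel].sum() * self.voxel_volume)


def local_frame(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Orthonormal frame from three points by Gram–Schmidt.

    Origin at ``a``; x-axis toward ``b``; xy-plane through ``c``.  Returns a
    (3, 3) matrix whose rows are the axes.
    """
    e1 = b - a
    n1 = np.linalg.norm(e1)
    v = c - a
    if n1 < 1e-9:
        raise DegenerateFrameError("first two frame sites coincide")
    e1 = e1 / n1
    v2 = v - (v @ e1) * e1
    n2 = np.linalg.norm(v2)
    if n2 < 1e-9:
        raise DegenerateFrameError("frame-defining sites are collinear")
    e2 = v2 / n2
    return np.stack([e1, e2, np.cross(e1, e2)])


def compute_sdf(
    traj: Trajectory,
    central_species: str,
    frame_sites: tuple[str, str, str],
    target: str,
    extent: float,
    voxel: float,
) -> VolumetricMap:
    """Accumulate target positions in the central molecules' local frames.

    For every central molecule the minimum-image displacement of each target
    site from the first frame-defining site is rotated into the molecule's
    local orthonormal frame and binned on a cubic voxel grid.  Target sites
    belonging to the central molecule itself are excluded.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    frame0 = traj.frames[0]
    centrals = [m for m, s in enumerate(frame0.species) if s == central_species]
    if not centrals:
        raise SelectorError(f"no molecules of species {central_species!r}")
    idx_t_all = frame0.select(target)
    if idx_t_all.size == 0:
        raise SelectorError(f"no sites of type {target!r}")

    n = max(2, int(round(2.0 * extent / voxel)))
    hist = np.zeros((n, n, n))
    edges = np.linspace(-extent, extent, n + 1)

    for frame in traj.frames:
        pos = frame.coords
        L = frame.box_length
        for m in centrals:
            sl = frame.mol_slice(m)
            labs = frame.site_labels[sl]
            # repeated labels (e.g. water's two hydrogens) resolve to
            # successive occurrences within the molecule
            ref = []
            for k, s in enumerate(frame_sites):
                occ = frame_sites[:k].count(s)
                hits = np.flatnonzero(labs == s)
                if hits.size <= occ:
                    raise SelectorError(
                        f"species {central_species!r} lacks frame site "
                        f"occurrence {occ + 1} of {s!r}"
                    )
                ref.append(int(hits[occ]))
            a = pos[sl][ref[0]]
            b = a + minimum_image(pos[sl][ref[1]] - a, L)
            c = a + minimum_image(pos[sl][ref[2]] - a, L)
            axes = local_frame(a, b, c)
            idx_t = idx_t_all[frame.mol_index[idx_t_all] != m]
            if idx_t.size == 0:
                continue
            disp = minimum_image(pos[idx_t] - a, L)
            local = disp @ axes.T
            inside = np.all(np.abs(local) < extent, axis=1)
            if np.any(inside):
                hist += np.histogramdd(local[inside], bins=(edges, edges, edges))[0]

    density = hist / (len(traj.frames) * len(centrals) * voxel ** 3)
    return VolumetricMap(
        density=density, voxel=float(edges[1] - edges[0]), extent=extent,
        n_central=len(centrals), n_frames=len(traj.frames),
    )


def isosurface_level(vmap: VolumetricMap, probability_fraction: float = 0.5) -> float:
    """Density level whose superlevel set holds >= the given mass fraction.

    Voxels are sorted by density (descending); the returned level is the
    density of the voxel at which the cumulative mass first reaches
    ``probability_fraction`` of the total.
    """
    if not 0.0 < probability_fraction <= 1.0:
        raise ValueError("probability_fraction must be in (0, 1]")
    flat = np.sort(vmap.density.ravel())[::-1]
    total = flat.sum()
    if total <= 0:
        raise ValueError("empty volumetric map")
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, probability_fraction * total))
    return float(flat[min(k, flat.size - 1)])
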