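"""Equilibrium structural observables of planar bilayers.

Area per lipid (projected-box and periodic Voronoi routes), density profiles
along the bilayer normal, thickness from the phosphate peaks, carbon-tail
order parameters, cholesterol tilt, leaflet interdigitation, first-shell
neighbor composition and center-of-mass distance distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi

from .core_model import (
    LOWER,
    ROLE_CHOL_OH,
    ROLE_CHOL_TAIL,
    UPPER,
    BilayerTopology,
    Frame,
    LeafletAssignment,
    assign_leaflets,
    parse_tail_role,
)
from .mechanics import block_standard_error


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """1D density along z (relative to the bilayer midplane) for a selection."""

    bin_centers: np.ndarray     # nm
    density: np.ndarray         # mass (amu) or electrons per nm^3
    selection: str
    bin_width: float            # nm

    def integral_per_area(self) -> float:
        """Integral of the profile over z: total weight per unit in-plane area."""
        return float(np.sum(self.density) * self.bin_width)


@dataclass
class ThicknessResult:
    """Peak-to-peak bilayer thickness; flagged when only one peak exists."""

    thickness: float | None
    peak_positions: tuple[float, float] | None
    single_peak: bool = False


@dataclass
class OrderParameterProfile:
    """Per-carbon order parameter S_C for one species and chain."""

    carbon_index: list[int]
    s_c: np.ndarray
    species: str
    chain: int
    stderr: np.ndarray | None = None


@dataclass
class NeighborStats:
    """Mean first-shell neighbor counts per species pair."""

    mean_counts: dict[str, dict[str, float]]
    shell_definition: dict
    n_molecules: dict[str, int] = field(default_factory=dict)

    def total_neighbors(self, species: str) -> float:
        return sum(self.mean_counts.get(species, {}).values())


# ---------------------------------------------------------------------------
# Area per lipid
# ---------------------------------------------------------------------------

def area_per_lipid_box(frame: Frame, topology: BilayerTopology) -> float:
    """Projected box area divided by the molecules in one leaflet, nm^2."""
    n_upper = topology.leaflet_counts.get(UPPER, 0)
    n_lower = topology.leaflet_counts.get(LOWER, 0)
    n_per_leaflet = (n_upper + n_lower) / 2.0
    if n_per_leaflet == 0:
        raise ValueError("no molecules in the leaflets")
    return frame.area / n_per_leaflet


def periodic_voronoi_areas(
    points: np.ndarray, Lx: float, Ly: float
) -> tuple[np.ndarray, list[set[int]]]:
    """Periodic 2D Voronoi tessellation: per-seed cell areas and adjacency.

    The box is tiled 3x3, the tessellation is computed on the 9 copies and
    the cells of the central copy are read off; the per-cell areas therefore
    partition the box exactly.  Coincident seed points are jittered by
    1e-6 nm with a warning.
    """
    pts = np.asarray(points, dtype=float).copy()
    if len(pts) < 4:
        raise ValueError("periodic Voronoi needs at least 4 seed points")
    pts[:, 0] %= Lx
    pts[:, 1] %= Ly
    # deduplicate coincident seeds
    rounded = np.round(pts / 1e-9).astype(np.int64)
    _, first = np.unique(rounded, axis=0, return_index=True)
    if len(first) < len(pts):
        warnings.warn("coincident Voronoi seeds jittered by 1e-6 nm")
        rng = np.random.default_rng(0)
        dupes = np.setdiff1d(np.arange(len(pts)), first)
        pts[dupes] += rng.uniform(-1e-6, 1e-6, size=(len(dupes), 2))
    n = len(pts)
    shifts = [(0.0, 0.0)] + [
        (i * Lx, j * Ly) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)
    ]
    tiled = np.concatenate([pts + np.asarray(s) for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # order convex-cell vertices by angle about the centroid
        c = verts.mean(axis=0)
        ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
        verts = verts[np.argsort(ang)]
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    adjacency: list[set[int]] = [set() for _ in range(n)]
    for a, b in vor.ridge_points:
        ia, ib = int(a) % n, int(b) % n
        if (a < n or b < n) and ia != ib:
            adjacency[ia].add(ib)
            adjacency[ib].add(ia)
    return areas, adjacency


def area_per_lipid_voronoi(
    frame: Frame,
    topology: BilayerTopology,
    leaflet: str,
    assignment: LeafletAssignment | None = None,
) -> tuple[np.ndarray, float]:
    """Per-molecule Voronoi cell areas (nm^2) of one leaflet and their mean.

    Cells are built from the in-plane projections of each molecule's
    headgroup-like reference site under periodic boundaries; the areas sum
    to Lx*Ly exactly (partition property), so the mean matches the
    projected-box route when the leaflet holds the nominal molecule count.
    """
    if assignment is None:
        assignment = assign_leaflets(frame, topology)
    mols = assignment.molecules_in(leaflet)
    if len(mols) < 4:
        raise ValueError(f"leaflet {leaflet} has fewer than 4 molecules")
    refs = np.asarray([topology.reference_site(i) for i in mols])
    points = frame.coords[refs][:, :2]
    areas, _ = periodic_voronoi_areas(points, frame.box[0], frame.box[1])
    return areas, float(areas.mean())


# ---------------------------------------------------------------------------
# Density profiles and thickness
# ---------------------------------------------------------------------------

def density_profile(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    selection: np.ndarray | str,
    n_bins: int = 100,
    weighting: str = "mass",
    label: str | None = None,
) -> DensityProfile:
    """Frame-averaged density of a selection along z about the midplane.

    ``selection`` is an array of global site indices (see
    ``BilayerTopology.select_sites``) or a species name.  ``weighting`` is
    "mass" (amu/nm^3) or "electron" (electrons/nm^3); electron weights come
    from the per-site electron counts declared in the topology.  The z of
    every site is taken relative to the frame's phosphate midplane with the
    minimum-image convention, so the integral of the profile equals the
    selected weight per unit in-plane area.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if isinstance(selection, str):
        label = label or selection
        selection = topology.select_sites(species=selection)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    if weighting == "mass":
        weights = topology.site_masses[selection]
    elif weighting == "electron":
        weights = topology.site_electrons[selection]
    else:
        raise ValueError(f"unknown weighting: {weighting}")

    Lz = frames[0].box[2]
    edges = np.linspace(-Lz / 2, Lz / 2, n_bins + 1)
    bin_w = edges[1] - edges[0]
    acc = np.zeros(n_bins)
    for frame in frames:
        mid = assign_leaflets(frame, topology).midplane_z
        z = frame.coords[selection, 2] - mid
        z -= np.round(z / Lz) * Lz  # minimum image about the midplane
        hist, _ = np.histogram(z, bins=edges, weights=weights)
        acc += hist / (bin_w * frame.area)
    acc /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        bin_centers=centers, density=acc, selection=label or "sites", bin_width=bin_w
    )


def bilayer_thickness(profile: DensityProfile) -> ThicknessResult:
    """Distance between the two phosphate peaks of a density profile.

    The maximal bin on each side of the midplane is refined by 3-point
    parabolic interpolation; equal-height tie goes to the outermost pair.
    A single-peak (collapsed or fully interdigitated) profile is returned
    flagged rather than as a silent number.
    """
    z, d = profile.bin_centers, profile.density
    maxima = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > 0 and d[i] >= d[i - 1] and d[i] >= d[i + 1]
    ]
    lower = [i for i in maxima if z[i] < 0]
    upper = [i for i in maxima if z[i] > 0]
    if not lower or not upper:
        return ThicknessResult(thickness=None, peak_positions=None, single_peak=True)
    # highest peak per side; ties to the outermost bin
    i_lo = min((i for i in lower if d[i] == max(d[j] for j in lower)), key=lambda i: z[i])
    i_up = max((i for i in upper if d[i] == max(d[j] for j in upper)), key=lambda i: z[i])
    z_lo = _parabolic_peak(z, d, i_lo)
    z_up = _parabolic_peak(z, d, i_up)
    return ThicknessResult(thickness=float(z_up - z_lo), peak_positions=(z_lo, z_up))


def _parabolic_peak(z: np.ndarray, d: np.ndarray, i: int) -> float:
    denom = d[i - 1] - 2 * d[i] + d[i + 1]
    if denom == 0:
        return float(z[i])
    shift = 0.5 * (d[i - 1] - d[i + 1]) / denom
    return float(z[i] + shift * (z[1] - z[0]))


# ---------------------------------------------------------------------------
# Order parameters and cholesterol tilt
# ---------------------------------------------------------------------------

def order_parameters(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    species: str,
    chain: int,
) -> OrderParameterProfile:
    """Carbon order parameters S_C = <3 cos^2(theta_i) - 1> / 2 per position.

    theta_i is the angle between the molecular axis through the C_(i-1) and
    C_(i+1) carbons and the bilayer normal (global z).  Only interior
    carbons are scored — the axis is undefined at the chain ends.  Averaged
    over all molecules of the species and all frames; a 4-block standard
    error over frames is attached when at least 4 frames are given.
    """
    sp = topology.species_of(species)
    tail_sites = sp.tail_sites(chain)
    if len(tail_sites) < 3:
        raise ValueError(f"{species} chain {chain} has fewer than 3 carbons")
    site_pos = {s: k for k, s in enumerate(sp.site_labels)}
    mols = [
        i for i, name in enumerate(topology.molecule_species) if name == species
    ]
    if not mols:
        raise ValueError(f"no molecules of species {species}")
    interior = list(range(2, len(tail_sites)))  # carbon numbers 2..n-1
    per_frame = np.full((len(frames), len(interior)), np.nan)
    for fi, frame in enumerate(frames):
        sums = np.zeros(len(interior))
        counts = np.zeros(len(interior))
        for mol in mols:
            start = topology.molecule_sites(mol).start
            pos = frame.coords[start : start + sp.n_sites]
            for k, carbon in enumerate(interior):
                a = pos[site_pos[tail_sites[carbon - 2]]]
                b = pos[site_pos[tail_sites[carbon]]]
                axis = b - a
                norm = np.linalg.norm(axis)
                if norm < 1e-12:
                    warnings.warn(
                        f"coincident C{carbon - 1}/C{carbon + 1} carbons skipped"
                    )
                    continue
                cos2 = (axis[2] / norm) ** 2
                sums[k] += 0.5 * (3.0 * cos2 - 1.0)
                counts[k] += 1
        per_frame[fi] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    s_c = np.nanmean(per_frame, axis=0)
    stderr = None
    if len(frames) >= 4:
        stderr = np.array(
            [block_standard_error(per_frame[:, k], 4) for k in range(len(interior))]
        )
    return OrderParameterProfile(
        carbon_index=list(interior),  # carbon numbers 2..n-1 (1-based)
        s_c=s_c,
        species=species,
        chain=chain,
        stderr=stderr,
    )


def cholesterol_tilt(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    assignment: LeafletAssignment | None = None,
) -> np.ndarray:
    """Per-molecule cholesterol tilt angles in degrees, pooled over frames.

    The angle is between the OH-carbon -> tail-carbon axis and the leaflet
    outward normal (+z for the upper leaflet, -z for the lower), so the two
    leaflets histogram onto the same axis.
    """
    chol_mols = [
        i
        for i, name in enumerate(topology.molecule_species)
        if topology.species_of(name).is_cholesterol
    ]
    if not chol_mols:
        raise ValueError("no cholesterol species in the topology")
    angles: list[float] = []
    for frame in frames:
        asg = assignment or assign_leaflets(frame, topology)
        for mol in chol_mols:
            sp = topology.species_of(topology.molecule_species[mol])
            start = topology.molecule_sites(mol).start
            labels = sp.site_labels
            oh = frame.coords[start + labels.index(sp.sites_with_role(ROLE_CHOL_OH)[0])]
            ta = frame.coords[start + labels.index(sp.sites_with_role(ROLE_CHOL_TAIL)[0])]
            v = ta - oh
            norm = np.linalg.norm(v)
            if norm < 1e-12:
                warnings.warn(f"zero-length cholesterol axis, molecule {mol} skipped")
                continue
            ref = 1.0 if asg.labels[mol] == UPPER else -1.0
            cosang = np.clip(ref * v[2] / norm, -1.0, 1.0)
            angles.append(float(np.degrees(np.arccos(cosang))))
    return np.asarray(angles)


# ---------------------------------------------------------------------------
# Interdigitation
# ---------------------------------------------------------------------------

def interdigitation(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    assignment: LeafletAssignment | None = None,
    n_bins: int = 100,
) -> float:
    """Leaflet mass-overlap parameter lambda in [0, 1].

    lambda = integral 4 rho_u rho_l dz / integral (rho_u + rho_l)^2 dz over
    the tail-site mass-density profiles of the two leaflets: 0 for disjoint
    leaflets, 1 for identical profiles (full interdigitation).
    """
    rho = {UPPER: np.zeros(n_bins), LOWER: np.zeros(n_bins)}
    Lz = frames[0].box[2]
    edges = np.linspace(-Lz / 2, Lz / 2, n_bins + 1)
    bin_w = edges[1] - edges[0]
    tail_mask = np.asarray(
        [
            parse_tail_role(r) is not None or r == ROLE_CHOL_TAIL
            for r in topology.site_roles
        ]
    )
    for frame in frames:
        asg = assignment or assign_leaflets(frame, topology)
        for leaflet in (UPPER, LOWER):
            mols = asg.molecules_in(leaflet)
            if len(mols) == 0:
                raise ValueError(f"leaflet {leaflet} is empty")
            site_sel = np.nonzero(np.isin(topology.site_molecule, mols) & tail_mask)[0]
            z = frame.coords[site_sel, 2] - asg.midplane_z
            z -= np.round(z / Lz) * Lz
            hist, _ = np.histogram(z, bins=edges, weights=topology.site_masses[site_sel])
            rho[leaflet] += hist / (bin_w * frame.area)
    ru, rl = rho[UPPER] / len(frames), rho[LOWER] / len(frames)
    denom = float(np.sum((ru + rl) ** 2))
    if denom == 0:
        raise ValueError("no tail density found")
    return float(4.0 * np.sum(ru * rl) / denom)


# ---------------------------------------------------------------------------
# Neighbor composition and COM distances
# ---------------------------------------------------------------------------

def neighbor_composition(
    frame: Frame,
    topology: BilayerTopology,
    leaflet: str,
    shell: str | float = "voronoi",
    assignment: LeafletAssignment | None = None,
) -> NeighborStats:
    """First-shell neighbor counts per species pair within one leaflet.

    ``shell`` is "voronoi" (parameter-free periodic Voronoi adjacency of the
    headgroup projections, the default) or a float in-plane cutoff radius in
    nm.  Returns, for every species s, the mean number of first-shell
    neighbors of each species t around an s molecule.
    """
    if assignment is None:
        assignment = assign_leaflets(frame, topology)
    mols = assignment.molecules_in(leaflet)
    if len(mols) < 2:
        raise ValueError(f"leaflet {leaflet} has fewer than 2 molecules")
    names = [topology.molecule_species[i] for i in mols]
    refs = np.asarray([topology.reference_site(i) for i in mols])
    pts = frame.coords[refs][:, :2]
    Lx, Ly = frame.box[0], frame.box[1]
    if shell == "voronoi":
        _, adjacency = periodic_voronoi_areas(pts, Lx, Ly)
        shell_def = {"mode": "voronoi"}
    elif isinstance(shell, (int, float)) and shell > 0:
        dx = pts[:, None, 0] - pts[None, :, 0]
        dy = pts[:, None, 1] - pts[None, :, 1]
        dx -= np.round(dx / Lx) * Lx
        dy -= np.round(dy / Ly) * Ly
        within = (dx**2 + dy**2 <= float(shell) ** 2)
        np.fill_diagonal(within, False)
        adjacency = [set(np.nonzero(row)[0].tolist()) for row in within]
        shell_def = {"mode": "cutoff", "radius_nm": float(shell)}
    else:
        raise ValueError(f"invalid shell definition: {shell!r}")
    species_set = sorted(set(names))
    sums = {s: {t: 0.0 for t in species_set} for s in species_set}
    counts = {s: 0 for s in species_set}
    for i, s in enumerate(names):
        counts[s] += 1
        for j in adjacency[i]:
            sums[s][names[j]] += 1.0
    mean_counts = {
        s: {t: sums[s][t] / counts[s] for t in species_set} for s in species_set
    }
    return NeighborStats(
        mean_counts=mean_counts, shell_definition=shell_def, n_molecules=counts
    )


def pairwise_com_distances(
    frame: Frame,
    topology: BilayerTopology,
    site_group: str,
    species: str | None = None,
) -> np.ndarray:
    """Nearest-neighbor distances (nm) between group centers of mass.

    One center of mass per molecule carrying sites of role ``site_group``
    (e.g. "sugar_ring"), minimum-image convention in all three dimensions.
    """
    coms = []
    for i, name in enumerate(topology.molecule_species):
        if species is not None and name != species:
            continue
        sp = topology.species_of(name)
        sites = sp.sites_with_role(site_group)
        if not sites:
            continue
        start = topology.molecule_sites(i).start
        idx = np.asarray([start + sp.site_labels.index(s) for s in sites])
        m = topology.site_masses[idx]
        coms.append(np.average(frame.coords[idx], axis=0, weights=m))
    if len(coms) < 2:
        raise ValueError(f"fewer than 2 instances of group {site_group}")
    coms = np.asarray(coms)
    box = np.asarray(frame.box)
    delta = coms[:, None, :] - coms[None, :, :]
    delta -= np.round(delta / box) * box
    dist = np.sqrt((delta**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    return dist.min(axis=1)
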