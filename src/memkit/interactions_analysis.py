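"""Hydrogen-bond detection and water-penetration probability maps.

Hydrogen bonds use geometric distance-angle criteria: donor-acceptor
distance <= 0.35 nm and donor-hydrogen-acceptor angle >= 135 degrees (both
cutoffs inclusive).  Note the angle is the D-H-A angle itself — a perfectly
linear bond scores 180 degrees — which differs from the deviation-angle
convention some MD tools use.

Water penetration is reported as a per-(x, y)-bin probability of observing
at least one water site in the hydrophobic-center sub-volume during the
production run; the default 0.31 nm bin holds one water molecule at the bulk
number density of 33.36 nm^-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import (
    ROLE_WATER,
    BilayerTopology,
    Frame,
    TopologyError,
    assign_leaflets,
)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (inclusive cutoffs)."""

    max_da_distance: float = 0.35  # nm
    min_dha_angle: float = 135.0   # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.min_dha_angle <= 180.0):
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # nm
    angle: float     # degrees


@dataclass
class HBondReport:
    bonds: list[HBond]
    pair_counts: dict[tuple[str, str], int]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def detect_hbonds(
    frame: Frame,
    donors: Sequence[int],
    hydrogens: Sequence[int],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    topology: BilayerTopology | None = None,
) -> HBondReport:
    """Find hydrogen bonds among the given donor/hydrogen/acceptor sites.

    ``donors`` and ``hydrogens`` are parallel arrays pairing each hydrogen
    with its covalently bound donor.  A bond exists iff the minimum-image
    D-A distance is <= the cutoff AND the D-H-A angle is >= the cutoff.
    The search uses uniform cell lists and is exactly equivalent to an
    all-pairs scan.  With a topology, bonds are also aggregated per
    (species, species) pair (order-free keys, so the lipid-lipid table is
    symmetric by construction).
    """
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.shape != hydrogens.shape:
        raise TopologyError("every hydrogen needs exactly one parent donor")
    box = np.asarray(frame.box)
    coords = frame.coords
    cut = criteria.max_da_distance
    cos_min = np.cos(np.radians(criteria.min_dha_angle))

    pairs = _candidate_pairs(coords, box, donors, acceptors, cut)
    bonds: list[HBond] = []
    for di, acc in pairs:
        d, h, a = donors[di], hydrogens[di], acc
        if a == d or a == h:
            continue
        dv = coords[a] - coords[d]
        dv -= np.round(dv / box) * box
        dist = float(np.linalg.norm(dv))
        if dist > cut:
            continue
        hd = coords[d] - coords[h]
        hd -= np.round(hd / box) * box
        ha = coords[a] - coords[h]
        ha -= np.round(ha / box) * box
        denom = np.linalg.norm(hd) * np.linalg.norm(ha)
        if denom < 1e-12:
            continue
        cosang = float(np.dot(hd, ha) / denom)
        # D-H-A angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
        if cosang <= cos_min + 1e-12:
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            bonds.append(HBond(int(d), int(h), int(a), dist, angle))

    pair_counts: dict[tuple[str, str], int] = {}
    if topology is not None:
        for b in bonds:
            s1 = str(topology.site_species[b.donor])
            s2 = str(topology.site_species[b.acceptor])
            key = tuple(sorted((s1, s2)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return HBondReport(bonds=bonds, pair_counts=pair_counts)


def _candidate_pairs(
    coords: np.ndarray,
    box: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    cut: float,
) -> list[tuple[int, int]]:
    """Donor-index / acceptor-site candidate pairs within the cutoff, via
    uniform cell lists (falls back to all pairs when the box is too small
    for 3 cells per dimension)."""
    ncell = np.maximum((box // cut).astype(int), 1)
    if np.any(ncell < 3):
        return [(di, int(a)) for di in range(len(donors)) for a in acceptors]
    cell_of = lambda p: tuple(((p % box) / (box / ncell)).astype(int) % ncell)
    acc_cells: dict[tuple, list[int]] = {}
    for a in acceptors:
        acc_cells.setdefault(cell_of(coords[a]), []).append(int(a))
    out: list[tuple[int, int]] = []
    offsets = [
        (i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    ]
    for di, d in enumerate(donors):
        c = cell_of(coords[d])
        for off in offsets:
            key = tuple((np.asarray(c) + off) % ncell)
            for a in acc_cells.get(key, ()):
                out.append((di, a))
    return out


# ---------------------------------------------------------------------------
# Water penetration
# ---------------------------------------------------------------------------

#: Bulk water number density, nm^-3.
BULK_WATER_DENSITY = 33.36


def default_bin_size(bulk_water_density: float = BULK_WATER_DENSITY,
                     exact: bool = False) -> float:
    """Bin edge (1/density)^(1/3): the cube holding one bulk water molecule.

    Rounded to 2 decimals for reporting (0.31 nm at 33.36 nm^-3); pass
    ``exact=True`` for the unrounded value used internally.
    """
    if bulk_water_density <= 0:
        raise ValueError("water density must be positive")
    size = (1.0 / bulk_water_density) ** (1.0 / 3.0)
    return size if exact else round(size, 2)


@dataclass
class PenetrationMap:
    """Per-bin probability of observing a water in the hydrophobic center."""

    probability: np.ndarray          # (nx, ny) in [0, 1]
    bin_size: float                  # nominal, nm
    actual_bin: tuple[float, float]  # realized bin edges, nm
    slab_halfwidth: float            # nm about the midplane
    fraction_nonzero: float

    def __post_init__(self) -> None:
        assert np.all((self.probability >= 0) & (self.probability <= 1))


def water_penetration_map(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    bin_size: float = 0.31,
    slab_halfwidth: float | None = None,
) -> PenetrationMap:
    """Probability map of water in the hydrophobic center of the bilayer.

    For every (x, y) bin, the probability is the fraction of frames with at
    least one water site inside the bin x slab sub-volume; the slab is
    centered on the instantaneous midplane with half-width ``bin_size/2``
    (one cube height) by default.  ``fraction_nonzero`` is the fraction of
    the bilayer plane that ever sees a water.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    Lx, Ly = frames[0].box[0], frames[0].box[1]
    if bin_size > min(Lx, Ly):
        raise ValueError("bin_size larger than the box")
    if slab_halfwidth is None:
        slab_halfwidth = bin_size / 2.0
    waters = topology.select_sites(roles=ROLE_WATER)
    nx, ny = max(1, int(Lx // bin_size)), max(1, int(Ly // bin_size))
    bwx, bwy = Lx / nx, Ly / ny
    occupied = np.zeros((nx, ny))
    for frame in frames:
        mid = assign_leaflets(frame, topology).midplane_z
        wrapped = frame.wrapped()
        hit = np.zeros((nx, ny), dtype=bool)
        for w in waters:
            x, y, z = wrapped.coords[w]
            if abs(z - mid) <= slab_halfwidth:
                hit[min(int(x / bwx), nx - 1), min(int(y / bwy), ny - 1)] = True
        occupied += hit
    prob = occupied / len(frames)
    return PenetrationMap(
        probability=prob,
        bin_size=bin_size,
        actual_bin=(bwx, bwy),
        slab_halfwidth=slab_halfwidth,
        fraction_nonzero=float(np.count_nonzero(prob) / prob.size),
    )
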