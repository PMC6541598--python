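"""Shared fixtures: hand-built minimal topologies and frames."""

from __future__ import annotations

import numpy as np
import pytest

from memkit import BilayerTopology, Frame, LipidSpecies


def make_lipid(name: str = "LIP", n_tail: int = 3, with_phosphate: bool = True) -> LipidSpecies:
    """A minimal lipid: headgroup (+phosphate) + one chain of n_tail carbons."""
    sites = {"HEAD": "headgroup"}
    if with_phosphate:
        sites["PO4"] = "phosphate"
    for i in range(1, n_tail + 1):
        sites[f"C{i}"] = f"tail1_carbon_{i}"
    return LipidSpecies(name=name, molar_mass=700.0, role_map=sites)


def make_water() -> LipidSpecies:
    return LipidSpecies(name="W", molar_mass=18.015, role_map={"W": "water"})


def simple_topology(n_upper: int, n_lower: int, n_water: int = 0,
                    n_tail: int = 3) -> BilayerTopology:
    lip = make_lipid(n_tail=n_tail)
    species = [lip] + ([make_water()] if n_water else [])
    mols = ["LIP"] * (n_upper + n_lower) + ["W"] * n_water
    return BilayerTopology(
        species=species,
        molecule_species=mols,
        leaflet_counts={"upper": n_upper, "lower": n_lower},
    )


def symmetric_frame(topology: BilayerTopology, box=(7.0, 7.0, 12.0),
                    z_upper: float = 8.0, z_lower: float = 4.0) -> Frame:
    """Lipids on a grid: upper-leaflet heads at z_upper, lower at z_lower,
    tails pointing toward the midplane; waters parked near z=1."""
    n_upper = topology.leaflet_counts["upper"]
    coords = np.zeros((topology.n_sites, 3))
    lipid_ids = list(topology.lipid_indices())
    side = int(np.ceil(np.sqrt(max(n_upper, len(lipid_ids) - n_upper, 1))))
    for pos, mol in enumerate(lipid_ids):
        upper = pos < n_upper
        k = pos if upper else pos - n_upper
        x = (k % side + 0.5) * box[0] / side
        y = (k // side + 0.5) * box[1] / side
        head_z = z_upper if upper else z_lower
        sign = 1.0 if upper else -1.0
        sl = topology.molecule_sites(mol)
        sp = topology.species_of(topology.molecule_species[mol])
        for j, site in enumerate(sp.site_labels):
            role = sp.role_map[site]
            if role == "headgroup":
                coords[sl.start + j] = [x, y, head_z + 0.1 * sign]
            elif role == "phosphate":
                coords[sl.start + j] = [x, y, head_z]
            else:  # tail carbons, descending toward the midplane
                depth = 0.3 * (j - (1 if "PO4" in sp.site_labels else 0))
                coords[sl.start + j] = [x, y, head_z - sign * depth]
    for mol in range(topology.n_molecules):
        if topology.molecule_is_water(mol):
            sl = topology.molecule_sites(mol)
            coords[sl.start] = [0.5 + 0.01 * mol, 0.5, 1.0]
    return Frame(box=box, coords=coords)


@pytest.fixture
def ten_ten_topology() -> BilayerTopology:
    return simple_topology(10, 10)


@pytest.fixture
def ten_ten_frame(ten_ten_topology) -> Frame:
    return symmetric_frame(ten_ten_topology, z_upper=6.0, z_lower=2.0)
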