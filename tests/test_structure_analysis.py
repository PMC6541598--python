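"""Structural observables: APL, Voronoi, profiles, order parameters, overlap."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memkit import (
    BilayerTopology,
    Frame,
    GeneratorSpec,
    LipidSpecies,
    TailTiltModel,
    area_per_lipid_box,
    area_per_lipid_voronoi,
    bilayer_thickness,
    build_bilayer_configuration,
    cholesterol_tilt,
    density_profile,
    interdigitation,
    neighbor_composition,
    order_parameters,
    pairwise_com_distances,
    periodic_voronoi_areas,
)
from memkit.structure_analysis import DensityProfile

from conftest import simple_topology, symmetric_frame


# ---------------------------------------------------------------------------
# Area per lipid
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("box,n,expected", [((7.0, 7.0, 12.0), 100, 0.49),
                                            ((42.0, 42.0, 12.0), 3600, 0.49)])
def test_area_per_lipid_box_arithmetic(box, n, expected):
    top = simple_topology(n, n)
    frame = Frame(box=box, coords=np.zeros((top.n_sites, 3)) + 1.0)
    assert area_per_lipid_box(frame, top) == pytest.approx(expected)


def test_generated_system_hits_target_apl():
    spec = GeneratorSpec(seed=1, n_lipids_per_leaflet=64, target_apl=0.45)
    frames, truth = build_bilayer_configuration(spec)
    assert area_per_lipid_box(frames[0], truth.topology) == pytest.approx(
        0.45, abs=1e-9
    )


def test_square_lattice_voronoi_cells_all_equal():
    pts = np.array([(i * 0.7 + 0.35, j * 0.7 + 0.35)
                    for i in range(10) for j in range(10)])
    areas, _ = periodic_voronoi_areas(pts, 7.0, 7.0)
    assert areas == pytest.approx(np.full(100, 0.49), abs=1e-9)


def test_hexagonal_lattice_has_six_voronoi_neighbors():
    a = 1.0
    nx, ny = 6, 6
    pts = []
    for j in range(ny):
        for i in range(nx):
            pts.append(((i + 0.5 * (j % 2)) * a, j * a * np.sqrt(3) / 2))
    Lx, Ly = nx * a, ny * a * np.sqrt(3) / 2
    _, adjacency = periodic_voronoi_areas(np.array(pts), Lx, Ly)
    assert all(len(nb) == 6 for nb in adjacency)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=60))
def test_voronoi_partition_conservation(seed, n):
    rng = np.random.default_rng(seed)
    Lx, Ly = 7.0, 5.0
    pts = rng.uniform(0, [Lx, Ly], size=(n, 2))
    areas, _ = periodic_voronoi_areas(pts, Lx, Ly)
    assert abs(areas.sum() - Lx * Ly) / (Lx * Ly) < 1e-9
    assert np.all(areas > 0)


def test_voronoi_mean_matches_box_route():
    spec = GeneratorSpec(seed=2, n_lipids_per_leaflet=49)
    frames, truth = build_bilayer_configuration(spec)
    _, mean = area_per_lipid_voronoi(frames[0], truth.topology, "upper")
    assert mean == pytest.approx(area_per_lipid_box(frames[0], truth.topology),
                                 rel=1e-9)


# ---------------------------------------------------------------------------
# Density profiles and thickness
# ---------------------------------------------------------------------------

def _delta_plane_topology_frame(z_offsets, box=(5.0, 5.0, 12.0)):
    """n lipids per leaflet with phosphates exactly at midplane +- offset."""
    top = simple_topology(len(z_offsets), len(z_offsets))
    frame = symmetric_frame(top, box=box, z_upper=6.0 + z_offsets[0],
                            z_lower=6.0 - z_offsets[0])
    return top, frame


def test_delta_plane_phosphates_give_peaks_at_construction():
    top, frame = _delta_plane_topology_frame([2.0] * 16)
    prof = density_profile([frame], top, top.select_sites(roles="phosphate"),
                           n_bins=120)
    th = bilayer_thickness(prof)
    assert not th.single_peak
    assert th.thickness == pytest.approx(4.0, abs=prof.bin_width)


def test_profile_integral_conserves_selected_mass():
    spec = GeneratorSpec(seed=3, n_lipids_per_leaflet=25)
    frames, truth = build_bilayer_configuration(spec, n_frames=2)
    top = truth.topology
    sel = top.select_sites(roles="phosphate")
    prof = density_profile(frames, top, sel, n_bins=80)
    total_mass = top.site_masses[sel].sum()
    assert prof.integral_per_area() * frames[0].area == pytest.approx(
        total_mass, rel=1e-6
    )


def test_gaussian_peaks_resolved_by_parabolic_refinement():
    z = np.arange(-5.0, 5.0, 0.1) + 0.05
    d = np.exp(-((z - 1.95) ** 2) / (2 * 0.3**2)) + np.exp(
        -((z + 1.95) ** 2) / (2 * 0.3**2)
    )
    prof = DensityProfile(bin_centers=z, density=d, selection="synthetic",
                          bin_width=0.1)
    th = bilayer_thickness(prof)
    assert th.thickness == pytest.approx(3.90, abs=0.02)


def test_single_central_peak_is_flagged_not_numbered():
    z = np.arange(-5.0, 5.0, 0.1) + 0.05
    d = np.exp(-(z**2) / (2 * 0.5**2))
    th = bilayer_thickness(DensityProfile(z, d, "synthetic", 0.1))
    assert th.single_peak
    assert th.thickness is None


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (90.0, -0.5),
                                            (54.7356103, 0.0), (30.0, 0.625)])
def test_fixed_tilt_recovers_closed_form(theta, expected):
    spec = GeneratorSpec(seed=4, n_lipids_per_leaflet=16,
                         tail_tilt_model=TailTiltModel(kind="fixed",
                                                       theta_deg=theta))
    frames, truth = build_bilayer_configuration(spec)
    prof = order_parameters(frames, truth.topology, "POPC", chain=1)
    assert prof.s_c == pytest.approx(np.full(len(prof.s_c), expected), abs=1e-6)


def test_isotropic_segments_average_to_zero():
    # ~10^4 segments per carbon: SE of S_C is ~0.0045, so 0.02 is ~4.5 sigma
    spec = GeneratorSpec(seed=5, n_lipids_per_leaflet=600,
                         composition={"POPC": 1.0},
                         tail_tilt_model=TailTiltModel(kind="isotropic"))
    frames, truth = build_bilayer_configuration(spec, n_frames=9)
    prof = order_parameters(frames, truth.topology, "POPC", chain=1)
    assert np.abs(prof.s_c).max() < 0.02


def test_order_parameter_invariant_under_z_rotation_and_translation():
    spec = GeneratorSpec(seed=6, n_lipids_per_leaflet=25)
    frames, truth = build_bilayer_configuration(spec)
    base = order_parameters(frames, truth.topology, "POPC", 1).s_c
    c, s = np.cos(0.7), np.sin(0.7)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    rotated = Frame(box=frames[0].box, coords=frames[0].coords @ R.T
                    + np.array([0, 0, 3.0]))
    got = order_parameters([rotated], truth.topology, "POPC", 1).s_c
    assert got == pytest.approx(base, abs=1e-9)


def test_only_interior_carbons_are_scored():
    spec = GeneratorSpec(seed=7, n_lipids_per_leaflet=9)
    frames, truth = build_bilayer_configuration(spec)
    prof = order_parameters(frames, truth.topology, "POPC", 1)
    n_carbons = len(truth.topology.species_of("POPC").tail_sites(1))
    assert prof.carbon_index == list(range(2, n_carbons))


# ---------------------------------------------------------------------------
# Cholesterol tilt
# ---------------------------------------------------------------------------

def _two_chol_system(axis_upper, axis_lower):
    chol = LipidSpecies("CHOL", 386.65, {"OHC": "chol_oh_carbon",
                                         "TAC": "chol_tail_carbon"})
    top = BilayerTopology([chol], ["CHOL", "CHOL"], {"upper": 1, "lower": 1})
    coords = np.array([
        [2.0, 2.0, 7.0], np.array([2.0, 2.0, 7.0]) + axis_upper,
        [2.0, 2.0, 3.0], np.array([2.0, 2.0, 3.0]) + axis_lower,
    ])
    return top, Frame(box=(5.0, 5.0, 10.0), coords=coords)


def test_leaflet_aware_tilt_signs():
    # lower-leaflet axis along -z scores 0 degrees; in-plane axis scores 90
    top, frame = _two_chol_system(np.array([0.9, 0, 0]), np.array([0, 0, -0.9]))
    angles = cholesterol_tilt([frame], top)
    assert sorted(angles) == pytest.approx([0.0, 90.0], abs=1e-9)


def test_generated_tilt_spread_is_recovered():
    spec = GeneratorSpec(seed=8, chol_tilt_sigma=10.0, n_lipids_per_leaflet=100)
    frames, truth = build_bilayer_configuration(spec, n_frames=4)
    tilts = cholesterol_tilt(frames, truth.topology)
    assert np.std(tilts, ddof=1) == pytest.approx(10.0, abs=1.5)


# ---------------------------------------------------------------------------
# Interdigitation
# ---------------------------------------------------------------------------

def _overlap_fixture(upper_tail_z, lower_tail_z, Lz=10.0):
    """One-carbon lipids: heads fix the leaflets, tails placed explicitly."""
    lip = LipidSpecies("TL", 100.0, {"HEAD": "headgroup", "PO4": "phosphate",
                                     "C1": "tail1_carbon_1"})
    n_u, n_l = len(upper_tail_z), len(lower_tail_z)
    top = BilayerTopology([lip], ["TL"] * (n_u + n_l),
                          {"upper": n_u, "lower": n_l})
    coords = []
    for k, tz in enumerate(upper_tail_z):
        x = 0.3 + 0.1 * k
        coords += [[x, 1.0, 8.1], [x, 1.0, 8.0], [x, 1.0, tz]]
    for k, tz in enumerate(lower_tail_z):
        x = 0.3 + 0.1 * k
        coords += [[x, 1.0, 1.9], [x, 1.0, 2.0], [x, 1.0, tz]]
    return top, Frame(box=(5.0, 5.0, Lz), coords=np.array(coords))


def test_disjoint_leaflets_have_zero_overlap():
    top, frame = _overlap_fixture([6.0 + 0.1 * k for k in range(10)],
                                  [3.0 - 0.1 * k for k in range(10)])
    assert interdigitation([frame], top, n_bins=100) == pytest.approx(0.0)


def test_identical_profiles_give_full_overlap():
    zs = [4.55 + 0.1 * k for k in range(10)]
    top, frame = _overlap_fixture(zs, zs)
    assert interdigitation([frame], top, n_bins=100) == pytest.approx(1.0)


def test_half_overlapping_rectangles_match_hand_integral():
    # upper tails uniform on [5.05, 5.95], lower on [4.55, 5.45] (bin 0.1):
    # 5 bins lower-only, 5 bins shared, 5 bins upper-only
    # lambda = 4*5 / (5 + 4*5 + 5) = 2/3 by direct integration
    upper = [5.05 + 0.1 * k for k in range(10)]
    lower = [4.55 + 0.1 * k for k in range(10)]
    top, frame = _overlap_fixture(upper, lower)
    assert interdigitation([frame], top, n_bins=100) == pytest.approx(2.0 / 3.0,
                                                                      abs=1e-9)


def test_overlap_invariant_under_leaflet_exchange():
    upper = [5.05 + 0.1 * k for k in range(10)]
    lower = [4.55 + 0.1 * k for k in range(10)]
    top, f1 = _overlap_fixture(upper, lower)
    top2, f2 = _overlap_fixture([10.0 - z for z in lower],
                                [10.0 - z for z in upper])
    lam1 = interdigitation([f1], top)
    lam2 = interdigitation([f2], top2)
    assert lam1 == pytest.approx(lam2, abs=1e-9)


# ---------------------------------------------------------------------------
# Neighbors and COM distances
# ---------------------------------------------------------------------------

def test_hexagonal_single_species_has_six_same_neighbors():
    a = 0.8
    nx, ny = 6, 6
    lipids = nx * ny
    top = simple_topology(lipids, lipids)
    frame = symmetric_frame(top, box=(nx * a, ny * a * np.sqrt(3) / 2, 12.0))
    coords = frame.coords.copy()
    k = 0
    for j in range(ny):
        for i in range(nx):
            mol = k
            sl = top.molecule_sites(mol)
            x, y = (i + 0.5 * (j % 2)) * a, j * a * np.sqrt(3) / 2
            coords[sl, 0], coords[sl, 1] = x, y
            k += 1
    stats = neighbor_composition(Frame(box=frame.box, coords=coords), top, "upper")
    assert stats.mean_counts["LIP"]["LIP"] == pytest.approx(6.0)


def test_alternating_columns_have_two_same_neighbors_in_cutoff_shell():
    # two species in alternating columns of a square lattice: the 4-neighbor
    # cutoff shell holds 2 same-species (up/down) and 2 cross (left/right)
    a = 1.0
    n = 6
    spA = LipidSpecies("A", 700.0, {"HEAD": "headgroup", "PO4": "phosphate",
                                    "C1": "tail1_carbon_1"})
    spB = LipidSpecies("B", 700.0, {"HEAD": "headgroup", "PO4": "phosphate",
                                    "C1": "tail1_carbon_1"})
    names = [("A" if i % 2 == 0 else "B") for i in range(n) for _ in range(n)]
    top = BilayerTopology([spA, spB], names + names,
                          {"upper": n * n, "lower": n * n})
    coords = np.zeros((top.n_sites, 3))
    for mol in range(2 * n * n):
        upper = mol < n * n
        k = mol if upper else mol - n * n
        i, j = k // n, k % n
        sl = top.molecule_sites(mol)
        coords[sl, 0], coords[sl, 1] = i * a, j * a
        coords[sl, 2] = [8.1, 8.0, 7.0] if upper else [1.9, 2.0, 3.0]
    frame = Frame(box=(n * a, n * a, 10.0), coords=coords)
    stats = neighbor_composition(frame, top, "upper", shell=1.2)
    assert stats.mean_counts["A"]["A"] == pytest.approx(2.0)
    assert stats.mean_counts["A"]["B"] == pytest.approx(2.0)


def test_random_binary_mixture_matches_well_mixed_null():
    # Voronoi shell averages 6 neighbors; with fraction f of species X the
    # expected X-around-X count is ~6f
    rng = np.random.default_rng(12)
    n, f = 400, 0.5
    spA = LipidSpecies("A", 700.0, {"HEAD": "headgroup", "PO4": "phosphate",
                                    "C1": "tail1_carbon_1"})
    spB = LipidSpecies("B", 700.0, {"HEAD": "headgroup", "PO4": "phosphate",
                                    "C1": "tail1_carbon_1"})
    names = ["A" if rng.random() < f else "B" for _ in range(n)]
    top = BilayerTopology([spA, spB], names + ["B"] * n, {"upper": n, "lower": n})
    L = np.sqrt(n * 0.6)
    coords = np.zeros((top.n_sites, 3))
    side = int(np.ceil(np.sqrt(n)))
    for mol in range(n):
        i, j = mol // side, mol % side
        x = (i + 0.5) * L / side + rng.uniform(-0.1, 0.1)
        y = (j + 0.5) * L / side + rng.uniform(-0.1, 0.1)
        sl = top.molecule_sites(mol)
        coords[sl, 0], coords[sl, 1] = x, y
        coords[sl, 2] = [8.1, 8.0, 7.0]
    for mol in range(n, 2 * n):
        sl = top.molecule_sites(mol)
        coords[sl, 0], coords[sl, 1] = rng.uniform(0, L, 2)
        coords[sl, 2] = [1.9, 2.0, 3.0]
    frame = Frame(box=(L, L, 10.0), coords=coords)
    stats = neighbor_composition(frame, top, "upper")
    fA = names.count("A") / n
    assert stats.mean_counts["A"]["A"] == pytest.approx(6 * fA, abs=0.5)


def test_com_distances_construction_and_minimum_image():
    sug = LipidSpecies("G", 700.0, {"HEAD": "headgroup", "SUG": "sugar_ring",
                                    "C1": "tail1_carbon_1"})
    top = BilayerTopology([sug], ["G", "G"], {"upper": 2, "lower": 0})
    coords = np.zeros((6, 3))
    coords[1] = [0.1, 1.0, 5.0]   # SUG of molecule 0
    coords[4] = [6.9, 1.0, 5.0]   # SUG of molecule 1, across the boundary
    frame = Frame(box=(7.0, 7.0, 10.0), coords=coords)
    d = pairwise_com_distances(frame, top, "sugar_ring")
    assert d == pytest.approx([0.2, 0.2], abs=1e-12)


def test_planted_sugar_spacing_is_modal_distance():
    sug = LipidSpecies("G", 700.0, {"HEAD": "headgroup", "SUG": "sugar_ring",
                                    "C1": "tail1_carbon_1"})
    n = 16
    top = BilayerTopology([sug], ["G"] * n, {"upper": n, "lower": 0})
    coords = np.zeros((top.n_sites, 3))
    for mol in range(n):
        i, j = mol // 4, mol % 4
        sl = top.molecule_sites(mol)
        coords[sl.start + 1] = [i * 0.6, j * 0.6, 5.0]
    frame = Frame(box=(2.4, 2.4, 10.0), coords=coords)
    d = pairwise_com_distances(frame, top, "sugar_ring")
    assert d == pytest.approx(np.full(n, 0.6), abs=1e-12)
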