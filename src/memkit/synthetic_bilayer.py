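"""Synthetic bilayer configurations and ensembles with known ground truth.

The generator does not run any dynamics.  It draws configurations and scalar
time series whose *statistics* are prescribed: equilibrium area fluctuations
with variance k_B*T*<A>/K_A, linear tension-strain response with Gaussian
noise, tail-segment orientations from a chosen tilt model, cholesterol axes
with a chosen angular spread, planted donor-H-acceptor geometries, leaflet
tail overlap, and planted water-penetration events.  Every generated
observable is therefore recoverable by exactly one analysis operation, which
is what makes the estimators testable without molecular dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_model import (
    KB,
    LOWER,
    ROLE_CHOL_OH,
    ROLE_CHOL_TAIL,
    ROLE_GLYCEROL,
    ROLE_HEADGROUP,
    ROLE_PHOSPHATE,
    ROLE_SUGAR,
    ROLE_WATER,
    UPPER,
    BilayerTopology,
    Frame,
    LipidSpecies,
    ScalarEnsemble,
    save_topology,
    write_configuration,
    write_scalar_csv,
)


class GeneratorError(ValueError):
    """The generator spec is invalid or geometrically infeasible."""


# ---------------------------------------------------------------------------
# Species table
# ---------------------------------------------------------------------------
# Formula masses (g/mol) of the species as modelled here:
#   POPC  C42H82NO8P, POPE C39H76NO8P, CHOL C27H46O,
#   SM    palmitoyl-sphingomyelin C39H79N2O6P,
#   GalCer beta-D-galactosylceramide d18:1/16:0 C40H77NO8.
DEFAULT_MOLAR_MASSES: dict[str, float] = {
    "POPC": 760.08,
    "POPE": 718.00,
    "CHOL": 386.65,
    "SM": 703.03,
    "GalCer": 700.05,
    "W": 18.015,
}

#: Canonical species order, used to break rounding ties deterministically.
SPECIES_ORDER = ["POPC", "POPE", "CHOL", "SM", "GalCer", "W"]

N_TAIL_CARBONS = 6  # carbons per chain in the simplified lipid geometry


def _phospholipid_sites(with_sugar: bool, with_phosphate: bool) -> dict[str, str]:
    sites: dict[str, str] = {"HEAD": ROLE_HEADGROUP}
    if with_sugar:
        sites["SUG"] = ROLE_SUGAR
    if with_phosphate:
        sites["PO4"] = ROLE_PHOSPHATE
    sites["GLY"] = ROLE_GLYCEROL
    for chain in (1, 2):
        for i in range(1, N_TAIL_CARBONS + 1):
            sites[f"C{chain}{i}"] = f"tail{chain}_carbon_{i}"
    return sites


def default_species() -> dict[str, LipidSpecies]:
    """Simplified multi-site species used by the generator.

    Each lipid carries a headgroup site, a phosphate (or sugar ring for the
    cerebroside), a backbone site and two chains of 6 tail carbons;
    cholesterol is a two-site axis (OH-bearing carbon and tail carbon);
    water is a single site.
    """
    return {
        "POPC": LipidSpecies("POPC", DEFAULT_MOLAR_MASSES["POPC"],
                             _phospholipid_sites(False, True)),
        "POPE": LipidSpecies("POPE", DEFAULT_MOLAR_MASSES["POPE"],
                             _phospholipid_sites(False, True)),
        "SM": LipidSpecies("SM", DEFAULT_MOLAR_MASSES["SM"],
                           _phospholipid_sites(False, True)),
        "GalCer": LipidSpecies("GalCer", DEFAULT_MOLAR_MASSES["GalCer"],
                               _phospholipid_sites(True, False)),
        "CHOL": LipidSpecies("CHOL", DEFAULT_MOLAR_MASSES["CHOL"],
                             {"OHC": ROLE_CHOL_OH, "TAC": ROLE_CHOL_TAIL}),
        "W": LipidSpecies("W", DEFAULT_MOLAR_MASSES["W"], {"W": ROLE_WATER}),
    }


# ---------------------------------------------------------------------------
# Composition accounting
# ---------------------------------------------------------------------------

def mole_to_weight_fractions(
    composition: dict[str, float], masses: dict[str, float] | None = None
) -> dict[str, float]:
    """Convert mole fractions to weight fractions: w_i = x_i M_i / sum_j x_j M_j."""
    if masses is None:
        masses = DEFAULT_MOLAR_MASSES
    missing = [s for s in composition if s not in masses]
    if missing:
        raise GeneratorError(f"no molar mass for species: {missing}")
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise GeneratorError("mole fractions must sum to 1")
    if any(masses[s] <= 0 for s in composition):
        raise GeneratorError("molar masses must be positive")
    total = sum(x * masses[s] for s, x in composition.items())
    return {s: x * masses[s] / total for s, x in composition.items()}


def counts_from_mole_fractions(composition: dict[str, float], n: int) -> dict[str, int]:
    """Integer per-species counts by largest-remainder rounding.

    Ties in the fractional remainder go to the species earliest in the
    canonical order (``SPECIES_ORDER``, then declaration order).
    """
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise GeneratorError("mole fractions must sum to 1")
    order = {name: i for i, name in enumerate(SPECIES_ORDER)}
    names = sorted(composition, key=lambda s: order.get(s, len(order)))
    floors = {s: int(math.floor(composition[s] * n)) for s in names}
    remainder = n - sum(floors.values())
    by_frac = sorted(
        names, key=lambda s: (-(composition[s] * n - floors[s]), names.index(s))
    )
    for s in by_frac[:remainder]:
        floors[s] += 1
    return {s: c for s, c in floors.items() if c > 0}


# ---------------------------------------------------------------------------
# Generator spec
# ---------------------------------------------------------------------------

@dataclass
class TailTiltModel:
    """Orientation model for tail segments.

    kind:
        "fixed"    — every segment at polar angle ``theta_deg`` from the
                     membrane-inward axis (straight rods);
        "gaussian" — per-segment polar angle drawn N(mu_deg, sigma_deg),
                     clipped to [0, 90];
        "isotropic"— per-segment direction uniform on the sphere.
    """

    kind: str = "gaussian"
    theta_deg: float = 0.0
    mu_deg: float = 25.0
    sigma_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gaussian", "isotropic"):
            raise GeneratorError(f"unknown tail tilt model: {self.kind}")


@dataclass
class GeneratorSpec:
    """All generative parameters of a synthetic bilayer; the ground truth.

    Defaults describe a cholesterol-containing reference membrane at 37 C:
    ~200 lipid and cholesterol molecules (100 per leaflet), area per lipid
    0.49 nm^2 (7x7 nm box), thickness 4.0 nm, area compressibility modulus
    457 mN/m.
    """

    seed: int
    composition: dict[str, float] = field(
        default_factory=lambda: {"POPC": 0.35, "POPE": 0.35, "CHOL": 0.30}
    )
    n_lipids_per_leaflet: int = 100
    target_apl: float = 0.49            # nm^2
    target_thickness: float = 4.0       # nm
    tail_tilt_model: TailTiltModel = field(default_factory=TailTiltModel)
    chol_tilt_sigma: float = 10.0       # degrees
    chol_tilt_mean: float = 20.0        # degrees
    K_A_true: float = 457.0             # mN/m
    temperature: float = 310.0          # K
    water_penetration_prob: float = 0.0
    interdigitation_depth: float = 0.0  # nm, tail overshoot past the midplane
    n_waters: int | None = None         # default: 4 per lipid

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GeneratorError("a seed is mandatory (no implicit entropy)")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise GeneratorError("composition mole fractions must sum to 1")
        if self.target_apl <= 0 or self.target_thickness <= 0:
            raise GeneratorError("target_apl and target_thickness must be positive")
        if not (0.0 <= self.water_penetration_prob <= 1.0):
            raise GeneratorError("water_penetration_prob must lie in [0, 1]")
        if self.n_lipids_per_leaflet < 1:
            raise GeneratorError("need at least one lipid per leaflet")
        if isinstance(self.tail_tilt_model, dict):
            self.tail_tilt_model = TailTiltModel(**self.tail_tilt_model)


@dataclass
class GroundTruth:
    """Everything the generator knows: spec parameters plus realized labels."""

    spec: GeneratorSpec
    topology: BilayerTopology
    leaflet_labels: list[str | None]
    box: tuple[float, float, float]
    midplane_z: float
    chol_tilt_deg: list[float]
    planted_water_bins: list[list[tuple[int, int]]]
    penetration_bin_size: float

    def to_json_dict(self) -> dict:
        d = asdict(self.spec)
        d["tail_tilt_model"] = asdict(self.spec.tail_tilt_model)
        return {
            "spec": d,
            "leaflet_labels": self.leaflet_labels,
            "box": list(self.box),
            "midplane_z": self.midplane_z,
            "chol_tilt_deg": self.chol_tilt_deg,
            "planted_water_bins": [
                [list(b) for b in frame] for frame in self.planted_water_bins
            ],
            "penetration_bin_size": self.penetration_bin_size,
            "molecule_species": self.topology.molecule_species,
        }


# ---------------------------------------------------------------------------
# Configuration builder
# ---------------------------------------------------------------------------

MIN_APL = 0.10          # nm^2, below this the site footprint cannot fit
PENETRATION_BIN = 0.31  # nm, one bulk-water cube (see interactions_analysis)
WATER_PAD = 3.0         # nm of water slab on each side of the bilayer


def build_bilayer_configuration(
    spec: GeneratorSpec, n_frames: int = 1
) -> tuple[list[Frame], GroundTruth]:
    """Build a jittered-lattice bilayer with prescribed statistics.

    Two leaflets of simplified multi-site lipids are placed on a jittered
    square lattice; the box area is ``n_lipids_per_leaflet * target_apl``;
    phosphate planes sit at +-target_thickness/2 about the midplane; tail
    orientations follow ``tail_tilt_model``; cholesterol axes are drawn with
    spread ``chol_tilt_sigma`` about the leaflet outward normal; waters fill
    the slabs outside the bilayer and penetration events are planted per
    (x, y) bin with probability ``water_penetration_prob`` per frame.
    Bit-reproducible for a fixed seed.
    """
    if spec.target_apl < MIN_APL:
        raise GeneratorError(
            f"target_apl {spec.target_apl} nm^2 is below the site footprint {MIN_APL}"
        )
    rng = np.random.default_rng(spec.seed)
    species = default_species()
    n = spec.n_lipids_per_leaflet
    L = math.sqrt(n * spec.target_apl)
    Lz = spec.target_thickness + 2 * WATER_PAD
    z0 = Lz / 2.0
    half_t = spec.target_thickness / 2.0

    counts = counts_from_mole_fractions(spec.composition, n)
    # molecule order: upper leaflet, then lower, then waters (core_model convention)
    leaflet_species: dict[str, list[str]] = {}
    for leaflet in (UPPER, LOWER):
        pool = [s for s, c in counts.items() for _ in range(c)]
        leaflet_species[leaflet] = [pool[i] for i in rng.permutation(len(pool))]

    n_waters = spec.n_waters if spec.n_waters is not None else 4 * n
    # penetration grid and per-frame planted events (decided up front so the
    # total site count is constant across frames)
    nx = max(1, int(L // PENETRATION_BIN))
    bin_w = L / nx
    planted: list[list[tuple[int, int]]] = []
    for _ in range(n_frames):
        hits = np.nonzero(rng.random((nx, nx)) < spec.water_penetration_prob)
        planted.append(list(zip(hits[0].tolist(), hits[1].tolist())))
    n_pool = max((len(p) for p in planted), default=0)

    molecule_species = leaflet_species[UPPER] + leaflet_species[LOWER]
    leaflet_labels: list[str | None] = [UPPER] * n + [LOWER] * n
    molecule_species += ["W"] * (n_waters + n_pool)
    leaflet_labels += [None] * (n_waters + n_pool)

    topology = BilayerTopology(
        species=[species[s] for s in SPECIES_ORDER if s in set(molecule_species)],
        molecule_species=molecule_species,
        leaflet_counts={UPPER: n, LOWER: n},
        composition=dict(spec.composition),
    )

    # lattice (shared across frames; jitter redrawn per frame)
    side = math.ceil(math.sqrt(n))
    spacing = L / side
    grid = np.array(
        [((i + 0.5) * spacing, (j + 0.5) * spacing) for i in range(side) for j in range(side)]
    )[:n]

    frames: list[Frame] = []
    chol_tilts: list[float] = []
    for f in range(n_frames):
        coords = np.zeros((topology.n_sites, 3))
        for leaflet, sign, mol_offset in ((UPPER, 1.0, 0), (LOWER, -1.0, n)):
            xy = grid + rng.uniform(-0.12, 0.12, size=grid.shape) * spacing
            for k in range(n):
                mol = mol_offset + k
                name = molecule_species[mol]
                sp = species[name]
                sl = topology.molecule_sites(mol)
                base = np.array([xy[k, 0] % L, xy[k, 1] % L])
                if sp.is_cholesterol:
                    tilt = float(
                        np.clip(rng.normal(spec.chol_tilt_mean, spec.chol_tilt_sigma),
                                0.0, 89.0)
                    )
                    chol_tilts.append(tilt)
                    coords[sl] = _place_cholesterol(
                        base, z0, sign, half_t, tilt, rng
                    )
                else:
                    coords[sl] = _place_lipid(
                        sp, base, z0, sign, half_t, spec, rng
                    )
        # bulk waters
        w_start = topology.molecule_sites(2 * n).start
        zs_low = rng.uniform(0.3, z0 - half_t - 0.3, size=n_waters)
        zs_high = rng.uniform(z0 + half_t + 0.3, Lz - 0.3, size=n_waters)
        pick_high = rng.random(n_waters) < 0.5
        wz = np.where(pick_high, zs_high, zs_low)
        coords[w_start : w_start + n_waters, 0] = rng.uniform(0, L, n_waters)
        coords[w_start : w_start + n_waters, 1] = rng.uniform(0, L, n_waters)
        coords[w_start : w_start + n_waters, 2] = wz
        # penetration pool: planted events at the midplane, the rest parked in bulk
        pool_start = w_start + n_waters
        events = planted[f]
        for p in range(n_pool):
            if p < len(events):
                i, j = events[p]
                coords[pool_start + p] = [
                    (i + rng.uniform(0.25, 0.75)) * bin_w,
                    (j + rng.uniform(0.25, 0.75)) * bin_w,
                    z0 + rng.uniform(-0.4, 0.4) * (PENETRATION_BIN / 2),
                ]
            else:
                coords[pool_start + p] = [
                    rng.uniform(0, L), rng.uniform(0, L), rng.uniform(0.3, 0.6)
                ]
        frames.append(Frame(box=(L, L, Lz), coords=coords, time=float(f),
                            temperature=spec.temperature))

    truth = GroundTruth(
        spec=spec,
        topology=topology,
        leaflet_labels=leaflet_labels,
        box=(L, L, Lz),
        midplane_z=z0,
        chol_tilt_deg=chol_tilts,
        planted_water_bins=planted,
        penetration_bin_size=bin_w,
    )
    return frames, truth


def _tilt_direction(sign: float, polar_deg: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``polar_deg`` from the membrane-inward axis (-sign * z)."""
    th = math.radians(polar_deg)
    return np.array(
        [math.sin(th) * math.cos(azimuth), math.sin(th) * math.sin(azimuth),
         -sign * math.cos(th)]
    )


def _place_lipid(
    sp: LipidSpecies,
    base: np.ndarray,
    z0: float,
    sign: float,
    half_t: float,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coordinates for one multi-site lipid (head/phosphate/backbone/tails)."""
    zp = z0 + sign * half_t  # phosphate plane
    pos: dict[str, np.ndarray] = {}
    pos["HEAD"] = np.array([base[0], base[1], zp + sign * 0.15])
    if "SUG" in sp.site_labels:
        pos["SUG"] = np.array([base[0] + 0.05, base[1], zp + sign * 0.05])
    if "PO4" in sp.site_labels:
        pos["PO4"] = np.array([base[0], base[1], zp])
    gly = np.array([base[0], base[1], zp - sign * 0.35])
    pos["GLY"] = gly

    model = spec.tail_tilt_model
    # z-extent the tails should cover; interdigitation pushes ends past the midplane
    z_extent = max(half_t - 0.50 + spec.interdigitation_depth, 0.05)
    n_seg = N_TAIL_CARBONS - 1
    for chain in (1, 2):
        offset = np.array([0.15 if chain == 1 else -0.15, 0.0, 0.0])
        start = gly + offset
        if model.kind == "fixed":
            azim = rng.uniform(0, 2 * math.pi)
            step = _tilt_direction(sign, model.theta_deg, azim)
            b = z_extent / (n_seg * max(math.cos(math.radians(model.theta_deg)), 0.05))
            steps = [b * step] * n_seg
        elif model.kind == "gaussian":
            cos_mu = max(math.cos(math.radians(model.mu_deg)), 0.05)
            b = z_extent / (n_seg * cos_mu)
            steps = [
                b * _tilt_direction(
                    sign,
                    float(np.clip(rng.normal(model.mu_deg, model.sigma_deg), 0, 90)),
                    rng.uniform(0, 2 * math.pi),
                )
                for _ in range(n_seg)
            ]
        else:  # isotropic: uniform on the sphere, random-walk chain
            b = 0.125
            steps = []
            for _ in range(n_seg):
                u = rng.uniform(-1, 1)
                phi = rng.uniform(0, 2 * math.pi)
                s = math.sqrt(1 - u * u)
                steps.append(b * np.array([s * math.cos(phi), s * math.sin(phi), u]))
        p = start.copy()
        for i in range(1, N_TAIL_CARBONS + 1):
            pos[f"C{chain}{i}"] = p.copy()
            if i <= n_seg:
                p = p + steps[i - 1]
    return np.array([pos[s] for s in sp.site_labels])


def _place_cholesterol(
    base: np.ndarray,
    z0: float,
    sign: float,
    half_t: float,
    tilt_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-site cholesterol: OH carbon deep in the leaflet, axis of length
    0.9 nm at ``tilt_deg`` from the leaflet outward normal (+z upper, -z lower)."""
    oh_depth = max(half_t - 1.2, 0.3)
    oh = np.array([base[0], base[1], z0 + sign * oh_depth])
    azim = rng.uniform(0, 2 * math.pi)
    th = math.radians(tilt_deg)
    axis = np.array(
        [math.sin(th) * math.cos(azim), math.sin(th) * math.sin(azim),
         sign * math.cos(th)]
    )
    tail = oh + 0.9 * axis
    return np.array([oh, tail])


# ---------------------------------------------------------------------------
# Scalar ensembles
# ---------------------------------------------------------------------------

def area_fluctuation_variance(
    K_A_true: float, mean_area: float, temperature: float
) -> float:
    """Equilibrium variance of the projected area, nm^4.

    var(A) = k_B * T * <A> / K_A with <A> in nm^2 and K_A in mN/m.
    """
    if K_A_true <= 0 or mean_area <= 0 or temperature <= 0:
        raise GeneratorError("K_A, mean area and temperature must be positive")
    return KB * temperature * (mean_area * 1e-18) / (K_A_true * 1e-3) * 1e36


def generate_area_series(
    K_A_true: float,
    mean_area: float,
    temperature: float,
    n: int,
    seed: int,
    ar1_phi: float | None = None,
) -> ScalarEnsemble:
    """Equilibrium projected-area series with the fluctuation statistics of a
    membrane of modulus ``K_A_true`` (mN/m) at ``temperature`` (K).

    Samples are i.i.d. Gaussian with mean ``mean_area`` (nm^2) and variance
    k_B*T*<A>/K_A.  The optional AR(1) mode (``ar1_phi`` in (0, 1)) produces
    a correlated series with the same stationary mean and variance, for
    stressing block-error estimators.
    """
    if n < 100:
        raise GeneratorError("need n >= 100 samples for a meaningful ensemble")
    var = area_fluctuation_variance(K_A_true, mean_area, temperature)
    rng = np.random.default_rng(seed)
    sd = math.sqrt(var)
    if ar1_phi is None:
        values = rng.normal(mean_area, sd, size=n)
    else:
        if not (0 < ar1_phi < 1):
            raise GeneratorError("ar1_phi must lie in (0, 1)")
        innov_sd = sd * math.sqrt(1 - ar1_phi**2)
        values = np.empty(n)
        values[0] = rng.normal(0.0, sd)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            values[i] = ar1_phi * values[i - 1] + eps[i - 1]
        values += mean_area
    return ScalarEnsemble(values=values, quantity="area", temperature=temperature)


def generate_tension_strain_series(
    K_A_true: float,
    strain_grid: Sequence[float],
    noise_sd: float,
    n_per_point: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear tension-strain response gamma = K_A * eps + N(0, noise_sd).

    Returns parallel arrays (strains, tensions) with ``n_per_point`` noisy
    tension samples at every strain of the grid; tensions in mN/m.
    """
    strain_grid = np.asarray(list(strain_grid), dtype=float)
    if strain_grid.size == 0:
        raise GeneratorError("strain grid is empty")
    if n_per_point < 1:
        raise GeneratorError("n_per_point must be >= 1")
    rng = np.random.default_rng(seed)
    strains = np.repeat(strain_grid, n_per_point)
    noise = rng.normal(0.0, noise_sd, size=strains.size) if noise_sd > 0 else 0.0
    tensions = K_A_true * strains + noise
    return strains, tensions


def plant_hbond_geometry(
    distance_nm: float, angle_deg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor, hydrogen, acceptor coordinates with exact D-A distance and
    D-H-A angle; the hydrogen sits 0.1 nm from the donor on the D-A geometry.
    """
    if distance_nm <= 0:
        raise GeneratorError("distance must be positive")
    if not (0.0 <= angle_deg <= 180.0):
        raise GeneratorError("angle must lie in [0, 180] degrees")
    dh = 0.1
    donor = np.zeros(3)
    hydrogen = np.array([dh, 0.0, 0.0])
    # direction of H->A making the requested angle with H->D = (-1, 0, 0)
    alpha = math.radians(180.0 - angle_deg)
    ux, uy = math.cos(alpha), math.sin(alpha)
    # |donor - acceptor| = distance: solve s^2 + 2 s dh ux + dh^2 = d^2
    disc = (dh * ux) ** 2 - dh**2 + distance_nm**2
    s = -dh * ux + math.sqrt(disc)
    acceptor = hydrogen + s * np.array([ux, uy, 0.0])
    return donor, hydrogen, acceptor


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def write_generated(
    outdir: str | Path,
    frames: Sequence[Frame],
    truth: GroundTruth,
    area_series: ScalarEnsemble | None = None,
) -> dict[str, Path]:
    """Write GRO + topology YAML + ground-truth JSON (+ scalar CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "configuration": outdir / "bilayer.gro",
        "topology": outdir / "topology.yaml",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_configuration(paths["configuration"], list(frames), truth.topology)
    save_topology(paths["topology"], truth.topology)
    paths["ground_truth"].write_text(
        json.dumps(truth.to_json_dict(), indent=1, sort_keys=True)
    )
    if area_series is not None:
        paths["scalars"] = outdir / "area_series.csv"
        write_scalar_csv(
            paths["scalars"],
            time_ns=np.arange(len(area_series), dtype=float),
            area_nm2=area_series.values,
            temperature_K=area_series.temperature,
        )
    return paths
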