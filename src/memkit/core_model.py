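"""Domain types, coordinate I/O and leaflet assignment for planar lipid bilayers.

Conventions used throughout the package:

* lengths in nm, energies in J, surface tension and area-compressibility
  moduli in mN/m; unit conversion happens only at I/O boundaries
  (PDB files are in Angstrom and are converted on read);
* the bilayer normal is the z axis — all systems are planar;
* a *site* is one interaction center (an atom or a coarse-grained bead), a
  *molecule* is an ordered block of sites, and the global site order is the
  concatenation of the molecule blocks in molecule order.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("memkit")

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Default temperature (37 C), K.
DEFAULT_TEMPERATURE = 310.15

#: Header used for scalar time-series CSV files.
SCALAR_CSV_COLUMNS = ["time_ns", "area_nm2", "tension_mN_m", "temperature_K"]

# Site roles.  Tail carbons carry their chain and position, e.g. "tail1_carbon_3".
ROLE_HEADGROUP = "headgroup"
ROLE_PHOSPHATE = "phosphate"
ROLE_GLYCEROL = "glycerol"
ROLE_CHOL_OH = "chol_oh_carbon"
ROLE_CHOL_TAIL = "chol_tail_carbon"
ROLE_SUGAR = "sugar_ring"
ROLE_WATER = "water"

UPPER = "upper"
LOWER = "lower"


class ParseError(ValueError):
    """A coordinate or config file could not be parsed."""


class TopologyError(ValueError):
    """A file or frame is inconsistent with the declared topology."""


class DegenerateInputError(ValueError):
    """The input admits no well-defined answer (e.g. a flat, planar 'bilayer')."""


def _tail_role(chain: int, index: int) -> str:
    return f"tail{chain}_carbon_{index}"


def parse_tail_role(role: str) -> tuple[int, int] | None:
    """Return (chain, carbon index) for a tail-carbon role, else None."""
    if not role.startswith("tail"):
        return None
    try:
        head, idx = role.split("_carbon_")
        return int(head[4:]), int(idx)
    except (ValueError, IndexError):
        return None


# ---------------------------------------------------------------------------
# Species and topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpecies:
    """One molecular species: its identity, mass and per-site roles.

    Parameters
    ----------
    name:
        Short label (POPC, POPE, CHOL, SM, GalCer, W ...).
    molar_mass:
        Molar mass in g/mol.
    role_map:
        Ordered mapping site label -> role.  Roles are the ``ROLE_*``
        constants or tail-carbon roles like ``tail1_carbon_4``.
    site_masses:
        Optional per-site masses (g/mol); defaults to an even split of
        ``molar_mass`` over the sites.
    site_electrons:
        Optional per-site electron counts, used for electron-weighted
        density profiles.
    """

    name: str
    molar_mass: float
    role_map: dict[str, str]
    site_masses: dict[str, float] | None = None
    site_electrons: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"species {self.name}: molar mass must be positive")
        if not self.role_map:
            raise ValueError(f"species {self.name}: no sites defined")
        # tail carbon indices must be contiguous starting at 1, per chain
        chains: dict[int, list[int]] = {}
        for role in self.role_map.values():
            tc = parse_tail_role(role)
            if tc is not None:
                chains.setdefault(tc[0], []).append(tc[1])
        for chain, idxs in chains.items():
            if sorted(idxs) != list(range(1, len(idxs) + 1)):
                raise ValueError(
                    f"species {self.name}: tail{chain} carbon indices must be "
                    f"contiguous starting at 1, got {sorted(idxs)}"
                )
        roles = list(self.role_map.values())
        if (ROLE_CHOL_OH in roles) or (ROLE_CHOL_TAIL in roles):
            if roles.count(ROLE_CHOL_OH) != 1 or roles.count(ROLE_CHOL_TAIL) != 1:
                raise ValueError(
                    f"species {self.name}: a cholesterol species needs exactly one "
                    f"{ROLE_CHOL_OH} and one {ROLE_CHOL_TAIL} site"
                )

    @property
    def site_labels(self) -> list[str]:
        return list(self.role_map)

    @property
    def n_sites(self) -> int:
        return len(self.role_map)

    @property
    def is_water(self) -> bool:
        return all(r == ROLE_WATER for r in self.role_map.values())

    @property
    def is_cholesterol(self) -> bool:
        return ROLE_CHOL_OH in self.role_map.values()

    def sites_with_role(self, role: str) -> list[str]:
        return [s for s, r in self.role_map.items() if r == role]

    def tail_sites(self, chain: int) -> list[str]:
        """Tail-carbon site labels of one chain, ordered by carbon index."""
        found = []
        for site, role in self.role_map.items():
            tc = parse_tail_role(role)
            if tc is not None and tc[0] == chain:
                found.append((tc[1], site))
        return [s for _, s in sorted(found)]

    @property
    def tail_chains(self) -> list[int]:
        chains = set()
        for role in self.role_map.values():
            tc = parse_tail_role(role)
            if tc is not None:
                chains.add(tc[0])
        return sorted(chains)

    def mass_of(self, site: str) -> float:
        if self.site_masses is not None and site in self.site_masses:
            return self.site_masses[site]
        return self.molar_mass / self.n_sites

    def electrons_of(self, site: str) -> float:
        if self.site_electrons is not None and site in self.site_electrons:
            return self.site_electrons[site]
        # fall back to mass-proportional weights so electron-mode profiles
        # remain usable when electron counts were not declared
        return self.mass_of(site) / 2.0


class BilayerTopology:
    """Static description of the system: species, molecule order, leaflet counts.

    Molecule order convention: all upper-leaflet lipids (grouped by species in
    declaration order), then lower-leaflet lipids, then waters.
    """

    def __init__(
        self,
        species: Sequence[LipidSpecies],
        molecule_species: Sequence[str],
        leaflet_counts: dict[str, int],
        composition: dict[str, float] | None = None,
    ) -> None:
        self.species = list(species)
        self._species_by_name = {s.name: s for s in self.species}
        if len(self._species_by_name) != len(self.species):
            raise TopologyError("duplicate species names")
        unknown = set(molecule_species) - set(self._species_by_name)
        if unknown:
            raise TopologyError(f"molecules reference unknown species: {sorted(unknown)}")
        self.molecule_species = list(molecule_species)
        self.leaflet_counts = dict(leaflet_counts)
        n_lipids = sum(
            1 for name in self.molecule_species if not self._species_by_name[name].is_water
        )
        if self.leaflet_counts.get(UPPER, 0) + self.leaflet_counts.get(LOWER, 0) != n_lipids:
            raise TopologyError(
                "leaflet counts must sum to the number of non-water molecules "
                f"({self.leaflet_counts} vs {n_lipids} lipids)"
            )
        if composition is None:
            counts: dict[str, float] = {}
            for name in self.molecule_species:
                if not self._species_by_name[name].is_water:
                    counts[name] = counts.get(name, 0) + 1
            composition = {k: v / n_lipids for k, v in counts.items()} if n_lipids else {}
        if composition and abs(sum(composition.values()) - 1.0) > 1e-9:
            raise TopologyError("mole fractions must sum to 1 within 1e-9")
        self.composition = dict(composition)
        self._build_site_tables()

    def _build_site_tables(self) -> None:
        offsets = [0]
        roles: list[str] = []
        labels: list[str] = []
        masses: list[float] = []
        electrons: list[float] = []
        mol_of_site: list[int] = []
        for i, name in enumerate(self.molecule_species):
            sp = self._species_by_name[name]
            for site in sp.site_labels:
                roles.append(sp.role_map[site])
                labels.append(site)
                masses.append(sp.mass_of(site))
                electrons.append(sp.electrons_of(site))
                mol_of_site.append(i)
            offsets.append(offsets[-1] + sp.n_sites)
        self._offsets = np.asarray(offsets)
        self.site_roles = np.asarray(roles, dtype=object)
        self.site_labels = np.asarray(labels, dtype=object)
        self.site_masses = np.asarray(masses)
        self.site_electrons = np.asarray(electrons)
        self.site_molecule = np.asarray(mol_of_site)
        self.site_species = np.asarray(
            [self.molecule_species[m] for m in mol_of_site], dtype=object
        )

    # -- basic sizes ------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecule_species)

    @property
    def n_sites(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_lipids(self) -> int:
        return sum(1 for n in self.molecule_species if not self.species_of(n).is_water)

    def species_of(self, name: str) -> LipidSpecies:
        return self._species_by_name[name]

    def molecule_sites(self, i: int) -> slice:
        """Global site-index slice of molecule ``i``."""
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def molecule_is_water(self, i: int) -> bool:
        return self.species_of(self.molecule_species[i]).is_water

    # -- selections -------------------------------------------------------
    def select_sites(
        self,
        species: str | Iterable[str] | None = None,
        roles: str | Iterable[str] | None = None,
        role_prefix: str | None = None,
    ) -> np.ndarray:
        """Global indices of sites filtered by species name and/or role."""
        mask = np.ones(self.n_sites, dtype=bool)
        if species is not None:
            wanted = {species} if isinstance(species, str) else set(species)
            mask &= np.isin(self.site_species, list(wanted))
        if roles is not None:
            wanted_r = {roles} if isinstance(roles, str) else set(roles)
            mask &= np.isin(self.site_roles, list(wanted_r))
        if role_prefix is not None:
            mask &= np.asarray([r.startswith(role_prefix) for r in self.site_roles])
        return np.nonzero(mask)[0]

    def reference_site(self, i: int) -> int:
        """Site representing molecule ``i`` in-plane (headgroup-like site).

        Preference order: headgroup, phosphate, cholesterol OH carbon, sugar
        ring, first site.
        """
        sp = self.species_of(self.molecule_species[i])
        start = int(self._offsets[i])
        for role in (ROLE_HEADGROUP, ROLE_PHOSPHATE, ROLE_CHOL_OH, ROLE_SUGAR):
            sites = sp.sites_with_role(role)
            if sites:
                return start + sp.site_labels.index(sites[0])
        return start

    def lipid_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i in range(self.n_molecules) if not self.molecule_is_water(i)]
        )


# ---------------------------------------------------------------------------
# Frames and scalar ensembles
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One configuration: periodic box (nm) and site coordinates (nm)."""

    box: tuple[float, float, float]
    coords: np.ndarray
    time: float = 0.0
    tension: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_sites, 3)")
        if not all(b > 0 for b in self.box):
            raise ValueError(f"box dimensions must be positive, got {self.box}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def area(self) -> float:
        """Projected bilayer area Lx*Ly in nm^2."""
        return self.box[0] * self.box[1]

    def check_topology(self, topology: BilayerTopology) -> None:
        if len(self.coords) != topology.n_sites:
            raise TopologyError(
                f"frame has {len(self.coords)} sites, topology defines {topology.n_sites}"
            )

    def wrapped(self) -> "Frame":
        """Copy with coordinates wrapped into the primary box [0, L)."""
        box = np.asarray(self.box)
        return Frame(
            box=self.box,
            coords=self.coords - np.floor(self.coords / box) * box,
            time=self.time,
            tension=self.tension,
            temperature=self.temperature,
        )


@dataclass
class LeafletAssignment:
    """Per-molecule leaflet labels; waters are unassigned (None)."""

    labels: list[str | None]
    midplane_z: float

    def molecules_in(self, leaflet: str) -> np.ndarray:
        return np.asarray([i for i, l in enumerate(self.labels) if l == leaflet])

    def counts(self) -> dict[str, int]:
        return {
            UPPER: sum(1 for l in self.labels if l == UPPER),
            LOWER: sum(1 for l in self.labels if l == LOWER),
        }


@dataclass
class ScalarEnsemble:
    """An ordered scalar time series (projected area in nm^2, tension in mN/m)."""

    values: np.ndarray
    quantity: str = "area"
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 4:
            raise ValueError("a scalar ensemble needs at least 4 values (block analysis)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ensemble values must be finite")
        if self.quantity == "area" and np.any(self.values <= 0):
            raise ValueError("area values must be positive")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(frame: Frame, topology: BilayerTopology) -> LeafletAssignment:
    """Assign every non-water molecule to the upper or lower leaflet.

    The midplane is the mean z of all phosphate sites (headgroup sites for
    species without a phosphate; OH carbon for cholesterol).  A lipid is
    *upper* iff its headgroup z exceeds the midplane; a lipid whose headgroup
    sits exactly on the midplane is assigned by the mean z of its tail
    carbons (documented tie-break).  Deterministic.
    """
    frame.check_topology(topology)
    z = frame.coords[:, 2]
    ref_zs = []
    for i in range(topology.n_molecules):
        if topology.molecule_is_water(i):
            continue
        ref_zs.append(z[_anchor_sites(topology, i)].mean())
    if not ref_zs:
        raise TopologyError("no lipid molecules to assign")
    midplane = float(np.mean(ref_zs))

    labels: list[str | None] = []
    for i in range(topology.n_molecules):
        if topology.molecule_is_water(i):
            labels.append(None)
            continue
        head_z = z[_anchor_sites(topology, i)].mean()
        if head_z > midplane:
            labels.append(UPPER)
        elif head_z < midplane:
            labels.append(LOWER)
        else:
            tail_z = _tail_center_z(frame, topology, i)
            if tail_z is None or tail_z == midplane:
                raise DegenerateInputError(
                    f"molecule {i} sits exactly on the midplane and has no "
                    "off-midplane tail center to break the tie"
                )
            # tails point toward the midplane from the headgroup side
            labels.append(LOWER if tail_z > midplane else UPPER)
    return LeafletAssignment(labels=labels, midplane_z=midplane)


def _anchor_sites(topology: BilayerTopology, i: int) -> np.ndarray:
    """Sites defining the interface position of molecule i."""
    sp = topology.species_of(topology.molecule_species[i])
    start = topology.molecule_sites(i).start
    if sp.is_cholesterol:
        role = ROLE_CHOL_OH
    elif sp.sites_with_role(ROLE_PHOSPHATE):
        role = ROLE_PHOSPHATE
    else:
        role = ROLE_HEADGROUP
    sites = sp.sites_with_role(role)
    if not sites:
        return np.asarray([topology.reference_site(i)])
    return np.asarray([start + sp.site_labels.index(s) for s in sites])


def _tail_center_z(frame: Frame, topology: BilayerTopology, i: int) -> float | None:
    sp = topology.species_of(topology.molecule_species[i])
    start = topology.molecule_sites(i).start
    tail_sites = []
    for site, role in sp.role_map.items():
        if parse_tail_role(role) is not None or role == ROLE_CHOL_TAIL:
            tail_sites.append(start + sp.site_labels.index(site))
    if not tail_sites:
        return None
    return float(frame.coords[np.asarray(tail_sites), 2].mean())


def stable_leaflets(
    frames: Sequence[Frame], topology: BilayerTopology
) -> LeafletAssignment:
    """Majority-vote leaflet labels across frames; flips are logged.

    Cholesterol flip-flop (or any label change between frames) is reported
    through the package logger and resolved by majority, ties to the first
    frame's label.
    """
    per_frame = [assign_leaflets(f, topology) for f in frames]
    labels: list[str | None] = []
    for i in range(topology.n_molecules):
        seq = [a.labels[i] for a in per_frame]
        if seq[0] is None:
            labels.append(None)
            continue
        n_upper = sum(1 for s in seq if s == UPPER)
        if 0 < n_upper < len(seq):
            logger.info("molecule %d changes leaflet across frames (%d/%d upper)",
                        i, n_upper, len(seq))
        if n_upper * 2 > len(seq):
            labels.append(UPPER)
        elif n_upper * 2 < len(seq):
            labels.append(LOWER)
        else:
            labels.append(seq[0])
    midplane = float(np.mean([a.midplane_z for a in per_frame]))
    return LeafletAssignment(labels=labels, midplane_z=midplane)


# ---------------------------------------------------------------------------
# Coordinate file I/O (GRO canonical, PDB read-only)
# ---------------------------------------------------------------------------

def read_configuration(
    path: str | Path, topology: BilayerTopology, wrap: bool = False
) -> list[Frame]:
    """Read a single- or multi-frame GRO file, or a PDB file with CRYST1.

    Boxes and coordinates are returned in nm (PDB Angstrom are converted).
    Coordinates are wrapped into the primary box only when ``wrap=True``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".gro":
        frames = _read_gro(path)
    elif suffix == ".pdb":
        frames = _read_pdb(path)
    else:
        raise ParseError(f"unsupported coordinate format: {path.name}")
    for frame in frames:
        if len(frame.coords) != topology.n_sites:
            raise TopologyError(
                f"{path.name}: frame has {len(frame.coords)} sites, "
                f"topology defines {topology.n_sites}"
            )
    if wrap:
        frames = [f.wrapped() for f in frames]
    return frames


def _read_gro(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        title = lines[pos]
        time = _gro_title_time(title, default=float(len(frames)))
        try:
            natoms = int(lines[pos + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"{path.name}: line {pos + 2}: expected atom count")
        end = pos + 2 + natoms
        if end >= len(lines) + 1 or end > len(lines):
            raise ParseError(f"{path.name}: line {pos + 2}: truncated frame")
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            line = lines[pos + 2 + k]
            try:
                coords[k, 0] = float(line[20:28])
                coords[k, 1] = float(line[28:36])
                coords[k, 2] = float(line[36:44])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path.name}: line {pos + 3 + k}: malformed atom record"
                )
        try:
            box_fields = [float(x) for x in lines[end].split()]
            box = (box_fields[0], box_fields[1], box_fields[2])
        except (IndexError, ValueError):
            raise ParseError(f"{path.name}: line {end + 1}: malformed box line")
        frames.append(Frame(box=box, coords=coords, time=time))
        pos = end + 1
    if not frames:
        raise ParseError(f"{path.name}: empty file")
    return frames


def _gro_title_time(title: str, default: float) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            pass
    return default


def write_configuration(
    path: str | Path, frames: Frame | Sequence[Frame], topology: BilayerTopology
) -> None:
    """Write frames as (multi-frame) GRO with 3-decimal nm coordinates."""
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    if path.suffix.lower() != ".gro":
        raise ParseError("only GRO output is supported (PDB is read-only)")
    buf = io.StringIO()
    for frame in frames:
        frame.check_topology(topology)
        buf.write(f"memkit bilayer t= {frame.time:.4f}\n")
        buf.write(f"{topology.n_sites:5d}\n")
        atom_id = 0
        for i, name in enumerate(topology.molecule_species):
            sp = topology.species_of(name)
            sl = topology.molecule_sites(i)
            for site, (x, y, z) in zip(sp.site_labels, frame.coords[sl]):
                atom_id += 1
                buf.write(
                    f"{(i + 1) % 100000:5d}{name[:5]:<5s}{site[:5]:>5s}"
                    f"{atom_id % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
        buf.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")
    path.write_text(buf.getvalue())


def _read_pdb(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    box: tuple[float, float, float] | None = None
    coords: list[list[float]] = []
    model_open = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = (
                        float(line[6:15]) / 10.0,
                        float(line[15:24]) / 10.0,
                        float(line[24:33]) / 10.0,
                    )
                except ValueError:
                    raise ParseError(f"{path.name}: line {lineno}: malformed CRYST1")
            elif rec == "MODEL":
                model_open = True
                coords = []
            elif rec in ("ATOM", "HETATM"):
                try:
                    coords.append(
                        [
                            float(line[30:38]) / 10.0,
                            float(line[38:46]) / 10.0,
                            float(line[46:54]) / 10.0,
                        ]
                    )
                except ValueError:
                    raise ParseError(f"{path.name}: line {lineno}: malformed ATOM record")
            elif rec == "ENDMDL":
                if box is None:
                    raise ParseError(f"{path.name}: line {lineno}: no CRYST1 before model")
                frames.append(
                    Frame(box=box, coords=np.asarray(coords), time=float(len(frames)))
                )
                model_open = False
                coords = []
    if coords and not model_open:
        if box is None:
            raise ParseError(f"{path.name}: missing CRYST1 record")
        frames.append(Frame(box=box, coords=np.asarray(coords), time=float(len(frames))))
    elif coords and model_open:
        raise ParseError(f"{path.name}: unterminated MODEL block")
    if not frames:
        raise ParseError(f"{path.name}: no coordinates found")
    return frames


# ---------------------------------------------------------------------------
# Topology YAML and scalar CSV
# ---------------------------------------------------------------------------

def save_topology(path: str | Path, topology: BilayerTopology) -> None:
    doc: dict = {"species": [], "leaflets": {UPPER: [], LOWER: []}, "water": 0}
    for sp in topology.species:
        entry: dict = {
            "name": sp.name,
            "molar_mass": sp.molar_mass,
            "sites": dict(sp.role_map),
        }
        if sp.site_masses:
            entry["masses"] = dict(sp.site_masses)
        if sp.site_electrons:
            entry["electrons"] = dict(sp.site_electrons)
        doc["species"].append(entry)
    # per-leaflet molecule sequences (order matters: it fixes the site layout)
    n_upper = topology.leaflet_counts.get(UPPER, 0)
    lipid_ids = list(topology.lipid_indices())
    for pos, i in enumerate(lipid_ids):
        leaflet = UPPER if pos < n_upper else LOWER
        doc["leaflets"][leaflet].append(topology.molecule_species[i])
    doc["water"] = topology.n_molecules - len(lipid_ids)
    doc["composition"] = dict(topology.composition)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_topology(path: str | Path) -> BilayerTopology:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        species = [
            LipidSpecies(
                name=e["name"],
                molar_mass=float(e["molar_mass"]),
                role_map=dict(e["sites"]),
                site_masses=e.get("masses"),
                site_electrons=e.get("electrons"),
            )
            for e in doc["species"]
        ]
        leaflets = doc["leaflets"]
        n_water = int(doc.get("water", 0))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: invalid topology file ({exc})")
    molecule_species: list[str] = []
    counts = {UPPER: 0, LOWER: 0}
    for leaflet in (UPPER, LOWER):
        entry = leaflets.get(leaflet, [])
        # sequence form (ordered molecules) or mapping form (species counts)
        seq = (
            [name for name, c in entry.items() for _ in range(int(c))]
            if isinstance(entry, dict)
            else [str(name) for name in entry]
        )
        molecule_species.extend(seq)
        counts[leaflet] += len(seq)
    water_species = next((s.name for s in species if s.is_water), None)
    if n_water:
        if water_species is None:
            raise ParseError(f"{path}: water molecules declared but no water species")
        molecule_species.extend([water_species] * n_water)
    return BilayerTopology(
        species=species,
        molecule_species=molecule_species,
        leaflet_counts=counts,
        composition=doc.get("composition"),
    )


def write_scalar_csv(
    path: str | Path,
    time_ns: np.ndarray,
    area_nm2: np.ndarray,
    tension_mN_m: np.ndarray | None = None,
    temperature_K: np.ndarray | float | None = None,
) -> None:
    n = len(time_ns)
    df = pd.DataFrame(
        {
            "time_ns": np.asarray(time_ns, dtype=float),
            "area_nm2": np.asarray(area_nm2, dtype=float),
            "tension_mN_m": (
                np.full(n, np.nan) if tension_mN_m is None else np.asarray(tension_mN_m)
            ),
            "temperature_K": (
                np.full(n, np.nan)
                if temperature_K is None
                else np.broadcast_to(np.asarray(temperature_K, dtype=float), (n,))
            ),
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def read_scalar_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCALAR_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: scalar CSV missing columns {missing}")
    return df


def area_ensemble_from_csv(path: str | Path) -> ScalarEnsemble:
    """Load the area channel of a scalar CSV as a ScalarEnsemble."""
    df = read_scalar_csv(path)
    temp = df["temperature_K"].dropna()
    return ScalarEnsemble(
        values=df["area_nm2"].to_numpy(),
        quantity="area",
        temperature=float(temp.iloc[0]) if len(temp) else None,
    )
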