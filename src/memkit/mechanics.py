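"""Mechanical observables of bilayers under tension.

Areal strain, the area compressibility modulus K_A by two routes — the slope
of surface tension versus areal strain, and the equilibrium area-fluctuation
formula K_A = k_B T <A> / <dA^2> — with 4-block standard errors, the
polymer-brush bending modulus K_c = K_A (h - h0)^2 / 24, classification of
the tension-strain curve into linear / logarithmic-like / plateau regimes,
and pore and interdigitated-state detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import (
    DEFAULT_TEMPERATURE,
    KB,
    LOWER,
    ROLE_PHOSPHATE,
    ROLE_WATER,
    UPPER,
    BilayerTopology,
    Frame,
    ScalarEnsemble,
    assign_leaflets,
)


# ---------------------------------------------------------------------------
# Strain and block statistics
# ---------------------------------------------------------------------------

def areal_strain(area: float, reference_area: float) -> float:
    """eps_A = A / A0 - 1, relative to the zero-tension reference area A0."""
    if reference_area <= 0:
        raise ValueError("reference area must be positive")
    if np.any(np.asarray(area) <= 0):
        raise ValueError("area must be positive")
    return area / reference_area - 1.0


def block_means(series: Sequence[float], n_blocks: int = 4) -> np.ndarray:
    """Means of ``n_blocks`` contiguous equal blocks; the remainder that does
    not divide evenly is dropped from the front of the series."""
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(series) < n_blocks:
        raise ValueError(f"series of length {len(series)} cannot form {n_blocks} blocks")
    m = len(series) // n_blocks
    trimmed = series[len(series) - m * n_blocks :]
    return trimmed.reshape(n_blocks, m).mean(axis=1)


def block_standard_error(series: Sequence[float], n_blocks: int = 4) -> float:
    """Standard error from block means: SD(block means) / sqrt(n_blocks)."""
    bm = block_means(series, n_blocks)
    return float(np.std(bm, ddof=1) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# Area compressibility modulus
# ---------------------------------------------------------------------------

@dataclass
class KAResult:
    """Area compressibility modulus with its standard error."""

    k_a: float              # mN/m
    stderr: float           # mN/m
    r_squared: float | None = None
    low_r_squared: bool = False
    n_points: int = 0


R_SQUARED_GATE = 0.9  # regression fits below this are flagged


def ka_regression(
    area_series_by_tension: dict[float, ScalarEnsemble],
    reference_area: float,
    n_blocks: int = 4,
    include_zero_tension: bool = False,
) -> KAResult:
    """K_A from the slope of surface tension versus areal strain.

    Each constant-tension area series is split into ``n_blocks`` contiguous
    blocks; every block contributes one (mean strain, tension) point and the
    unweighted ordinary-least-squares slope over all points is K_A, its
    standard error the SE of K_A.  The zero-tension series only defines the
    reference area unless ``include_zero_tension`` is set.  Fits with
    r^2 below 0.9 are flagged.
    """
    tensions = [
        g for g in area_series_by_tension if include_zero_tension or g != 0.0
    ]
    if len(set(tensions)) < 2:
        raise ValueError("need at least 2 distinct tension values (rank deficiency)")
    eps_pts: list[float] = []
    gam_pts: list[float] = []
    for gamma in sorted(tensions):
        for a in block_means(area_series_by_tension[gamma].values, n_blocks):
            eps_pts.append(areal_strain(float(a), reference_area))
            gam_pts.append(gamma)
    return _ols_result(eps_pts, gam_pts)


def _ols_result(eps_pts, gam_pts) -> KAResult:
    fit = stats.linregress(eps_pts, gam_pts)
    r2 = float(fit.rvalue**2)
    if not np.isfinite(r2):
        r2 = 0.0  # degenerate fit (constant tension): no explained variance
    return KAResult(
        k_a=float(fit.slope),
        stderr=float(fit.stderr),
        r_squared=r2,
        low_r_squared=r2 < R_SQUARED_GATE,
        n_points=len(eps_pts),
    )


def ka_from_tension_strain(
    strains: Sequence[float],
    tensions: Sequence[float],
    n_blocks: int = 4,
) -> KAResult:
    """K_A from repeated tension measurements on a strain grid.

    Tension samples sharing a strain value are reduced to ``n_blocks`` block
    means; the OLS slope of tension versus strain over the block points is
    K_A (mN/m).
    """
    strains = np.asarray(strains, dtype=float)
    tensions = np.asarray(tensions, dtype=float)
    if strains.shape != tensions.shape:
        raise ValueError("strains and tensions must be parallel arrays")
    grid = np.unique(strains)
    if grid.size < 2:
        raise ValueError("need at least 2 distinct strain values (rank deficiency)")
    eps_pts: list[float] = []
    gam_pts: list[float] = []
    for e in grid:
        samples = tensions[strains == e]
        if len(samples) >= n_blocks:
            bms = block_means(samples, n_blocks)
        else:
            bms = samples
        eps_pts.extend([float(e)] * len(bms))
        gam_pts.extend(float(b) for b in bms)
    return _ols_result(eps_pts, gam_pts)


def ka_fluctuation(area_series: ScalarEnsemble, n_blocks: int = 4) -> KAResult:
    """K_A from equilibrium area fluctuations: k_B T <A> / <dA^2>, in mN/m.

    The variance is the population variance of the full production series.
    The standard error comes from a delete-one-block jackknife over
    ``n_blocks`` contiguous blocks.
    """
    values = area_series.values
    if len(values) < 100:
        raise ValueError("fluctuation route needs at least 100 samples")
    T = area_series.temperature or DEFAULT_TEMPERATURE
    k_a = _ka_from_moments(float(values.mean()), float(values.var()), T)
    # jackknife over contiguous blocks
    m = len(values) // n_blocks
    trimmed = values[len(values) - m * n_blocks :]
    loo = []
    for b in range(n_blocks):
        rest = np.concatenate([trimmed[: b * m], trimmed[(b + 1) * m :]])
        loo.append(_ka_from_moments(float(rest.mean()), float(rest.var()), T))
    loo = np.asarray(loo)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return KAResult(k_a=k_a, stderr=se, n_points=len(values))


def _ka_from_moments(mean_area: float, var_area: float, temperature: float) -> float:
    if var_area <= 0:
        raise ValueError("zero area variance: modulus undefined (infinite)")
    # areas in nm^2: kB*T*<A>/var is J/nm^2 = 1e18 N/m = 1e21 mN/m
    return KB * temperature * mean_area / var_area * 1e21


def bending_modulus(k_a: float, thickness: float, h0: float = 1.0) -> float:
    """Polymer-brush bending modulus K_c = K_A (h - h0)^2 / 24, in J.

    ``k_a`` in mN/m, ``thickness`` (h) and ``h0`` in nm; h0 = 1 nm is the
    standard choice, valid for phosphatidylcholine bilayers in the liquid
    phase.
    """
    if thickness <= h0:
        raise ValueError(f"thickness {thickness} nm must exceed h0 = {h0} nm")
    return (k_a * 1e-3) * ((thickness - h0) * 1e-9) ** 2 / 24.0


# ---------------------------------------------------------------------------
# Regime classification
# ---------------------------------------------------------------------------

@dataclass
class Regime:
    strain_range: tuple[float, float]
    label: str  # "linear", "logarithmic" or "plateau"


LINEAR_RESIDUAL_TOL = 0.05   # max relative residual of the through-origin fit
PLATEAU_SLOPE_FRACTION = 0.10  # local slope below this fraction of the linear slope
MIN_LINEAR_POINTS = 3


def classify_regimes(
    strains: Sequence[float],
    tensions: Sequence[float],
    linear_tol: float = LINEAR_RESIDUAL_TOL,
    plateau_frac: float = PLATEAU_SLOPE_FRACTION,
) -> list[Regime]:
    """Label the tension-strain curve as linear / logarithmic-like / plateau.

    The linear regime is the maximal prefix on which a through-origin fit
    keeps every relative residual below ``linear_tol`` (at least 3 points);
    the plateau is the maximal suffix on which every local slope stays below
    ``plateau_frac`` of the linear-regime slope; whatever lies between is
    labelled logarithmic.  Thresholds are package choices — the underlying
    behaviour (linear, then logarithmic-like, then plateau) is qualitative.
    """
    eps = np.asarray(strains, dtype=float)
    gam = np.asarray(tensions, dtype=float)
    if len(eps) < 8:
        raise ValueError("regime classification needs at least 8 points")
    if np.any(np.diff(eps) <= 0):
        raise ValueError("strains must be strictly increasing")

    # maximal linear prefix
    linear_end = 0
    linear_slope = None
    for k in range(len(eps), MIN_LINEAR_POINTS - 1, -1):
        e, g = eps[:k], gam[:k]
        s = float(np.dot(e, g) / np.dot(e, e))
        resid = np.abs(g - s * e) / np.maximum(np.abs(g), 1e-12)
        if np.all(resid < linear_tol):
            linear_end = k
            linear_slope = s
            break
    if linear_slope is None:
        linear_slope = float((gam[-1] - gam[0]) / (eps[-1] - eps[0]))

    # maximal plateau suffix (pairwise local slopes)
    local = np.diff(gam) / np.diff(eps)
    plateau_start = len(eps)
    for p in range(max(linear_end, 0), len(eps) - 1):
        if np.all(np.abs(local[p:]) < plateau_frac * abs(linear_slope)):
            plateau_start = p
            break

    regimes: list[Regime] = []
    if linear_end >= MIN_LINEAR_POINTS:
        regimes.append(Regime((float(eps[0]), float(eps[linear_end - 1])), "linear"))
        mid_lo = linear_end - 1
    else:
        mid_lo = 0
    if plateau_start < len(eps):
        if plateau_start > mid_lo:
            regimes.append(
                Regime((float(eps[mid_lo]), float(eps[plateau_start])), "logarithmic")
            )
        regimes.append(
            Regime((float(eps[plateau_start]), float(eps[-1])), "plateau")
        )
    elif mid_lo < len(eps) - 1:
        regimes.append(Regime((float(eps[mid_lo]), float(eps[-1])), "logarithmic"))
    if not regimes:
        regimes.append(Regime((float(eps[0]), float(eps[-1])), "logarithmic"))
    return regimes


# ---------------------------------------------------------------------------
# Pore and interdigitation detectors
# ---------------------------------------------------------------------------

@dataclass
class PoreResult:
    detected: bool
    bin: tuple[int, int] | None = None


def detect_pore(
    frame: Frame, topology: BilayerTopology, bin_size: float = 0.31
) -> PoreResult:
    """Detect a transmembrane water column.

    A pore exists iff some (x, y) bin column holds water sites spanning the
    hydrophobic slab between the two phosphate planes with every vertical
    gap (including the gaps to the planes) smaller than ``bin_size``.  When
    the phosphate planes cannot be resolved the check falls back to a fixed
    +-1 nm central slab, with a warning.
    """
    if bin_size <= 0 or bin_size > min(frame.box[0], frame.box[1]):
        raise ValueError("bin_size must be positive and no larger than the box")
    waters = topology.select_sites(roles=ROLE_WATER)
    if waters.size == 0:
        raise ValueError("no water sites present")
    try:
        asg = assign_leaflets(frame, topology)
        z_planes = []
        for leaflet in (LOWER, UPPER):
            mols = asg.molecules_in(leaflet)
            sel = np.nonzero(
                np.isin(topology.site_molecule, mols)
                & (topology.site_roles == ROLE_PHOSPHATE)
            )[0]
            if sel.size == 0:  # e.g. phosphate-free composition
                raise ValueError("no phosphate sites")
            z_planes.append(float(frame.coords[sel, 2].mean()))
        z_low, z_high = sorted(z_planes)
    except ValueError:
        warnings.warn("phosphate planes unresolved; using fixed central slab")
        lipid_sites = np.nonzero(topology.site_roles != ROLE_WATER)[0]
        mid = float(frame.coords[lipid_sites, 2].mean())
        z_low, z_high = mid - 1.0, mid + 1.0

    wrapped = frame.wrapped()
    Lx, Ly = frame.box[0], frame.box[1]
    nx = max(1, int(Lx // bin_size))
    ny = max(1, int(Ly // bin_size))
    bwx, bwy = Lx / nx, Ly / ny
    columns: dict[tuple[int, int], list[float]] = {}
    for w in waters:
        x, y, z = wrapped.coords[w]
        if z_low - bin_size < z < z_high + bin_size:
            key = (min(int(x / bwx), nx - 1), min(int(y / bwy), ny - 1))
            columns.setdefault(key, []).append(z)
    for key, zs in columns.items():
        pts = np.sort([z for z in zs if z_low <= z <= z_high])
        ladder = np.concatenate([[z_low], pts, [z_high]])
        if np.all(np.diff(ladder) < bin_size):
            return PoreResult(detected=True, bin=key)
    return PoreResult(detected=False)


@dataclass
class InterdigitationResult:
    interdigitated: bool
    overlap: float
    threshold: float


def detect_interdigitation(
    frames: Sequence[Frame],
    topology: BilayerTopology,
    threshold: float = 0.9,
) -> InterdigitationResult:
    """Flag a (fully) interdigitated state: leaflet overlap lambda >= threshold
    (inclusive)."""
    from .structure_analysis import interdigitation  # local import, avoids a cycle

    lam = interdigitation(frames, topology)
    return InterdigitationResult(
        interdigitated=lam >= threshold, overlap=lam, threshold=threshold
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class MechanicalReport:
    """Summary of the mechanical observables of one system."""

    k_a_regression: KAResult | None = None
    k_a_fluctuation: KAResult | None = None
    k_c: float | None = None            # J
    reference_area: float | None = None  # nm^2
    regimes: list[Regime] = field(default_factory=list)
    pore_detected: bool | None = None
    interdigitated: bool | None = None

    def to_json_dict(self) -> dict:
        def ka(r: KAResult | None) -> dict | None:
            if r is None:
                return None
            return {
                "k_a_mN_m": r.k_a,
                "stderr_mN_m": r.stderr,
                "r_squared": r.r_squared,
                "low_r_squared": r.low_r_squared,
                "n_points": r.n_points,
            }

        return {
            "k_a_regression": ka(self.k_a_regression),
            "k_a_fluctuation": ka(self.k_a_fluctuation),
            "k_c_J": self.k_c,
            "reference_area_nm2": self.reference_area,
            "regimes": [
                {"strain_range": list(r.strain_range), "label": r.label}
                for r in self.regimes
            ],
            "pore_detected": self.pore_detected,
            "interdigitated": self.interdigitated,
        }
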