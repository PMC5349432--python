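"""Density-grid synthesis, masking and map-correlation metrics.

The "observed", model and difference maps are real-space Gaussian
syntheses on a regular orthogonal grid: each atom contributes an
isotropic Gaussian of mass occ*Z (Z = atomic number) whose width
combines the B-factor smearing u^2 = B/(8 pi^2) with a fixed softening
width.  The direct map (ligand-omit residual) and difference map
(observed minus full model) are plain grid subtractions, so the
correlation metrics keep their crystallographic meaning while the
structure-factor round trip is avoided entirely.

Grid points entering a correlation are chosen REFMAC-style: inside the
masking radius r0(element) + c_b*sqrt(B/(8 pi^2)) of at least one ligand
atom and outside the (inflated) masking radius of every neighbouring
atom, so density contributed by the environment never pollutes the
ligand-site statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from .model_io import Atom, LigandSelection, Structure

__all__ = [
    "DensityGrid",
    "MaskSpec",
    "QQData",
    "ReflectionSet",
    "GridSpec",
    "calc_model_map",
    "mask_radius",
    "ligand_grid_points",
    "correlation",
    "diff_map_correlation",
    "qq_data",
    "effective_resolution",
    "occupancy_scan",
    "UndefinedCorrelationError",
    "ZeroResidualError",
]

B_TO_U2 = 1.0 / (8.0 * math.pi**2)  # u^2 = B / (8 pi^2)


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation has no defined value (zero variance)."""


class ZeroResidualError(UndefinedCorrelationError):
    """The difference density is numerically zero at the ligand site:
    the well-modelled limit, where cc_diff has no defined value."""


@dataclass
class DensityGrid:
    """Regular isotropic 3-D grid of density values.

    origin is the Cartesian position (A) of grid node (0,0,0); spacing
    is A per step along each axis.  Two grids are compatible iff their
    origin, spacing and dims agree.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def compatible(self, other: "DensityGrid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and math.isclose(self.spacing, other.spacing)
            and self.dims == other.dims
        )

    def node_position(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    # --- arithmetic -------------------------------------------------
    def __sub__(self, other: "DensityGrid") -> "DensityGrid":
        if not self.compatible(other):
            raise ValueError("incompatible grids")
        return DensityGrid(self.origin.copy(), self.spacing, self.values - other.values)

    def __add__(self, other: "DensityGrid") -> "DensityGrid":
        if not self.compatible(other):
            raise ValueError("incompatible grids")
        return DensityGrid(self.origin.copy(), self.spacing, self.values + other.values)

    def scaled(self, factor: float) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing, self.values * factor)

    # --- i/o --------------------------------------------------------
    def to_npz(self, path: str | Path) -> None:
        np.savez(path, origin=self.origin, spacing=self.spacing, values=self.values)

    @classmethod
    def from_npz(cls, path: str | Path) -> "DensityGrid":
        with np.load(path) as f:
            return cls(f["origin"], float(f["spacing"]), f["values"])

    def to_ccp4(self, path: str | Path) -> None:
        """Export as a CCP4/MRC map with an orthogonal P1 cell."""
        nx, ny, nz = self.dims
        cell = gemmi.UnitCell(nx * self.spacing, ny * self.spacing, nz * self.spacing, 90, 90, 90)
        grid = gemmi.FloatGrid(nx, ny, nz)
        grid.set_unit_cell(cell)
        grid.spacegroup = gemmi.SpaceGroup("P1")
        arr = np.array(grid, copy=False)
        arr[...] = self.values.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def from_ccp4(cls, path: str | Path, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "DensityGrid":
        m = gemmi.read_ccp4_map(str(path))
        grid = m.grid
        if not (
            math.isclose(grid.unit_cell.alpha, 90)
            and math.isclose(grid.unit_cell.beta, 90)
            and math.isclose(grid.unit_cell.gamma, 90)
        ):
            raise ValueError("only orthogonal cells are supported")
        vals = np.array(grid, copy=True).astype(float)
        spacing = grid.unit_cell.a / grid.nu
        return cls(np.asarray(origin, dtype=float), spacing, vals)


@dataclass
class GridSpec:
    """Geometry of a grid to synthesize onto."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @classmethod
    def around_atoms(cls, atoms: Sequence[Atom], spacing: float = 0.5, margin: float = 4.0) -> "GridSpec":
        pos = np.array([a.pos for a in atoms])
        lo = pos.min(axis=0) - margin
        hi = pos.max(axis=0) + margin
        dims = tuple(int(math.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(lo, spacing, dims)  # type: ignore[arg-type]


#: Default per-element base masking radii (A), REFMAC-like.
DEFAULT_R0 = {"C": 1.7, "N": 1.6, "O": 1.5, "S": 1.8, "P": 1.8}


@dataclass
class MaskSpec:
    """Masking-radius parameterization: r(element, B) = r0 + c_b*sqrt(B/(8 pi^2)).

    neighbour_radius_inflation (A) is added to environment-atom radii
    when excluding grid points contaminated by neighbouring residues.
    """

    r0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_R0))
    c_b: float = 3.0
    neighbour_radius_inflation: float = 0.0
    default_r0: float = 1.7


@dataclass
class QQData:
    """Paired quantiles for a normal Q-Q plot of difference density."""

    theoretical: np.ndarray
    observed: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.theoretical = np.asarray(self.theoretical, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.theoretical.shape != self.observed.shape:
            raise ValueError("quantile arrays must have equal length")
        if np.any(np.diff(self.theoretical) < 0) or np.any(np.diff(self.observed) < 0):
            raise ValueError("quantile arrays must be non-decreasing")


@dataclass
class ReflectionSet:
    """Reflection amplitudes with uncertainties; missing records carry
    observed=False.  Backed by a DataFrame with columns
    (h, k, l, F, sigF, observed)."""

    records: pd.DataFrame
    d_min: float

    def __post_init__(self) -> None:
        need = {"F", "sigF", "observed"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"reflection table needs columns {sorted(need)}")
        obs = self.records[self.records["observed"].astype(bool)]
        if (obs["sigF"] < 0).any():
            raise ValueError("negative sigma(F) on observed reflection")

    @classmethod
    def from_csv(cls, path: str | Path, d_min: float | None = None) -> "ReflectionSet":
        df = pd.read_csv(path)
        if d_min is None:
            if "d_min" not in df.columns:
                raise ValueError("d_min not given and no d_min column present")
            d_min = float(df["d_min"].iloc[0])
        return cls(df, d_min)


def atomic_number(element: str) -> int:
    z = gemmi.Element(element).atomic_number
    if z == 0:
        warnings.warn(f"unknown element {element!r}; using carbon Z")
        z = 6
    return z


def calc_model_map(
    atoms: Sequence[Atom],
    grid: GridSpec,
    omit: Iterable[Atom] = (),
    softening_width: float = 0.5,
    cutoff_sigmas: float = 6.0,
) -> DensityGrid:
    """Synthesize model density from Gaussian atoms.

    Each non-omitted, non-hydrogen atom contributes
    occ * Z * (2 pi s^2)^(-3/2) * exp(-d^2 / (2 s^2)) with
    s^2 = B/(8 pi^2) + softening_width^2; contributions are summed on
    the grid.  Atoms are rendered only within cutoff_sigmas * s, beyond
    which the Gaussian tail is negligible.  Linear in occupancy.
    """
    omit_keys = {a.key() for a in omit}
    values = np.zeros(grid.dims, dtype=float)
    origin = grid.origin
    sp = grid.spacing
    dims = grid.dims

    axes = [origin[i] + sp * np.arange(dims[i]) for i in range(3)]
    lo_corner = origin
    hi_corner = origin + sp * (np.array(dims) - 1)

    for a in atoms:
        if a.key() in omit_keys or a.element.upper() == "H":
            continue
        if np.any(a.pos < lo_corner - 3.0) or np.any(a.pos > hi_corner + 3.0):
            warnings.warn(f"atom {a.name} outside grid + 3 A margin")
        s2 = a.b * B_TO_U2 + softening_width**2
        s = math.sqrt(s2)
        cut = cutoff_sigmas * s
        sl = []
        ok = True
        for i in range(3):
            i0 = max(0, int(math.ceil((a.pos[i] - cut - origin[i]) / sp)))
            i1 = min(dims[i] - 1, int(math.floor((a.pos[i] + cut - origin[i]) / sp)))
            if i1 < i0:
                ok = False
                break
            sl.append((i0, i1))
        if not ok:
            continue
        dx = axes[0][sl[0][0] : sl[0][1] + 1] - a.pos[0]
        dy = axes[1][sl[1][0] : sl[1][1] + 1] - a.pos[1]
        dz = axes[2][sl[2][0] : sl[2][1] + 1] - a.pos[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        amp = a.occ * atomic_number(a.element) * (2 * math.pi * s2) ** -1.5
        values[
            sl[0][0] : sl[0][1] + 1,
            sl[1][0] : sl[1][1] + 1,
            sl[2][0] : sl[2][1] + 1,
        ] += amp * np.exp(-d2 / (2 * s2))
    return DensityGrid(origin.copy(), sp, values)


def mask_radius(element: str, b: float, spec: MaskSpec | None = None) -> float:
    """REFMAC-style masking radius r0(element) + c_b*sqrt(B/(8 pi^2))."""
    if b < 0:
        raise ValueError("negative B-factor")
    spec = spec or MaskSpec()
    el = element.capitalize()
    r0 = spec.r0.get(el)
    if r0 is None:
        warnings.warn(f"no base radius for element {element!r}; using {spec.default_r0} A")
        r0 = spec.default_r0
    return r0 + spec.c_b * math.sqrt(b * B_TO_U2)


def ligand_grid_points(
    grid: DensityGrid | GridSpec,
    lig_atoms: Sequence[Atom],
    env_atoms: Sequence[Atom],
    spec: MaskSpec | None = None,
) -> set[tuple[int, int, int]]:
    """Grid nodes inside the mask of >=1 ligand atom and outside the
    (inflated) mask of every environment atom."""
    spec = spec or MaskSpec()
    dims = grid.dims
    sp = grid.spacing
    origin = np.asarray(grid.origin, dtype=float)

    inside = np.zeros(dims, dtype=bool)
    _paint_spheres(inside, origin, sp, lig_atoms, spec, inflation=0.0, value=True)
    excluded = np.zeros(dims, dtype=bool)
    _paint_spheres(
        excluded, origin, sp, env_atoms, spec,
        inflation=spec.neighbour_radius_inflation, value=True,
    )
    keep = inside & ~excluded
    idx = np.argwhere(keep)
    if idx.size == 0:
        raise ValueError("ligand fully masked by environment")
    return {tuple(int(v) for v in row) for row in idx}


def _paint_spheres(mask, origin, sp, atoms, spec, inflation, value) -> None:
    dims = mask.shape
    axes = [origin[i] + sp * np.arange(dims[i]) for i in range(3)]
    for a in atoms:
        if a.element.upper() == "H":
            continue
        r = mask_radius(a.element, a.b, spec) + inflation
        sl = []
        ok = True
        for i in range(3):
            i0 = max(0, int(math.ceil((a.pos[i] - r - origin[i]) / sp)))
            i1 = min(dims[i] - 1, int(math.floor((a.pos[i] + r - origin[i]) / sp)))
            if i1 < i0:
                ok = False
                break
            sl.append((i0, i1))
        if not ok:
            continue
        dx = axes[0][sl[0][0] : sl[0][1] + 1] - a.pos[0]
        dy = axes[1][sl[1][0] : sl[1][1] + 1] - a.pos[1]
        dz = axes[2][sl[2][0] : sl[2][1] + 1] - a.pos[2]
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        region = mask[
            sl[0][0] : sl[0][1] + 1,
            sl[1][0] : sl[1][1] + 1,
            sl[2][0] : sl[2][1] + 1,
        ]
        region |= d2 <= r * r


def _values_at(grid: DensityGrid, points: Iterable[tuple[int, int, int]]) -> np.ndarray:
    idx = np.array(sorted(points))
    return grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]


def correlation(
    a: DensityGrid, b: DensityGrid, points: Iterable[tuple[int, int, int]]
) -> float:
    """Pearson correlation of two maps over the selected grid nodes."""
    if not a.compatible(b):
        raise ValueError("incompatible grids")
    pts = set(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 grid points")
    va = _values_at(a, pts)
    vb = _values_at(b, pts)
    sa = va.std()
    sb = vb.std()
    if sa == 0.0 or sb == 0.0:
        raise UndefinedCorrelationError("zero variance over the selected points")
    return float(np.corrcoef(va, vb)[0, 1])


def diff_map_correlation(
    diff: DensityGrid, model_lig: DensityGrid, points: Iterable[tuple[int, int, int]]
) -> float:
    """Correlation of residual (observed - full model) density with the
    ligand's own model density; negative values flag excess modelled
    density at the ligand site (over-estimated occupancy).

    A residual whose variation over the points is negligible relative
    to the ligand density (< 1e-9 of its spread) is numerically zero --
    the well-modelled limit -- and the correlation is undefined.
    """
    pts = set(points)
    if len(pts) >= 2:
        vd = _values_at(diff, pts)
        vm = _values_at(model_lig, pts)
        if vd.std() <= 1e-9 * vm.std():
            raise ZeroResidualError("difference density is zero at the ligand site")
    return correlation(diff, model_lig, pts)


def qq_data(
    diff: DensityGrid | np.ndarray,
    points: Iterable[tuple[int, int, int]] | None = None,
    n_quantiles: int = 100,
) -> QQData:
    """Normal Q-Q data for the difference density in the ligand context.

    Observed quantiles are taken from the difference-map values over the
    masked points, standardized by their own mean/sd; theoretical
    quantiles are standard-normal at plotting positions (i-0.5)/n.
    """
    if isinstance(diff, DensityGrid):
        if points is None:
            raise ValueError("points required with a grid input")
        vals = _values_at(diff, set(points))
    else:
        vals = np.asarray(diff, dtype=float).ravel()
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if vals.size < n_quantiles:
        raise ValueError("fewer values than requested quantiles")
    sd = vals.std()
    if sd == 0.0:
        raise ValueError("zero variance in difference density")
    z = (vals - vals.mean()) / sd
    p = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    return QQData(stats.norm.ppf(p), np.quantile(z, p), n=int(vals.size))


def effective_resolution(refl: ReflectionSet) -> float:
    """Effective resolution correcting the nominal d_min for missing
    data and amplitude uncertainties:

        N_eff = sum over observed of F^2 / (F^2 + sigma(F)^2)
        R_eff = d_min * (N_total / N_eff)^(1/3)

    Complete, error-free data give R_eff = d_min; incompleteness and
    noise only ever increase it.
    """
    df = refl.records
    obs = df[df["observed"].astype(bool)]
    if len(obs) == 0:
        raise ValueError("no observed reflections")
    f2 = obs["F"].to_numpy(dtype=float) ** 2
    s2 = obs["sigF"].to_numpy(dtype=float) ** 2
    with np.errstate(invalid="ignore"):
        n_eff = float(np.sum(np.where(f2 + s2 > 0, f2 / (f2 + s2), 0.0)))
    if n_eff <= 0:
        raise ValueError("effective reflection count is zero")
    return refl.d_min * (len(df) / n_eff) ** (1.0 / 3.0)


DEFAULT_OCC_GRID = tuple(round(0.05 * i, 2) for i in range(21))  # 0.0 .. 1.0 step 0.05


def occupancy_scan(
    s: Structure,
    lig: LigandSelection,
    observed: DensityGrid,
    grid: GridSpec | None = None,
    occupancies: Sequence[float] = DEFAULT_OCC_GRID,
    spec: MaskSpec | None = None,
    env_radius: float = 4.0,
) -> list[tuple[float, float | None, float | None]]:
    """Scan trial ligand occupancies and record both correlations.

    For each trial occupancy q the full-model map is rebuilt with the
    ligand at occ=q (no re-refinement) and the difference map is
    observed minus that model; cc_direct correlates the ligand-omit
    residual with the ligand model and cc_diff correlates the residual
    with the ligand density over the masked ligand points.  Undefined
    correlations (e.g. zero residual at the true occupancy, or zero
    ligand density at q=0) yield None entries rather than failures.

    Density is linear in occupancy, so the model map at occupancy q is
    assembled as env_map + q * (unit-occupancy ligand map).
    """
    if any(q < 0 or q > 1 for q in occupancies):
        raise ValueError("occupancies must lie in [0, 1]")
    if grid is None:
        grid = GridSpec(observed.origin, observed.spacing, observed.dims)
    from .model_io import neighbourhood  # local import to avoid cycle noise

    env = neighbourhood(s, lig, env_radius)
    points = ligand_grid_points(grid, lig.atoms, env, spec)

    lig_unit = calc_model_map(
        [Atom(a.name, a.element, a.pos.copy(), 1.0, a.b, a.altloc, a.comp_id, a.chain, a.seq_id)
         for a in lig.atoms],
        grid,
    )
    lig_keys = lig.atom_keys()
    env_map = calc_model_map([a for a in s.atoms if a.key() not in lig_keys], grid)
    direct = observed - env_map  # ligand-omit residual

    out: list[tuple[float, float | None, float | None]] = []
    for q in occupancies:
        model_lig = lig_unit.scaled(q)
        diff = direct - model_lig  # == observed - (env + q*lig)
        try:
            cc_dir = correlation(direct, model_lig, points)
        except (UndefinedCorrelationError, ValueError):
            cc_dir = None
        try:
            cc_diff = diff_map_correlation(diff, model_lig, points)
        except (UndefinedCorrelationError, ValueError):
            cc_diff = None
        out.append((float(q), cc_dir, cc_diff))
    return out
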