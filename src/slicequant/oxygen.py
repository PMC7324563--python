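"""Oxygen reaction–diffusion modelling of tissue-slice culture.

The model describes oxygen partial pressure ``p`` (mmHg) over a 2D cross
section (lateral ``x``, depth ``z``) of a slice-culture vessel.  Transport is
written in the partial-pressure formulation

    alpha * dp/dt = div(K grad p) - R(p)

where ``alpha`` is the oxygen solubility of the local phase
(mol m^-3 mmHg^-1) and ``K`` the diffusive permeability, the product of
effective diffusivity and solubility (mol m^-1 s^-1 mmHg^-1).  Working in
partial pressure makes ``p`` continuous across phase interfaces, so no
partition coefficients are needed.  Consumption follows Michaelis–Menten
kinetics ``R(p) = r_max * p / (p + km)`` inside tissue and is optionally
hard-zeroed below the anoxia threshold (cells below ~0.1 mmHg stop
respiring).

Two vessel geometries are supported:

* ``transwell`` — the slice rests on a liquid-permeable membrane suspended in
  medium; oxygen enters only through the free medium surface on top (Dirichlet
  boundary at the gas tension), the dish bottom is impermeable (zero flux) and
  the membrane is a zero-thickness flux-conserving (continuity) interface.
* ``pfc`` — the slice rests on a gas-permeable, liquid-impermeable
  perfluorocarbon membrane; the slice base *and* the medium free surface are
  both Dirichlet boundaries at the gas tension ("oxygen sandwich").

Discretization is a vertex-centred finite-volume scheme on a structured
tensor grid (second order in space), with backward-Euler time stepping and
the kinetics resolved by Picard iteration within each step.  The per-step system is an
M-matrix, so the scheme is unconditionally stable, preserves positivity and
satisfies a discrete maximum principle; a per-step discrete oxygen balance
(boundary influx - consumption = storage change) is tracked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ATMOSPHERIC_GAS_PO2",
    "MEDIUM",
    "TISSUE",
    "TransportPhase",
    "KineticsSpec",
    "CultureConfiguration",
    "GridResolution",
    "DomainLayout",
    "OxygenField",
    "SimulationResult",
    "default_phases",
    "build_domain",
    "build_slab",
    "steady_state",
    "simulate",
    "anoxic_fraction",
    "anoxia_onset",
    "ocr_sweep",
    "calibrate_transwell_medium_depth",
    "calibrated_transwell_config",
    "calibrated_pfc_config",
    "CALIBRATED_RESOLUTION",
    "CALIBRATED_DT_S",
    "TRANSWELL_CALIBRATED_DEPTH_ABOVE_MM",
    "TRANSWELL_CALIBRATED_DEPTH_BELOW_MM",
]

#: 21% O2 in a humidified incubator: 0.21 * (760 - 47) mmHg.
ATMOSPHERIC_GAS_PO2 = 0.21 * (760.0 - 47.0)


@dataclass(frozen=True)
class TransportPhase:
    """Oxygen transport properties of one phase (medium, tissue, ...)."""

    name: str
    #: oxygen solubility, mol m^-3 mmHg^-1
    solubility_alpha: float
    #: diffusive permeability K = D_eff * alpha, mol m^-1 s^-1 mmHg^-1
    permeability_K: float

    def __post_init__(self) -> None:
        if not self.solubility_alpha > 0:
            raise ValueError("solubility_alpha must be > 0")
        if not self.permeability_K > 0:
            raise ValueError("permeability_K must be > 0")


# 37 degC aqueous defaults; both configurable per run.
MEDIUM = TransportPhase("medium", solubility_alpha=1.27e-3, permeability_K=3.5e-12)
TISSUE = TransportPhase("tissue", solubility_alpha=1.27e-3, permeability_K=2.4e-12)


def default_phases() -> dict[str, TransportPhase]:
    return {"medium": MEDIUM, "tissue": TISSUE}


@dataclass(frozen=True)
class KineticsSpec:
    """Michaelis–Menten oxygen consumption inside tissue.

    ``r_max`` is the volumetric oxygen consumption rate (OCR, mol m^-3 s^-1);
    0.03 is the average for islet plus acinar tissue.  ``km`` (mmHg) is not a
    measured quantity here; 0.44 mmHg is the standard islet-modelling value.
    Below ``anoxia_threshold`` (mmHg) consumption is hard-zeroed when
    ``shutoff_below_threshold`` is set.
    """

    r_max: float = 0.03
    km: float = 0.44
    anoxia_threshold: float = 0.1
    #: With the shutoff enabled, consumption stops below the threshold and the
    #: field floors just above it wherever any supply remains (the anoxic
    #: region then only marks fully starved tissue); the default keeps the
    #: continuous Michaelis–Menten law everywhere so pO2 crosses the threshold
    #: smoothly and the anoxic-volume statistic is well defined.
    shutoff_below_threshold: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_max <= 1.0):
            raise ValueError("r_max must be within [0, 1] mol m^-3 s^-1")
        if self.km < 0:
            raise ValueError("km must be >= 0")
        if not self.anoxia_threshold > 0:
            raise ValueError("anoxia_threshold must be > 0")


@dataclass(frozen=True)
class CultureConfiguration:
    """Vessel geometry for one culture mode.

    ``medium_depth_below_mm`` only applies to transwell mode (medium between
    the dish bottom and the membrane); it must be ``None`` for ``pfc``.
    ``lateral_margin_mm`` is medium extending beyond the slice edge on each
    side.
    """

    mode: str
    slice_thickness_um: float = 120.0
    slice_width_mm: float = 10.0
    medium_depth_above_mm: float = 1.0
    medium_depth_below_mm: float | None = None
    gas_po2: float = ATMOSPHERIC_GAS_PO2
    lateral_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("transwell", "pfc"):
            raise ValueError(f"unknown culture mode: {self.mode!r}")
        if not self.slice_thickness_um > 0:
            raise ValueError("slice_thickness_um must be > 0")
        if not self.slice_width_mm > 0:
            raise ValueError("slice_width_mm must be > 0")
        if not self.medium_depth_above_mm > 0:
            raise ValueError("medium_depth_above_mm must be > 0")
        if self.lateral_margin_mm < 0:
            raise ValueError("lateral_margin_mm must be >= 0")
        if not self.gas_po2 > 0:
            raise ValueError("gas_po2 must be > 0")
        if self.mode == "pfc":
            if self.medium_depth_below_mm is not None:
                raise ValueError("pfc mode has no medium below the slice")
        else:
            if self.medium_depth_below_mm is None:
                object.__setattr__(self, "medium_depth_below_mm", 1.0)
            if not self.medium_depth_below_mm > 0:
                raise ValueError("medium_depth_below_mm must be > 0")


@dataclass(frozen=True)
class GridResolution:
    """Node counts per layer (vertex-centred; interface nodes are shared)."""

    nx: int = 24
    nz_tissue: int = 13
    nz_medium_above: int = 21
    nz_medium_below: int = 21

    def __post_init__(self) -> None:
        for name in ("nx", "nz_tissue", "nz_medium_above", "nz_medium_below"):
            if getattr(self, name) < 3:
                raise ValueError("resolution must be >= 3 nodes across every layer")


@dataclass
class DomainLayout:
    """Discretized culture cross-section.

    Node arrays are indexed ``[iz, jx]`` with ``z`` increasing upward from the
    vessel bottom.  Cell (dual-grid) arrays have shape ``(nz-1, nx-1)``.
    ``capacity`` is the per-node storage alpha*V, ``tissue_volume`` the tissue
    share of each node's control volume (per unit thickness in the third
    dimension, so 2D areas stand in for volumes).
    """

    x: np.ndarray
    z: np.ndarray
    cell_is_tissue: np.ndarray
    cell_K: np.ndarray
    cell_alpha: np.ndarray
    dirichlet_mask: np.ndarray
    dirichlet_value: np.ndarray
    capacity: np.ndarray
    volume: np.ndarray
    tissue_volume: np.ndarray
    core_index: tuple[int, int]
    config: CultureConfiguration | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.z), len(self.x)

    @property
    def n_nodes(self) -> int:
        return len(self.z) * len(self.x)

    @property
    def tissue_mask(self) -> np.ndarray:
        """Nodes whose control volume contains any tissue."""
        return self.tissue_volume > 0


@dataclass
class OxygenField:
    """Gridded pO2 (mmHg) at one instant."""

    po2: np.ndarray
    time_s: float

    def __post_init__(self) -> None:
        if np.any(self.po2 < 0):
            raise ValueError("pO2 must be non-negative")


@dataclass
class SimulationResult:
    """Snapshot traces of a transient run (times in hours)."""

    times_h: np.ndarray
    core_po2: np.ndarray
    anoxic_fraction: np.ndarray
    min_tissue_po2: np.ndarray
    mass_balance_max_rel_error: float
    layout: DomainLayout | None = None
    kinetics: KineticsSpec | None = None
    fields: list[OxygenField] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "core_po2_mmHg": self.core_po2,
                "anoxic_fraction": self.anoxic_fraction,
                "min_tissue_po2_mmHg": self.min_tissue_po2,
            }
        )


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------


def _layered_grid(layers: Sequence[tuple[str, float, int]]) -> tuple[np.ndarray, list[str]]:
    """Concatenate per-layer linspaces sharing interface nodes.

    ``layers`` are (phase name, thickness_m, n_nodes) from bottom to top.
    Returns node coordinates and the phase name of every z-interval.
    """
    z = [0.0]
    interval_phase: list[str] = []
    for name, thickness, n_nodes in layers:
        if thickness <= 0:
            raise ValueError(f"layer {name!r} has non-positive thickness")
        if n_nodes < 3:
            raise ValueError("resolution must be >= 3 nodes across every layer")
        seg = np.linspace(z[-1], z[-1] + thickness, n_nodes)
        z.extend(seg[1:].tolist())
        interval_phase.extend([name] * (n_nodes - 1))
    return np.asarray(z), interval_phase


def _finalize_layout(
    x: np.ndarray,
    z: np.ndarray,
    cell_is_tissue: np.ndarray,
    phases: Mapping[str, TransportPhase],
    dirichlet_mask: np.ndarray,
    dirichlet_value: np.ndarray,
    tissue_z_mid: float,
    config: CultureConfiguration | None,
) -> DomainLayout:
    med = phases["medium"]
    tis = phases["tissue"]
    cell_K = np.where(cell_is_tissue, tis.permeability_K, med.permeability_K)
    cell_alpha = np.where(cell_is_tissue, tis.solubility_alpha, med.solubility_alpha)

    dz = np.diff(z)[:, None]
    dx = np.diff(x)[None, :]
    cell_area = dz * dx  # per unit thickness in y

    def scatter_quarters(cell_vals: np.ndarray) -> np.ndarray:
        out = np.zeros((len(z), len(x)))
        q = cell_vals / 4.0
        out[:-1, :-1] += q
        out[:-1, 1:] += q
        out[1:, :-1] += q
        out[1:, 1:] += q
        return out

    capacity = scatter_quarters(cell_alpha * cell_area)
    volume = scatter_quarters(cell_area)
    tissue_volume = scatter_quarters(np.where(cell_is_tissue, cell_area, 0.0))

    # core = tissue node nearest (lateral centre, tissue mid-depth)
    x_mid = 0.5 * (x[0] + x[-1])
    zz, xx = np.meshgrid(z, x, indexing="ij")
    dist2 = (zz - tissue_z_mid) ** 2 + (xx - x_mid) ** 2
    dist2[tissue_volume == 0] = np.inf
    core_flat = int(np.argmin(dist2))
    core_index = (core_flat // len(x), core_flat % len(x))

    return DomainLayout(
        x=x,
        z=z,
        cell_is_tissue=cell_is_tissue,
        cell_K=cell_K,
        cell_alpha=cell_alpha,
        dirichlet_mask=dirichlet_mask,
        dirichlet_value=dirichlet_value,
        capacity=capacity,
        volume=volume,
        tissue_volume=tissue_volume,
        core_index=core_index,
        config=config,
    )


def build_domain(
    config: CultureConfiguration,
    phases: Mapping[str, TransportPhase] | None = None,
    resolution: GridResolution | None = None,
) -> DomainLayout:
    """Build the layered 2D domain for one culture configuration.

    Transwell (bottom to top): zero-flux dish bottom, lower medium, continuity
    membrane interface, tissue, upper medium, Dirichlet gas boundary at the
    free surface.  PFC: Dirichlet gas boundary at the vessel floor (the
    gas-permeable membrane spans the dish) and at the medium free surface.
    The slice occupies ``slice_width`` centred laterally, flanked by medium in
    the lateral margins; lateral outer edges are zero flux.
    """
    phases = dict(default_phases() if phases is None else phases)
    for required in ("medium", "tissue"):
        if required not in phases:
            raise ValueError(f"phases must include {required!r}")
    resolution = resolution or GridResolution()

    t_m = config.slice_thickness_um * 1e-6
    a_m = config.medium_depth_above_mm * 1e-3
    w_m = config.slice_width_mm * 1e-3
    margin_m = config.lateral_margin_mm * 1e-3

    if config.mode == "transwell":
        b_m = config.medium_depth_below_mm * 1e-3
        layers = [
            ("medium", b_m, resolution.nz_medium_below),
            ("tissue", t_m, resolution.nz_tissue),
            ("medium", a_m, resolution.nz_medium_above),
        ]
        tissue_z0 = b_m
    else:
        layers = [
            ("tissue", t_m, resolution.nz_tissue),
            ("medium", a_m, resolution.nz_medium_above),
        ]
        tissue_z0 = 0.0

    z, interval_phase = _layered_grid(layers)
    width_total = w_m + 2 * margin_m
    if w_m > width_total + 1e-15:
        raise ValueError("tissue wider than domain")
    x = np.linspace(0.0, width_total, resolution.nx)

    x_centers = 0.5 * (x[:-1] + x[1:])
    in_slice = (x_centers >= margin_m - 1e-15) & (x_centers <= margin_m + w_m + 1e-15)
    tissue_rows = np.array([p == "tissue" for p in interval_phase])
    cell_is_tissue = tissue_rows[:, None] & in_slice[None, :]

    dirichlet_mask = np.zeros((len(z), len(x)), dtype=bool)
    dirichlet_value = np.zeros((len(z), len(x)))
    dirichlet_mask[-1, :] = True  # medium free surface
    dirichlet_value[-1, :] = config.gas_po2
    if config.mode == "pfc":
        dirichlet_mask[0, :] = True
        dirichlet_value[0, :] = config.gas_po2

    return _finalize_layout(
        x,
        z,
        cell_is_tissue,
        phases,
        dirichlet_mask,
        dirichlet_value,
        tissue_z_mid=tissue_z0 + t_m / 2.0,
        config=config,
    )


def build_slab(
    thickness_um: float,
    nz: int,
    phase: TransportPhase = TISSUE,
    p_top: float = 150.0,
    p_bottom: float | None = 150.0,
    nx: int = 3,
    width_mm: float = 1.0,
) -> DomainLayout:
    """A single-phase 1D slab (laterally uniform), for solver validation.

    ``p_bottom=None`` leaves the bottom face insulated (zero flux).
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    z, _ = _layered_grid([("tissue", thickness_um * 1e-6, nz)])
    x = np.linspace(0.0, width_mm * 1e-3, nx)
    cell_is_tissue = np.ones((len(z) - 1, len(x) - 1), dtype=bool)

    phases = {"medium": MEDIUM, "tissue": phase}
    dirichlet_mask = np.zeros((len(z), len(x)), dtype=bool)
    dirichlet_value = np.zeros((len(z), len(x)))
    dirichlet_mask[-1, :] = True
    dirichlet_value[-1, :] = p_top
    if p_bottom is not None:
        dirichlet_mask[0, :] = True
        dirichlet_value[0, :] = p_bottom

    return _finalize_layout(
        x,
        z,
        cell_is_tissue,
        phases,
        dirichlet_mask,
        dirichlet_value,
        tissue_z_mid=thickness_um * 1e-6 / 2.0,
        config=None,
    )


# ---------------------------------------------------------------------------
# discrete operator
# ---------------------------------------------------------------------------


class _System:
    """Assembled FV operator on one layout (Dirichlet nodes eliminated)."""

    def __init__(self, layout: DomainLayout):
        self.layout = layout
        nz, nx = layout.shape
        z, x = layout.z, layout.x
        dz = np.diff(z)
        dx = np.diff(x)
        Kc = layout.cell_K

        # conductance of vertical edges (iz,j)-(iz+1,j): cells (iz, j-1), (iz, j)
        gz = np.zeros((nz - 1, nx))
        t = Kc * (dx[None, :] / 2.0) / dz[:, None]
        gz[:, :-1] += t
        gz[:, 1:] += t
        # conductance of horizontal edges (i,jx)-(i,jx+1): cells (i-1, jx), (i, jx)
        gx = np.zeros((nz, nx - 1))
        t = Kc * (dz[:, None] / 2.0) / dx[None, :]
        gx[:-1, :] += t
        gx[1:, :] += t

        def nid(i, j):
            return i * nx + j

        rows, cols, data = [], [], []
        ii, jj = np.meshgrid(np.arange(nz - 1), np.arange(nx), indexing="ij")
        a = nid(ii, jj).ravel()
        b = nid(ii + 1, jj).ravel()
        g = gz.ravel()
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        data += [-g, -g, g, g]

        ii, jj = np.meshgrid(np.arange(nz), np.arange(nx - 1), indexing="ij")
        a = nid(ii, jj).ravel()
        b = nid(ii, jj + 1).ravel()
        g = gx.ravel()
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        data += [-g, -g, g, g]

        n = nz * nx
        A = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

        self.free = ~layout.dirichlet_mask.ravel()
        self.fixed = ~self.free
        self.p_fixed = layout.dirichlet_value.ravel()[self.fixed]
        self.A_ff = A[self.free][:, self.free].tocsr()
        self.A_fd = A[self.free][:, self.fixed].tocsr()
        self.capacity_f = layout.capacity.ravel()[self.free]
        self.tissue_vol_f = layout.tissue_volume.ravel()[self.free]
        # row sums of Dirichlet couplings, for boundary-flux bookkeeping
        self.g_fd = -np.asarray(self.A_fd.sum(axis=1)).ravel()
        self.b_dirichlet = -self.A_fd @ self.p_fixed

    def full(self, p_free: np.ndarray) -> np.ndarray:
        out = np.empty(self.layout.n_nodes)
        out[self.free] = p_free
        out[self.fixed] = self.p_fixed
        return out.reshape(self.layout.shape)

    def consumption_coeff(self, p_ref: np.ndarray, kin: KineticsSpec) -> np.ndarray:
        """Diagonal c such that R*V ~= c * p_new (linearized Michaelis–Menten).

        The anoxic shutoff is exactly zero below the threshold and ramps
        linearly to full Michaelis–Menten over [thr, 2*thr]; the continuous
        ramp keeps the discrete dynamics free of on/off chatter at the
        threshold.
        """
        denom = np.maximum(p_ref, 0.0) + kin.km
        denom = np.maximum(denom, 1e-30)
        c = kin.r_max * self.tissue_vol_f / denom
        if kin.shutoff_below_threshold:
            thr = kin.anoxia_threshold
            c = c * np.clip(p_ref / thr - 1.0, 0.0, 1.0)
        return c


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def steady_state(
    layout: DomainLayout,
    kinetics: KineticsSpec,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> OxygenField:
    """Fixed point of the discrete reaction–diffusion system.

    Picard iteration with lagged Michaelis–Menten kinetics; the zeroth-order
    limit (km = 0) is handled as a constant sink with active-set shutoff so
    the closed-form slab solutions are reproduced.
    """
    if not layout.dirichlet_mask.any():
        raise ValueError("steady state requires at least one Dirichlet boundary")
    sys_ = _System(layout)
    kin = kinetics
    p = np.full(int(sys_.free.sum()), float(sys_.p_fixed.max() if sys_.p_fixed.size else 0.0))

    for _ in range(max_iter):
        if kin.km > 0:
            c = sys_.consumption_coeff(p, kin)
            lhs = sys_.A_ff + sp.diags(c)
            rhs = sys_.b_dirichlet
        else:
            active = sys_.tissue_vol_f > 0
            if kin.shutoff_below_threshold:
                active &= p >= kin.anoxia_threshold
            lhs = sys_.A_ff
            rhs = sys_.b_dirichlet - kin.r_max * sys_.tissue_vol_f * active
        p_new = spla.spsolve(lhs.tocsc(), rhs)
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta <= tol * max(1.0, float(np.max(np.abs(p)))):
            break
    else:
        raise RuntimeError("steady_state did not converge within the iteration cap")

    p = np.clip(p, 0.0, None)
    return OxygenField(po2=sys_.full(p), time_s=np.inf)


def simulate(
    layout: DomainLayout,
    kinetics: KineticsSpec,
    duration_h: float,
    dt_s: float = 30.0,
    initial: OxygenField | float | None = None,
    snapshot_every_s: float = 600.0,
    store_fields: bool = False,
) -> SimulationResult:
    """Transient run: backward-Euler steps with Picard-resolved kinetics.

    ``initial`` defaults to medium equilibrated at the gas tension (uniform at
    the maximum Dirichlet value).  Snapshots record the core pO2 (tissue
    centroid node), the minimum tissue pO2 and the anoxic tissue fraction.
    The scheme is unconditionally stable; ``dt_s`` only controls accuracy.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    sys_ = _System(layout)
    kin = kinetics

    if initial is None:
        p0_val = float(layout.dirichlet_value.max()) if layout.dirichlet_mask.any() else 0.0
        p_full = np.full(layout.shape, p0_val)
    elif isinstance(initial, OxygenField):
        p_full = np.array(initial.po2, dtype=float)
        if p_full.shape != layout.shape:
            raise ValueError("initial field shape does not match layout")
    else:
        p_full = np.full(layout.shape, float(initial))
    p = p_full.ravel()[sys_.free]

    n_steps = int(round(duration_h * 3600.0 / dt_s))
    snap_stride = max(1, int(round(snapshot_every_s / dt_s)))
    m_over_dt = sys_.capacity_f / dt_s

    tissue_nodes = sys_.tissue_vol_f > 0
    tv = sys_.tissue_vol_f[tissue_nodes]

    def record(t_s: float, p_free: np.ndarray, interval_min: float | None = None):
        full = sys_.full(p_free)
        pt = p_free[tissue_nodes]
        now_min = float(pt.min()) if pt.size else np.nan
        times.append(t_s / 3600.0)
        core.append(full[layout.core_index])
        # running minimum over the snapshot interval, so brief excursions
        # below the anoxia threshold between snapshots are not missed
        minp.append(now_min if interval_min is None else min(now_min, interval_min))
        afrac.append(float(tv[pt < kin.anoxia_threshold].sum() / tv.sum()) if tv.size else np.nan)
        if store_fields:
            fields.append(OxygenField(po2=full.copy(), time_s=t_s))

    times: list[float] = []
    core: list[float] = []
    minp: list[float] = []
    afrac: list[float] = []
    fields: list[OxygenField] = []
    record(0.0, p)

    max_rel_imbalance = 0.0
    p_max_allowed = max(float(p.max(initial=0.0)), float(sys_.p_fixed.max(initial=0.0)))
    interval_min = np.inf

    p_scale = max(1.0, float(sys_.p_fixed.max(initial=1.0)))
    for step in range(1, n_steps + 1):
        # Picard iteration within the step: the Michaelis–Menten/shutoff
        # coefficients must be consistent with the end-of-step field, or hard
        # switching at the anoxia threshold chatters between steps.
        rhs = m_over_dt * p + sys_.b_dirichlet
        p_new = p
        for _ in range(30):
            c = sys_.consumption_coeff(p_new, kin)
            lhs = (sys_.A_ff + sp.diags(m_over_dt + c)).tocsc()
            p_next = spla.spsolve(lhs, rhs)
            done = np.max(np.abs(p_next - p_new)) <= 1e-9 * p_scale
            p_new = p_next
            if done:
                break

        if not np.all(np.isfinite(p_new)):
            raise FloatingPointError("transient solve diverged (NaN/inf)")
        if p_new.min() < -1e-9 * max(1.0, p_max_allowed):
            raise FloatingPointError("negative pO2 produced by transient scheme")
        p_new = np.clip(p_new, 0.0, None)

        # discrete balance: influx - consumption = storage change (exact)
        influx = float((sys_.b_dirichlet - sys_.g_fd * p_new).sum())
        consumed = float((c * p_new).sum())
        storage = float((sys_.capacity_f * (p_new - p)).sum()) / dt_s
        scale = max(abs(influx), abs(consumed), abs(storage), 1e-300)
        max_rel_imbalance = max(max_rel_imbalance, abs(influx - consumed - storage) / scale)

        p = p_new
        if tissue_nodes.any():
            interval_min = min(interval_min, float(p[tissue_nodes].min()))
        if step % snap_stride == 0 or step == n_steps:
            record(step * dt_s, p, interval_min)
            interval_min = np.inf

    return SimulationResult(
        times_h=np.asarray(times),
        core_po2=np.asarray(core),
        anoxic_fraction=np.asarray(afrac),
        min_tissue_po2=np.asarray(minp),
        mass_balance_max_rel_error=max_rel_imbalance,
        layout=layout,
        kinetics=kin,
        fields=fields if store_fields else None,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def anoxic_fraction(
    po2: np.ndarray | OxygenField,
    tissue_volume: np.ndarray,
    threshold: float = 0.1,
) -> float:
    """Volume-weighted fraction of tissue below ``threshold`` (mmHg).

    2D node areas stand in for volume (uniform third dimension).
    """
    p = po2.po2 if isinstance(po2, OxygenField) else np.asarray(po2)
    w = np.asarray(tissue_volume, dtype=float)
    if p.shape != w.shape:
        raise ValueError("po2 and tissue_volume shapes differ")
    total = w.sum()
    if total <= 0:
        raise ValueError("empty tissue mask")
    return float(w[p < threshold].sum() / total)


def anoxia_onset(result: SimulationResult, threshold: float | None = None) -> float | None:
    """Earliest snapshot time (h) at which any tissue node is below threshold."""
    if len(result.times_h) < 2:
        raise ValueError("result must contain at least 2 snapshots")
    if threshold is None:
        threshold = result.kinetics.anoxia_threshold if result.kinetics else 0.1
    below = result.min_tissue_po2 < threshold
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return None
    return float(result.times_h[idx[0]])


def ocr_sweep(
    configs: Sequence[CultureConfiguration],
    ocr_values: Sequence[float],
    duration_h: float,
    kinetics: KineticsSpec | None = None,
    phases: Mapping[str, TransportPhase] | None = None,
    resolution: GridResolution | None = None,
    dt_s: float = 60.0,
    snapshot_every_s: float = 600.0,
) -> pd.DataFrame:
    """Terminal anoxic fraction for each configuration x OCR combination."""
    ocr_values = list(ocr_values)
    if any(v <= 0 for v in ocr_values):
        raise ValueError("ocr_values must be positive")
    if sorted(ocr_values) != ocr_values:
        raise ValueError("ocr_values must be sorted ascending")
    base = kinetics or KineticsSpec()
    rows = []
    for config in configs:
        layout = build_domain(config, phases=phases, resolution=resolution)
        for ocr in ocr_values:
            kin = KineticsSpec(
                r_max=ocr,
                km=base.km,
                anoxia_threshold=base.anoxia_threshold,
                shutoff_below_threshold=base.shutoff_below_threshold,
            )
            res = simulate(
                layout, kin, duration_h, dt_s=dt_s, snapshot_every_s=snapshot_every_s
            )
            onset = anoxia_onset(res)
            rows.append(
                {
                    "mode": config.mode,
                    "ocr": ocr,
                    "anoxic_fraction": float(res.anoxic_fraction[-1]),
                    "onset_h": np.nan if onset is None else onset,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibrated study configurations
# ---------------------------------------------------------------------------

#: Calibrated transwell geometry (see docs/methods.md).  A late anoxia onset
#: requires the upper unstirred medium film to throttle supply to just below
#: the slice's Michaelis–Menten demand while a deep lower medium column acts
#: as a slowly draining diffusive oxygen reservoir; the film depth was frozen
#: by bisection (`calibrate_transwell_medium_depth`) at CALIBRATED_RESOLUTION
#: and CALIBRATED_DT_S so that onset lands at the 16 h the near-critical
#: supply-to-demand balance implies.
TRANSWELL_CALIBRATED_DEPTH_ABOVE_MM = 0.0971484375
TRANSWELL_CALIBRATED_DEPTH_BELOW_MM = 10.0

CALIBRATED_RESOLUTION = GridResolution(nx=6, nz_tissue=13, nz_medium_above=9, nz_medium_below=61)
CALIBRATED_DT_S = 30.0


def calibrated_transwell_config() -> CultureConfiguration:
    """Transwell geometry whose oxygen budget matches the published model."""
    return CultureConfiguration(
        mode="transwell",
        medium_depth_above_mm=TRANSWELL_CALIBRATED_DEPTH_ABOVE_MM,
        medium_depth_below_mm=TRANSWELL_CALIBRATED_DEPTH_BELOW_MM,
        lateral_margin_mm=0.0,
    )


def calibrated_pfc_config() -> CultureConfiguration:
    return CultureConfiguration(mode="pfc", medium_depth_above_mm=1.0)


def calibrate_transwell_medium_depth(
    target_onset_h: float = 16.0,
    bracket_mm: tuple[float, float] = (0.09, 0.105),
    medium_depth_below_mm: float = TRANSWELL_CALIBRATED_DEPTH_BELOW_MM,
    kinetics: KineticsSpec | None = None,
    resolution: GridResolution = CALIBRATED_RESOLUTION,
    dt_s: float = CALIBRATED_DT_S,
    duration_h: float = 24.0,
    snapshot_every_s: float = 600.0,
    tol_h: float = 0.2,
    max_iter: int = 60,
    phases: Mapping[str, TransportPhase] | None = None,
) -> tuple[float, list[dict]]:
    """Bisect the upper-medium film depth so anoxia onset matches the target.

    Onset time decreases monotonically with film depth (a thicker unstirred
    film throttles the top supply, the transwell's only steady oxygen source,
    while the lower medium column of ``medium_depth_below_mm`` sets the
    reservoir timescale).  Returns the calibrated depth (mm) and a log of
    every trial.
    """
    kin = kinetics or KineticsSpec()
    log: list[dict] = []

    def onset_at(depth_mm: float) -> float:
        config = CultureConfiguration(
            mode="transwell",
            medium_depth_above_mm=depth_mm,
            medium_depth_below_mm=medium_depth_below_mm,
            lateral_margin_mm=0.0,
        )
        layout = build_domain(config, phases=phases, resolution=resolution)
        res = simulate(layout, kin, duration_h, dt_s=dt_s, snapshot_every_s=snapshot_every_s)
        onset = anoxia_onset(res)
        value = np.inf if onset is None else onset
        log.append({"depth_mm": depth_mm, "onset_h": value})
        return value

    lo, hi = bracket_mm
    onset_lo = onset_at(lo)
    onset_hi = onset_at(hi)
    if onset_lo <= target_onset_h:
        raise ValueError("lower bracket already reaches anoxia before the target onset")
    if onset_hi >= target_onset_h:
        raise ValueError("upper bracket never reaches anoxia early enough")

    best = (np.inf, lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        onset = onset_at(mid)
        err = abs(onset - target_onset_h) if np.isfinite(onset) else np.inf
        if err < best[0]:
            best = (err, mid)
        if err <= tol_h:
            return mid, log
        if onset > target_onset_h:
            lo = mid  # supply still too good; deepen the column
        else:
            hi = mid
    return best[1], log
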