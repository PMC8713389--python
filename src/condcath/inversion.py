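"""Lookup-table inversion of the conductance models.

The analytical conversion from measured conductance ``G`` back to cavity
radius ``R`` is not available in closed form, so each model/configuration is
sampled on a radius grid into a characteristic lookup table whose strict
monotonicity is verified at build time, and the inverse map ``R(G)`` is
evaluated by monotone piecewise-cubic (PCHIP) interpolation on the
``(G, R)`` knots.

Measured conductances falling outside the table span are clamped to the
nearest endpoint radius and flagged (``in_range=False``) rather than
rejected, since noisy measurements can fall marginally outside.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .acm_models import ACMS, PLATE_VALIDITY_FLAG, TissueModel, total_conductance
from .field_core import ElectrodeConfig

__all__ = [
    "LookupTable",
    "EstimationResult",
    "LookupTableBuildError",
    "build_lookup_table",
    "radius_from_conductance",
    "write_table_csv",
    "read_table_csv",
]

DEFAULT_R_MARGIN = 0.5  # mm above r0 for the default grid lower bound
DEFAULT_R_MAX = 80.0  # mm, covers severely dilated ventricles
DEFAULT_GRID_SIZE = 2000


class LookupTableBuildError(RuntimeError):
    """Raised when the sampled conductance map is not strictly monotone."""


@dataclass(frozen=True)
class LookupTable:
    """Monotone sampled map between cavity radius and total conductance."""

    acm: str
    cfg: ElectrodeConfig
    tissue: TissueModel
    radii: np.ndarray  # mm, strictly increasing
    conductances: np.ndarray  # S, strictly increasing
    build_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        conds = np.asarray(self.conductances, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductances", conds)
        if radii.shape != conds.shape or radii.ndim != 1 or radii.size < 2:
            raise ValueError("radii and conductances must be matching 1-D arrays, length >= 2")
        for name, arr in (("radii", radii), ("conductances", conds)):
            if not np.all(np.diff(arr) > 0):
                k = int(np.argmin(np.diff(arr)))
                raise LookupTableBuildError(
                    f"{name} not strictly increasing on "
                    f"[{arr[k]!r}, {arr[k + 1]!r}] (knots {k}..{k + 1})"
                )

    @property
    def _inverse(self) -> PchipInterpolator:
        # cached monotone interpolant on the (G, R) knots
        cache = self.build_metadata.setdefault("_cache", {})
        if "inverse" not in cache:
            cache["inverse"] = PchipInterpolator(self.conductances, self.radii)
        return cache["inverse"]


@dataclass(frozen=True)
class EstimationResult:
    """Radius estimate for one measured conductance."""

    G_measured: float
    R_estimated: float
    acm: str
    in_range: bool
    warnings: tuple[str, ...] = ()


def build_lookup_table(
    acm: str,
    cfg: ElectrodeConfig,
    tissue: TissueModel,
    R_min: float | None = None,
    R_max: float = DEFAULT_R_MAX,
    n: int = DEFAULT_GRID_SIZE,
    enforce_validity: bool = False,
) -> LookupTable:
    """Sample the ACM's total conductance on a uniform radius grid (mm).

    Raises :class:`LookupTableBuildError` if the sampled map is not strictly
    monotone.  For the plate model, a grid extending beyond ``R = L`` lies
    outside the model's intended validity: with ``enforce_validity=True``
    this is an error, otherwise the table is built (monotonicity permitting)
    and the validity warning recorded in the metadata.
    """
    if acm not in ACMS:
        raise ValueError(f"unknown ACM {acm!r}; expected one of {ACMS}")
    if R_min is None:
        R_min = cfg.r0 + DEFAULT_R_MARGIN
    if not cfg.r0 < R_min < R_max:
        raise ValueError(f"grid bounds must satisfy r0 < R_min < R_max, got [{R_min}, {R_max}]")
    if n < 2:
        raise ValueError(f"grid size must be >= 2, got {n}")

    warnings_: list[str] = []
    if acm == "plate" and R_max > cfg.L:
        if enforce_validity:
            raise LookupTableBuildError(
                f"plate-model table with R_max={R_max} mm exceeds the validity bound "
                f"R < L = {cfg.L} mm; shrink the grid or disable strict validity"
            )
        warnings_.append(PLATE_VALIDITY_FLAG)

    radii = np.linspace(R_min, R_max, n)
    conds = np.array([total_conductance(acm, float(r), cfg, tissue).G_total for r in radii])
    meta = {
        "R_min_mm": float(R_min),
        "R_max_mm": float(R_max),
        "n": int(n),
        "warnings": tuple(warnings_),
        "built_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return LookupTable(acm=acm, cfg=cfg, tissue=tissue, radii=radii,
                       conductances=conds, build_metadata=meta)


def radius_from_conductance(G: float, table: LookupTable) -> EstimationResult:
    """Invert a measured conductance (S) to a cavity radius (mm).

    Exact at the table knots; out-of-span conductances clamp to the nearest
    endpoint radius with ``in_range=False``.
    """
    if not math.isfinite(G):
        raise ValueError(f"measured conductance must be finite, got {G!r}")
    warns = tuple(table.build_metadata.get("warnings", ()))
    g_lo, g_hi = table.conductances[0], table.conductances[-1]
    if G < g_lo:
        return EstimationResult(G, float(table.radii[0]), table.acm, False,
                                warns + ("conductance below table span",))
    if G > g_hi:
        return EstimationResult(G, float(table.radii[-1]), table.acm, False,
                                warns + ("conductance above table span",))
    return EstimationResult(G, float(table._inverse(G)), table.acm, True, warns)


# ---------------------------------------------------------------------------
# CSV serialization (radius_mm, conductance_S with '#' metadata header)
# ---------------------------------------------------------------------------

_META_FIELDS = (
    ("acm", str),
    ("r0_mm", float),
    ("L_mm", float),
    ("d_mm", float),
    ("sigma_bl_S_per_m", float),
    ("sigma_m_S_per_m", float),
    ("sigma_ba_S_per_m", float),
    ("wall_thickness_mm", float),
    ("background_outer_radius_mm", lambda v: None if v == "none" else float(v)),
    ("R_min_mm", float),
    ("R_max_mm", float),
    ("n", int),
)


def write_table_csv(table: LookupTable, path) -> None:
    """Write a lookup table with a reproducible '#'-prefixed metadata header.

    Floats are serialized with 17 significant digits so a read round-trips to
    full precision; the in-memory build timestamp is deliberately omitted so
    repeated runs produce byte-identical files.
    """
    t = table.tissue
    bg = "none" if t.background_outer_radius is None else repr(t.background_outer_radius)
    meta = {
        "acm": table.acm,
        "r0_mm": repr(table.cfg.r0),
        "L_mm": repr(table.cfg.L),
        "d_mm": repr(table.cfg.d),
        "sigma_bl_S_per_m": repr(t.sigma_bl),
        "sigma_m_S_per_m": repr(t.sigma_m),
        "sigma_ba_S_per_m": repr(t.sigma_ba),
        "wall_thickness_mm": repr(t.wall_thickness),
        "background_outer_radius_mm": bg,
        "R_min_mm": repr(table.build_metadata.get("R_min_mm", float(table.radii[0]))),
        "R_max_mm": repr(table.build_metadata.get("R_max_mm", float(table.radii[-1]))),
        "n": str(table.radii.size),
    }
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    for w in table.build_metadata.get("warnings", ()):
        lines.append(f"# warning = {w}")
    lines.append("radius_mm,conductance_S")
    for r, g in zip(table.radii, table.conductances):
        lines.append(f"{float(r)!r},{float(g)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_table_csv(path) -> LookupTable:
    """Read a lookup table written by :func:`write_table_csv`."""
    meta_raw: dict[str, str] = {}
    warnings_: list[str] = []
    radii: list[float] = []
    conds: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                key, value = key.strip(), value.strip()
                if key == "warning":
                    warnings_.append(value)
                else:
                    meta_raw[key] = value
            elif line.startswith("radius_mm"):
                continue
            else:
                r, g = line.split(",")
                radii.append(float(r))
                conds.append(float(g))
    meta = {name: conv(meta_raw[name]) for name, conv in _META_FIELDS}
    cfg = ElectrodeConfig(r0=meta["r0_mm"], L=meta["L_mm"], d=meta["d_mm"])
    tissue = TissueModel(
        sigma_bl=meta["sigma_bl_S_per_m"],
        sigma_m=meta["sigma_m_S_per_m"],
        sigma_ba=meta["sigma_ba_S_per_m"],
        wall_thickness=meta["wall_thickness_mm"],
        background_outer_radius=meta["background_outer_radius_mm"],
    )
    build_meta = {
        "R_min_mm": meta["R_min_mm"],
        "R_max_mm": meta["R_max_mm"],
        "n": meta["n"],
        "warnings": tuple(warnings_),
    }
    return LookupTable(acm=meta["acm"], cfg=cfg, tissue=tissue,
                       radii=np.array(radii), conductances=np.array(conds),
                       build_metadata=build_meta)
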