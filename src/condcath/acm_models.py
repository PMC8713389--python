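"""Closed-form conductance models G(R) for the three analytical methods.

Each analytical calculation method (ACM) maps the radius ``R`` of a
cylindrical blood cavity to the conductance a tetrapolar catheter measures:

``wei``
    The classical two-point-charge model: current through the mid-plane
    annulus ``[r0, R]`` divided by the on-axis voltage between the
    measurement electrodes.  Generalized here with annulus extensions for the
    muscle wall and background compartments.
``plate``
    Models field compression at the blood-muscle boundary by replacing one
    drive sphere with a uniformly charged plate spanning the cavity
    cross-section.  Intended for small cavities (R < L); muscle and
    background terms reuse the Wei-style annulus extension.
``lead``
    Restores reciprocity between drive and measurement fields: the two
    injection configurations (spacing d and spacing L) share one voltage but
    produce different currents, which enter as their geometric mean.

Convention: current integrals over the ``z = 0`` plane use the
surface-referenced radial coordinate ``rho - r0`` in the sphere fields of the
plate and lead models (radial distance measured from the electrode surface),
while on-axis voltage integrals use the ideal point-charge field.  The Wei
model keeps the ideal field throughout.  Every closed form is certified
against the quadrature oracle in :mod:`condcath.field_core`.

All lengths are in mm, conductivities in S/m, conductances in S (reported as
positive magnitudes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .field_core import MM, ElectrodeConfig, SourceStrength

__all__ = [
    "TissueModel",
    "ConductanceBreakdown",
    "ACMS",
    "wei_conductance",
    "annulus_conductance_wei_style",
    "plate_blood_conductance",
    "plate_total_conductance",
    "lead_currents",
    "lead_voltage",
    "lead_compartment_conductance",
    "lead_total_conductance",
    "wei_total_conductance",
    "total_conductance",
]

#: identifiers of the implemented analytical calculation methods
ACMS = ("wei", "plate", "lead")

#: factor by which the default bounded background extends beyond d
BACKGROUND_EXTENT_FACTOR = 5.0


@dataclass(frozen=True)
class TissueModel:
    """Conductivities and radial extents of the tissue compartments.

    Parameters
    ----------
    sigma_bl : float
        Blood (or saline) conductivity, S/m.
    sigma_m : float
        Muscle / wall conductivity, S/m (0 for an insulating wall).
    sigma_ba : float
        Background conductivity, S/m.
    wall_thickness : float
        Radial thickness ``b`` of the muscle compartment, mm.
    background_outer_radius : float or None
        Outer radius of the background compartment, mm.  ``None`` selects the
        default bounded extent ``5*d``; ``math.inf`` selects the true
        unbounded limit of the closed forms.
    """

    sigma_bl: float
    sigma_m: float = 0.0
    sigma_ba: float = 0.0
    wall_thickness: float = 10.0
    background_outer_radius: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_bl", "sigma_m", "sigma_ba"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.wall_thickness < 0:
            raise ValueError(f"wall_thickness must be non-negative, got {self.wall_thickness}")

    def outer_radius(self, cfg: ElectrodeConfig) -> float:
        """Resolved background outer radius in mm (may be ``math.inf``)."""
        if self.background_outer_radius is None:
            return BACKGROUND_EXTENT_FACTOR * cfg.d
        return self.background_outer_radius


@dataclass(frozen=True)
class ConductanceBreakdown:
    """Per-compartment and total conductance of one ACM at one radius."""

    acm: str
    G_blood: float
    G_muscle: float
    G_background: float
    validity_flags: tuple[str, ...] = ()

    @property
    def G_total(self) -> float:
        return self.G_blood + self.G_muscle + self.G_background


# ---------------------------------------------------------------------------
# Wei model
# ---------------------------------------------------------------------------


def _wei_prefactor(cfg: ElectrodeConfig, sigma: float) -> float:
    d, L = cfg.d_m, cfg.L_m
    return math.pi * sigma * d * (d * d - L * L) / (2.0 * L)


def _wei_bracket_term(cfg: ElectrodeConfig, radius_m: float) -> float:
    if math.isinf(radius_m):
        return 0.0
    return 1.0 / math.sqrt(cfg.d_m**2 + 4.0 * radius_m**2)


def wei_conductance(R: float, cfg: ElectrodeConfig, sigma: float) -> float:
    """Blood conductance of the classical two-point-charge model (S).

    ``G = pi*sigma*d*(d^2-L^2)/(2L) * [1/sqrt(d^2+4*r0^2) - 1/sqrt(d^2+4*R^2)]``
    — the mid-plane current over the annulus ``[r0, R]`` divided by the
    on-axis voltage across the measurement pair.  Strictly increasing in R,
    zero at ``R = r0``, bounded by the ``R -> inf`` limit.
    """
    if R < cfg.r0:
        raise ValueError(f"cavity radius R={R} mm must be >= electrode radius r0={cfg.r0} mm")
    return annulus_conductance_wei_style(cfg.r0, R, cfg, sigma)


def annulus_conductance_wei_style(
    R_in: float, R_out: float, cfg: ElectrodeConfig, sigma: float
) -> float:
    """Wei-style conductance with the current integral over [R_in, R_out] mm.

    Extends the blood-term current integral to an arbitrary annulus; used for
    the muscle (``[R, R+b]``) and background (``[R+b, R_ba]``) compartments.
    ``R_out`` may be ``math.inf``.  Telescopes exactly:
    ``annulus(a,b) + annulus(b,c) == annulus(a,c)``.
    """
    if R_in < cfg.r0:
        raise ValueError(f"inner radius {R_in} mm must be >= electrode radius r0={cfg.r0} mm")
    if R_in > R_out:
        raise ValueError(f"annulus bounds inverted: R_in={R_in} > R_out={R_out}")
    bracket = _wei_bracket_term(cfg, R_in * MM) - _wei_bracket_term(cfg, R_out * MM)
    return _wei_prefactor(cfg, sigma) * bracket


def wei_total_conductance(
    R: float, cfg: ElectrodeConfig, tissue: TissueModel
) -> ConductanceBreakdown:
    """Wei blood term plus Wei-style annulus muscle/background terms.

    The classical (insulating-surround) Wei model of the literature is the
    ``sigma_m = sigma_ba = 0`` case.
    """
    b = tissue.wall_thickness
    r_ba = tissue.outer_radius(cfg)
    return ConductanceBreakdown(
        acm="wei",
        G_blood=wei_conductance(R, cfg, tissue.sigma_bl),
        G_muscle=annulus_conductance_wei_style(R, R + b, cfg, tissue.sigma_m),
        G_background=annulus_conductance_wei_style(R + b, r_ba, cfg, tissue.sigma_ba),
    )


# ---------------------------------------------------------------------------
# plate model
# ---------------------------------------------------------------------------


def _plate_current_bracket(R_m: float, r0_m: float, d_m: float) -> float:
    """Dimensionless mid-plane current factor of the plate field.

    Sphere term uses the surface-referenced radial coordinate; plate term
    contributes the uniform flux ``1 - r0^2/R^2`` over the annulus.
    """
    root = math.sqrt(4.0 * (r0_m - R_m) ** 2 + d_m * d_m)
    sphere = 1.0 - (4.0 * r0_m * (r0_m - R_m) + d_m * d_m) / (d_m * root)
    plate = 1.0 - (r0_m / R_m) ** 2
    return sphere + plate


def _plate_voltage_bracket(R_m: float, L_m: float, d_m: float) -> float:
    """On-axis voltage factor (1/m): point-charge sphere plus plate term."""
    sphere = 2.0 / (d_m - L_m) - 2.0 / d_m
    plate = (2.0 / R_m**2) * (L_m / 2.0 + R_m - math.hypot(L_m / 2.0, R_m))
    return sphere + plate


def plate_blood_conductance(R: float, cfg: ElectrodeConfig, sigma_bl: float) -> float:
    """Blood-cavity conductance of the plate model (S).

    ``G = pi*sigma_bl * B_I(R) / B_V(R)`` with the current factor ``B_I``
    taken over the mid-plane annulus ``[r0, R]`` and the voltage factor
    ``B_V`` over twice the axial segment ``[0, L/2]`` (the configuration is
    treated as symmetric about the mid-plane).  Valid for ``R < L``; larger
    radii are computed but carry a validity warning in the breakdown.

    At ``R = r0`` the current factor vanishes identically (zero-cavity
    limit), so 0 is returned exactly.
    """
    if R < cfg.r0:
        raise ValueError(f"cavity radius R={R} mm must be >= electrode radius r0={cfg.r0} mm")
    num = _plate_current_bracket(R * MM, cfg.r0_m, cfg.d_m)
    den = _plate_voltage_bracket(R * MM, cfg.L_m, cfg.d_m)
    return math.pi * sigma_bl * num / den


PLATE_VALIDITY_FLAG = "plate model applied beyond its validity range (R >= L)"


def plate_total_conductance(
    R: float, cfg: ElectrodeConfig, tissue: TissueModel
) -> ConductanceBreakdown:
    """Plate blood term plus Wei-style annulus muscle/background terms."""
    b = tissue.wall_thickness
    r_ba = tissue.outer_radius(cfg)
    flags = (PLATE_VALIDITY_FLAG,) if R >= cfg.L else ()
    return ConductanceBreakdown(
        acm="plate",
        G_blood=plate_blood_conductance(R, cfg, tissue.sigma_bl),
        G_muscle=annulus_conductance_wei_style(R, R + b, cfg, tissue.sigma_m),
        G_background=annulus_conductance_wei_style(R + b, r_ba, cfg, tissue.sigma_ba),
        validity_flags=flags,
    )


# ---------------------------------------------------------------------------
# lead model
# ---------------------------------------------------------------------------


def _lead_current_primitive(rho_m: float, r0_m: float, x_m: float) -> float:
    """Antiderivative (in rho) of the surface-referenced mid-plane current."""
    if math.isinf(rho_m):
        return 4.0 * r0_m / (x_m * x_m)
    u = rho_m - r0_m
    h = x_m / 2.0
    root = math.sqrt(h * h + u * u)
    return -1.0 / root + r0_m * u / (h * h * root)


def lead_currents(
    R: float,
    cfg: ElectrodeConfig,
    sigma: float,
    rho_in: float | None = None,
    rho_out: float | None = None,
    V0: float = 1.0,
) -> tuple[float, float]:
    """Closed-form currents (I_d, I_L) in A over an annulus (defaults [r0, R]).

    Each is the mid-plane flux of the surface-referenced two-charge field
    with injection spacing ``d`` or ``L`` respectively; both vanish for an
    empty annulus and swap when ``d`` and ``L`` are interchanged.
    ``rho_out`` may be ``math.inf``.
    """
    if rho_in is None:
        rho_in = cfg.r0
    if rho_out is None:
        rho_out = R
    if rho_in > rho_out:
        raise ValueError(f"annulus bounds inverted: rho_in={rho_in} > rho_out={rho_out}")
    q = V0 * cfg.r0_m
    a, b = rho_in * MM, rho_out * MM
    out = []
    for x_m in (cfg.d_m, cfg.L_m):
        diff = _lead_current_primitive(b, cfg.r0_m, x_m) - _lead_current_primitive(
            a, cfg.r0_m, x_m
        )
        out.append(-2.0 * math.pi * sigma * q * x_m * diff)
    return out[0], out[1]


def lead_voltage(cfg: ElectrodeConfig, V0: float = 1.0) -> float:
    """Shared reciprocal voltage V_all (V), identical for both injection roles.

    ``V_all = 8*V0*r0*lo/(hi^2 - lo^2)`` with ``lo``/``hi`` the smaller and
    larger electrode spacing — manifestly symmetric under interchanging the
    drive and measurement pairs.
    """
    lo, hi = sorted((cfg.L_m, cfg.d_m))
    return 8.0 * V0 * cfg.r0_m * lo / (hi * hi - lo * lo)


def lead_compartment_conductance(I_d: float, I_L: float, V_all: float) -> float:
    """Reciprocity-restoring conductance ``sqrt(I_d*I_L)/|V_all|`` (S).

    The geometric mean balances the two injection roles; it is invariant
    under interchanging them.  The currents must not have opposite signs.
    """
    prod = I_d * I_L
    if prod < 0:
        raise ValueError(
            f"currents with opposite signs (I_d={I_d}, I_L={I_L}) describe a "
            "non-physical configuration"
        )
    return math.sqrt(prod) / abs(V_all)


def _lead_annulus_conductance(
    cfg: ElectrodeConfig, sigma: float, rho_in: float, rho_out: float
) -> float:
    if sigma == 0.0 or rho_in == rho_out:
        return 0.0
    I_d, I_L = lead_currents(0.0, cfg, sigma, rho_in=rho_in, rho_out=rho_out)
    return lead_compartment_conductance(I_d, I_L, lead_voltage(cfg))


def lead_total_conductance(
    R: float, cfg: ElectrodeConfig, tissue: TissueModel
) -> ConductanceBreakdown:
    """Lead-model conductance: blood, muscle and background compartments.

    Each compartment applies the reciprocity construction to its own annulus
    and conductivity; the shared voltage ``V_all`` is unchanged.
    """
    if R < cfg.r0:
        raise ValueError(f"cavity radius R={R} mm must be >= electrode radius r0={cfg.r0} mm")
    b = tissue.wall_thickness
    r_ba = tissue.outer_radius(cfg)
    return ConductanceBreakdown(
        acm="lead",
        G_blood=_lead_annulus_conductance(cfg, tissue.sigma_bl, cfg.r0, R),
        G_muscle=_lead_annulus_conductance(cfg, tissue.sigma_m, R, R + b),
        G_background=_lead_annulus_conductance(cfg, tissue.sigma_ba, R + b, r_ba),
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_TOTALS = {
    "wei": wei_total_conductance,
    "plate": plate_total_conductance,
    "lead": lead_total_conductance,
}


def total_conductance(
    acm: str, R: float, cfg: ElectrodeConfig, tissue: TissueModel
) -> ConductanceBreakdown:
    """Total conductance breakdown of the named ACM at radius ``R`` (mm)."""
    try:
        fn = _TOTALS[acm]
    except KeyError:
        raise ValueError(f"unknown ACM {acm!r}; expected one of {ACMS}") from None
    return fn(R, cfg, tissue)
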