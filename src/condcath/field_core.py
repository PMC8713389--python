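"""Electric-field primitives and a numerical-quadrature oracle.

A tetrapolar conductance catheter drives current through an outer electrode
pair (spacing ``d``) and senses voltage across an inner pair (spacing ``L``).
The analytical conductance models in :mod:`condcath.acm_models` idealize the
drive electrodes as small charged spheres of radius ``r0`` on the catheter
axis and derive closed-form currents and voltages from the resulting
electrostatic fields.

This module defines those fields explicitly and evaluates the defining
integrals *numerically*:

* the injected current as the flux of current density through the catheter
  mid-plane (``z = 0``) over a radial annulus, and
* the sensed voltage as the line integral of the axial field between the
  measurement electrodes.

The quadrature routines are deliberately independent of the closed forms so
they can certify them (see the oracle-equivalence tests).

Unit convention: all lengths cross the public API in millimetres and are
converted to metres internally, so with conductivities in S/m the currents,
voltages and conductances come out in SI units (A, V, S).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.integrate import IntegrationWarning, quad

MM = 1e-3  # metres per millimetre

#: requested relative quadrature tolerance
QUAD_EPSREL = 1e-10
#: absolute floor so near-zero integrals do not spuriously fail
QUAD_EPSABS = 1e-15


class SingularFieldError(ValueError):
    """Raised when a field or integral is evaluated at a non-integrable point."""


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to converge."""


# ---------------------------------------------------------------------------
# geometry and source strength
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeConfig:
    """Tetrapolar catheter geometry (all lengths in mm).

    Parameters
    ----------
    r0 : float
        Radius of the spherical injection electrodes.
    L : float
        Spacing of the inner (voltage-measurement) electrode pair.
    d : float
        Spacing of the outer (current-injection) electrode pair.
    """

    r0: float
    L: float
    d: float

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"electrode radius r0 must be positive, got {self.r0}")
        if not 0 < self.L < self.d:
            raise ValueError(
                f"electrode spacings must satisfy 0 < L < d, got L={self.L}, d={self.d}"
            )
        if not self.r0 < self.L / 2:
            raise ValueError(
                f"injection spheres must not overlap the measurement electrodes: "
                f"require r0 < L/2, got r0={self.r0}, L={self.L}"
            )

    @property
    def r0_m(self) -> float:
        return self.r0 * MM

    @property
    def L_m(self) -> float:
        return self.L * MM

    @property
    def d_m(self) -> float:
        return self.d * MM


@dataclass(frozen=True)
class FieldPoint:
    """Observation point in cylindrical coordinates (mm); azimuthal symmetry."""

    rho: float
    z: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"radial coordinate must be non-negative, got {self.rho}")


@dataclass(frozen=True)
class SourceStrength:
    """Drive strength of the injection electrodes.

    ``V0`` is the electrode potential; the equivalent point-charge strength is
    ``Q/(4*pi*eps) = V0 * r0`` (a sphere of radius ``r0`` at potential ``V0``).
    """

    V0: float = 1.0

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise ValueError(f"drive potential V0 must be positive, got {self.V0}")

    def q(self, cfg: ElectrodeConfig) -> float:
        """Point-charge strength Q/(4*pi*eps) in V*m."""
        return self.V0 * cfg.r0_m


# ---------------------------------------------------------------------------
# field components (SI units internally)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointChargeField:
    """Coulomb field of one charge at ``(rho=0, z=z0_m)``.

    ``q_vm`` is the signed strength Q/(4*pi*eps) in V*m.  ``radial_offset_m``
    replaces the radial coordinate by ``rho - offset`` in the field expression,
    referencing radial distance to the electrode *surface* rather than the
    axis; this is the convention behind the lead-model current integrals.
    """

    q_vm: float
    z0_m: float
    radial_offset_m: float = 0.0

    def e_components(self, rho_m: float, z_m: float) -> tuple[float, float]:
        u = rho_m - self.radial_offset_m
        w = z_m - self.z0_m
        r2 = u * u + w * w
        if r2 == 0.0:
            raise SingularFieldError(
                f"field evaluated at the charge location (rho={rho_m / MM} mm, "
                f"z={z_m / MM} mm)"
            )
        r3 = r2 * math.sqrt(r2)
        return self.q_vm * u / r3, self.q_vm * w / r3

    def axial_point_charges(self) -> list[tuple[float, float]]:
        # on the axis the field is singular only for an unshifted charge
        if self.radial_offset_m == 0.0:
            return [(self.z0_m, self.q_vm)]
        return []


@dataclass(frozen=True)
class UniformDiskField:
    """Purely axial field of a uniformly charged disk of radius ``R_m`` at z=0.

    On-axis magnitude ``q*(2/R^2)*(1 - |z|/sqrt(z^2+R^2))``, extended to all
    rho (the model treats the plate field as uniform over the cross-section)
    and antisymmetrically to z < 0.
    """

    q_vm: float
    R_m: float

    def e_components(self, rho_m: float, z_m: float) -> tuple[float, float]:
        s = 1.0 if z_m >= 0 else -1.0  # z=0 evaluated as the z->0+ limit
        az = abs(z_m)
        ez = self.q_vm * (2.0 / self.R_m**2) * s * (1.0 - az / math.hypot(az, self.R_m))
        return 0.0, ez

    def axial_point_charges(self) -> list[tuple[float, float]]:
        return []


@dataclass(frozen=True)
class SuperposedField:
    """Linear superposition of field components."""

    components: tuple = field(default_factory=tuple)

    def e_components(self, rho_m: float, z_m: float) -> tuple[float, float]:
        erho = ez = 0.0
        for c in self.components:
            dr, dz = c.e_components(rho_m, z_m)
            erho += dr
            ez += dz
        return erho, ez

    def axial_point_charges(self) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = []
        for c in self.components:
            out.extend(c.axial_point_charges())
        return out


def two_charge_field(
    q_vm: float, spacing_m: float, radial_offset_m: float = 0.0
) -> SuperposedField:
    """Opposite charges ``+q`` at ``z=+spacing/2`` and ``-q`` at ``z=-spacing/2``."""
    return SuperposedField(
        (
            PointChargeField(q_vm, +spacing_m / 2, radial_offset_m),
            PointChargeField(-q_vm, -spacing_m / 2, radial_offset_m),
        )
    )


# ---------------------------------------------------------------------------
# public field constructors (mm in, V/m out)
# ---------------------------------------------------------------------------


def dipole_field(
    p: FieldPoint,
    cfg: ElectrodeConfig,
    s: SourceStrength,
    spacing: float,
    radial_offset: float = 0.0,
) -> tuple[float, float]:
    """Field (E_rho, E_z in V/m) of the two-point-charge injection arrangement.

    ``spacing`` (mm) is the charge separation: ``cfg.d`` for the drive pair,
    ``cfg.L`` when modelling injection at the measurement electrodes (lead
    model).  ``radial_offset`` selects the surface-referenced radial
    convention used by the lead current integrals (normally 0 or ``cfg.r0``).
    """
    fld = two_charge_field(s.q(cfg), spacing * MM, radial_offset * MM)
    return fld.e_components(p.rho * MM, p.z * MM)


def plate_superposition_field(
    p: FieldPoint, cfg: ElectrodeConfig, s: SourceStrength, R: float
) -> tuple[float, float]:
    """Field (V/m) of the plate model: charged sphere plus charged plate.

    A sphere at ``z=+d/2`` carrying ``-Q`` is superposed with a uniformly
    charged plate (``+Q``, radius ``R`` mm) in the ``z=0`` plane, compressing
    the field into the blood-filled cavity.  The plate term is purely axial.
    """
    if R <= cfg.r0:
        raise ValueError(f"plate radius R={R} mm must exceed the electrode radius r0={cfg.r0} mm")
    fld = plate_model_field(cfg, s, R)
    return fld.e_components(p.rho * MM, p.z * MM)


def plate_model_field(
    cfg: ElectrodeConfig, s: SourceStrength, R: float, radial_offset: float | None = None
) -> SuperposedField:
    """Internal constructor of the plate-model field (lengths in mm).

    ``radial_offset`` defaults to ``cfg.r0`` (the surface-referenced sphere
    term that the closed-form current uses); pass 0 for the ideal point-charge
    sphere term used on the axis.
    """
    off = cfg.r0 if radial_offset is None else radial_offset
    q = s.q(cfg)
    return SuperposedField(
        (
            PointChargeField(-q, cfg.d_m / 2, off * MM),
            UniformDiskField(+q, R * MM),
        )
    )


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------


def _quad(f, a: float, b: float, what: str, points=None) -> float:
    # the principal-value remainder is cancellation noise near a subtracted
    # charge; QUADPACK then warns even though the explicit error check below
    # still guards convergence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        val, err = quad(
            f, a, b, epsabs=QUAD_EPSABS, epsrel=QUAD_EPSREL, limit=200, points=points
        )
    if err > max(1e-6 * abs(val), 1e-9):
        raise QuadratureError(
            f"quadrature of {what} on [{a}, {b}] did not converge "
            f"(value {val!r}, error estimate {err!r})"
        )
    return val


def numeric_current(fld, sigma: float, rho_in: float, rho_out: float) -> float:
    """Current (A) through the z=0 plane over the annulus [rho_in, rho_out] mm.

    Evaluates ``2*pi*sigma * \\int E_z(rho, 0) rho drho`` by adaptive
    quadrature; the sign follows the +z surface normal.
    """
    if rho_in > rho_out:
        raise ValueError(f"annulus bounds inverted: rho_in={rho_in} > rho_out={rho_out}")
    if rho_in == rho_out:
        return 0.0
    a, b = rho_in * MM, rho_out * MM

    def integrand(rho_m: float) -> float:
        return fld.e_components(rho_m, 0.0)[1] * rho_m

    return 2.0 * math.pi * sigma * _quad(integrand, a, b, "current density on z=0 plane")


def numeric_voltage(fld, z_a: float, z_b: float) -> float:
    """Potential difference (V) ``-\\int_{z_a}^{z_b} E_z(0, z) dz`` (mm bounds).

    Point charges lying strictly inside the integration segment make the
    on-axis integral a principal value: the Coulomb term is antisymmetric
    about the charge, so its divergences cancel.  The on-axis field of such a
    charge is exactly ``q*sgn(z-z0)/(z-z0)^2``, whose principal value over
    the segment is elementary; those components are therefore integrated
    analytically and removed from the field, and the remaining (smooth)
    components are handled by adaptive quadrature.
    """
    if z_a == z_b:
        return 0.0
    sign = 1.0
    if z_a > z_b:
        z_a, z_b = z_b, z_a
        sign = -1.0
    a, b = z_a * MM, z_b * MM

    tol = 1e-12 * max(abs(a), abs(b), 1.0)
    inner: list[tuple[float, float]] = []
    for z0, qc in fld.axial_point_charges():
        if abs(z0 - a) < tol or abs(z0 - b) < tol:
            raise SingularFieldError(
                f"integration endpoint coincides with a charge at z={z0 / MM} mm"
            )
        if a < z0 < b:
            inner.append((z0, qc))

    smooth = _without_axial_charges(fld, inner)
    total = 0.0
    if smooth is not None:

        def integrand(z_m: float) -> float:
            return smooth.e_components(0.0, z_m)[1]

        total = _quad(integrand, a, b, "axial field between measurement electrodes")
    for z0, qc in inner:  # exact principal value of the singular Coulomb terms
        total += qc * (1.0 / (z0 - a) - 1.0 / (b - z0))
    return -sign * total


def _without_axial_charges(fld, charges: list[tuple[float, float]]):
    """Field with the listed on-axis point charges removed (None if empty)."""
    if not charges:
        return fld
    keys = {(z0, qc) for z0, qc in charges}

    def keep(component) -> bool:
        return not (
            isinstance(component, PointChargeField)
            and component.radial_offset_m == 0.0
            and (component.z0_m, component.q_vm) in keys
        )

    if isinstance(fld, PointChargeField):
        return fld if keep(fld) else None
    if isinstance(fld, SuperposedField):
        kept = tuple(c for c in fld.components if keep(c))
        return SuperposedField(kept) if kept else None
    raise SingularFieldError(
        "cannot integrate through an interior on-axis charge of this field type"
    )
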