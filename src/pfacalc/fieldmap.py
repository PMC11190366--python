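"""Electric field of two parallel needle electrodes in the monolayer plane.

Two cylindrical conductors (radius ``a``, centers ``D`` apart, potentials
±V/2) are modeled in 2-D by their equivalent line charges at (±b, 0) with
b = sqrt((D/2)² − a²). Writing Λ = V / (2·arccosh(D/(2a))), the in-plane
field magnitude is

    |E|(P) = 2 Λ b / (r₁ r₂),

with r₁, r₂ the distances from P to the two line charges. Iso-magnitude
contours are Cassini ovals r₁r₂ = const: a single oval enclosing both
electrodes for low thresholds, splitting into two lobes (through the
lemniscate) at high thresholds. The oval area has the closed form
2 m² E((b/m)⁴) with m² = r₁r₂ on the contour and E the complete elliptic
integral of the second kind, which makes threshold↔area inversion cheap.

An independent finite-difference Laplace solver (:func:`numeric_field`)
provides the numeric oracle: Dirichlet ±V/2 on the electrode boundaries with
Shortley–Weller cut-cell stencils, and a choice of outer boundary closure.
The default "open" closure averages the insulating (Neumann) and grounded
(Dirichlet 0) solves, cancelling the leading domain-truncation term that
either closure alone leaves on a finite box.

All lengths in mm; field magnitudes in kV/cm; the per-volt map is
voltage-independent (electrostatic linearity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import brentq
from scipy.sparse.linalg import spsolve
from scipy.special import ellipe

__all__ = [
    "ElectrodeGeometry",
    "AnalyticFieldMap",
    "NumericFieldMap",
    "IsolineResult",
    "analytic_field",
    "numeric_field",
    "isoline_area",
    "eft_from_area",
    "lesion_area",
    "UnattainableAreaError",
]

_VMM_TO_KVCM = 0.01  # V/mm -> kV/cm


class UnattainableAreaError(ValueError):
    """Requested enclosed area exceeds what the field map can produce."""

    def __init__(self, requested: float, attainable_max: float):
        self.requested = requested
        self.attainable_max = attainable_max
        super().__init__(
            f"requested area {requested:.4g} mm² exceeds the attainable maximum "
            f"{attainable_max:.4g} mm² for this map"
        )


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Two parallel cylindrical electrodes: radius ``a`` and spacing ``D`` (mm)."""

    radius: float = 0.35
    center_distance: float = 1.72

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("electrode radius must be positive")
        if not self.center_distance > 2 * self.radius:
            raise ValueError(
                "center_distance must exceed the electrode diameter "
                f"(D={self.center_distance}, 2a={2 * self.radius})"
            )

    @property
    def charge_half_separation(self) -> float:
        """b = sqrt((D/2)² − a²), mm."""
        return math.sqrt((self.center_distance / 2) ** 2 - self.radius**2)

    @property
    def footprint_area(self) -> float:
        """Total electrode cross-section area 2πa², mm²."""
        return 2 * math.pi * self.radius**2

    def lambda_per_volt(self) -> float:
        """Line-charge potential coefficient Λ/V = 1/(2·arccosh(D/2a))."""
        return 1.0 / (2.0 * math.acosh(self.center_distance / (2 * self.radius)))

    def inside_electrodes(self, x, y):
        """Boolean mask of points inside either conductor cross-section."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        half = self.center_distance / 2
        return ((x - half) ** 2 + y**2 <= self.radius**2) | (
            (x + half) ** 2 + y**2 <= self.radius**2
        )


@dataclass(frozen=True)
class IsolineResult:
    """Area enclosed by the |E| = threshold contour."""

    threshold: float  # kV/cm
    enclosed_area: float  # mm²
    electrode_area_subtracted: bool
    topology: str  # "single-oval" | "two-lobes"


class AnalyticFieldMap:
    """Closed-form two-line-charge field at a fixed applied voltage."""

    kind = "analytic"

    def __init__(self, geometry: ElectrodeGeometry, voltage: float):
        if not voltage > 0:
            raise ValueError("voltage must be positive")
        self.geometry = geometry
        self.voltage = float(voltage)

    @property
    def lam(self) -> float:
        """Λ = V / (2·arccosh(D/2a)), volts."""
        return self.voltage * self.geometry.lambda_per_volt()

    def _continued_magnitude(self, x, y):
        """|E| in kV/cm by the line-charge formula, continued through the
        conductor interiors (diverges at the charges)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        b = self.geometry.charge_half_separation
        r1r2 = np.abs((x + 1j * y) ** 2 - b**2)  # mm²
        with np.errstate(divide="ignore"):
            return 2 * self.lam * b / r1r2 * _VMM_TO_KVCM

    def magnitude(self, x, y):
        """|E| in kV/cm; NaN inside the conductor cross-sections, where the
        line-charge continuation is not the physical (zero) field."""
        e = self._continued_magnitude(x, y)
        return np.where(self.geometry.inside_electrodes(x, y), np.nan, e)

    def per_volt(self, x, y):
        """Field magnitude per applied volt, (kV/cm)/V."""
        return self.magnitude(x, y) / self.voltage

    def at_voltage(self, voltage: float) -> "AnalyticFieldMap":
        return AnalyticFieldMap(self.geometry, voltage)

    def cassini_parameter(self, threshold: float) -> float:
        """m² (mm²) of the Cassini contour r₁r₂ = m² at ``threshold`` kV/cm."""
        if not threshold > 0:
            raise ValueError("threshold must be positive")
        b = self.geometry.charge_half_separation
        return 2 * self.lam * b * _VMM_TO_KVCM / threshold


class NumericFieldMap:
    """Finite-difference field sampled on a uniform grid, bilinearly
    interpolated between nodes."""

    kind = "numeric"

    def __init__(self, geometry, voltage, xs, potential, residual):
        from scipy.interpolate import RegularGridInterpolator

        self.geometry = geometry
        self.voltage = float(voltage)
        self.xs = xs
        self.potential_grid = potential  # volts, indexed [ix, iy]
        self.residual = residual
        h = xs[1] - xs[0]
        ex, ey = np.gradient(-potential, h, h)
        emag = np.hypot(ex, ey) * _VMM_TO_KVCM  # V/mm -> kV/cm
        self._emag_grid = emag
        self._interp_e = RegularGridInterpolator(
            (xs, xs), emag, bounds_error=False, fill_value=0.0
        )
        self._interp_phi = RegularGridInterpolator(
            (xs, xs), potential, bounds_error=False, fill_value=0.0
        )

    def magnitude(self, x, y):
        pts = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
        out = self._interp_e(pts)
        return float(out[0]) if pts.ndim == 1 else out

    def potential(self, x, y):
        pts = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
        out = self._interp_phi(pts)
        return float(out[0]) if pts.ndim == 1 else out

    def per_volt(self, x, y):
        return self.magnitude(x, y) / self.voltage

    def at_voltage(self, voltage: float) -> "NumericFieldMap":
        scale = voltage / self.voltage
        return NumericFieldMap(
            self.geometry, voltage, self.xs, self.potential_grid * scale,
            self.residual * scale,
        )


def analytic_field(
    geometry: ElectrodeGeometry = ElectrodeGeometry(), voltage: float = 1.0
) -> AnalyticFieldMap:
    """Two-line-charge field map for ``geometry`` at ``voltage``."""
    return AnalyticFieldMap(geometry, voltage)


# ---------------------------------------------------------------------------
# finite-difference Laplace oracle
# ---------------------------------------------------------------------------


def _leg_fraction(x, y, dx, dy, h, cx, radius):
    """Fraction θ ∈ (0, 1] of the step (dx·h, dy·h) from (x, y) to the circle
    |P − (cx, 0)| = radius; 1 if the step does not cross it."""
    px, py = x - cx, y
    A = (dx * h) ** 2 + (dy * h) ** 2
    B = 2 * (px * dx * h + py * dy * h)
    C = px * px + py * py - radius * radius
    disc = B * B - 4 * A * C
    if disc < 0:
        return 1.0
    r = math.sqrt(disc)
    ts = [t for t in ((-B - r) / (2 * A), (-B + r) / (2 * A)) if 1e-12 < t <= 1.0]
    return min(ts) if ts else 1.0


def _solve_once(geometry, voltage, h, L, outer_bc):
    a = geometry.radius
    half = geometry.center_distance / 2
    n = int(round(L / h)) + 1
    xs = np.linspace(-L / 2, L / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    in_plus = (X - half) ** 2 + Y**2 <= a**2
    in_minus = (X + half) ** 2 + Y**2 <= a**2
    electrode = in_plus | in_minus
    vals = np.where(in_plus, voltage / 2, np.where(in_minus, -voltage / 2, 0.0))

    outer = np.zeros((n, n), bool)
    if outer_bc == "grounded":
        outer[0, :] = outer[-1, :] = outer[:, 0] = outer[:, -1] = True
    fixed = electrode | outer
    free = ~fixed
    idx = -np.ones((n, n), np.int64)
    nfree = int(free.sum())
    idx[free] = np.arange(nfree)

    # nodes needing Shortley-Weller legs: free with an electrode neighbor
    el_pad = np.zeros((n, n), bool)
    el_pad[1:, :] |= electrode[:-1, :]
    el_pad[:-1, :] |= electrode[1:, :]
    el_pad[:, 1:] |= electrode[:, :-1]
    el_pad[:, :-1] |= electrode[:, 1:]
    sw = free & el_pad
    regular = free & ~sw

    rows, cols, data = [], [], []
    rhs = np.zeros(nfree)
    dirs = ((1, 0), (-1, 0), (0, 1), (0, -1))

    # vectorized uniform 5-point stencil for regular free nodes
    ri, rj = np.where(regular)
    rrow = idx[ri, rj]
    diag = np.zeros(len(ri))
    for di, dj in dirs:
        ii, jj = ri + di, rj + dj
        inb = (ii >= 0) & (ii < n) & (jj >= 0) & (jj < n)
        # out-of-bounds neighbor: insulating mirror -> term drops entirely
        diag[inb] += 1.0
        nb_fixed = np.zeros(len(ri), bool)
        nb_fixed[inb] = fixed[ii[inb], jj[inb]]
        add = inb & nb_fixed
        np.add.at(rhs, rrow[add], vals[ii[add], jj[add]])
        keep = inb & ~nb_fixed
        rows.append(rrow[keep])
        cols.append(idx[ii[keep], jj[keep]])
        data.append(np.full(keep.sum(), -1.0))
    rows.append(rrow)
    cols.append(rrow)
    data.append(diag)

    # Shortley-Weller rows (short python loop: only the electrode rim)
    srows, scols, sdata = [], [], []
    for i, j in zip(*np.where(sw)):
        k = idx[i, j]
        x, y = xs[i], xs[j]
        for axis_dirs in (((1, 0), (-1, 0)), ((0, 1), (0, -1))):
            th = [1.0, 1.0]
            kind = [None, None]  # "free" | "dirichlet" | "mirror"
            ref = [0, 0]
            bval = [0.0, 0.0]
            for s, (di, dj) in enumerate(axis_dirs):
                ii, jj = i + di, j + dj
                if ii < 0 or ii >= n or jj < 0 or jj >= n:
                    kind[s] = "mirror"
                    continue
                if electrode[ii, jj]:
                    cx = half if in_plus[ii, jj] else -half
                    th[s] = max(_leg_fraction(x, y, di, dj, h, cx, a), 0.05)
                    kind[s] = "dirichlet"
                    bval[s] = vals[ii, jj]
                elif outer[ii, jj]:
                    kind[s] = "dirichlet"
                    bval[s] = 0.0
                else:
                    kind[s] = "free"
                    ref[s] = idx[ii, jj]
            if kind[0] == "mirror" and kind[1] == "mirror":
                continue
            for s in (0, 1):
                if kind[s] == "mirror":
                    o = 1 - s
                    c = 2.0
                    srows.append(k), scols.append(k), sdata.append(c)
                    if kind[o] == "dirichlet":
                        rhs[k] += c * bval[o]
                    else:
                        srows.append(k), scols.append(ref[o]), sdata.append(-c)
                    break
            else:
                te, tw = th
                ce = 2.0 / (te * (te + tw))
                cw = 2.0 / (tw * (te + tw))
                srows.append(k), scols.append(k), sdata.append(ce + cw)
                for s, c in ((0, ce), (1, cw)):
                    if kind[s] == "dirichlet":
                        rhs[k] += c * bval[s]
                    else:
                        srows.append(k), scols.append(ref[s]), sdata.append(-c)

    rows = np.concatenate(rows + [np.asarray(srows, np.int64)])
    cols = np.concatenate(cols + [np.asarray(scols, np.int64)])
    data = np.concatenate(data + [np.asarray(sdata, float)])
    A = sparse.csr_matrix((data, (rows, cols)), shape=(nfree, nfree))
    sol = spsolve(A, rhs)
    resid = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if not np.all(np.isfinite(sol)) or resid > 1e-8:
        raise RuntimeError(f"Laplace solve did not converge (relative residual {resid:.3g})")
    phi = np.where(fixed, vals, 0.0)
    phi[free] = sol
    return xs, phi, resid


def numeric_field(
    geometry: ElectrodeGeometry = ElectrodeGeometry(),
    voltage: float = 1.0,
    grid_spacing: float = 0.05,
    domain_size: float = 20.0,
    outer_bc: str = "open",
) -> NumericFieldMap:
    """Finite-difference Laplace solve of the two-electrode problem.

    Parameters
    ----------
    grid_spacing : float
        Node spacing h in mm; must resolve the electrodes (h ≤ a/5).
    domain_size : float
        Side length of the square solution box, mm (≥ 5·D).
    outer_bc : {"open", "insulating", "grounded"}
        Closure at the box edge. "insulating" (zero normal current) and
        "grounded" (φ=0) each leave an O((r/L)²) image bias of opposite
        sign; "open" averages the two solves and cancels it.
    """
    if not voltage > 0:
        raise ValueError("voltage must be positive")
    if grid_spacing > geometry.radius / 5 + 1e-12:
        raise ValueError(
            f"grid_spacing must be at most a/5 = {geometry.radius / 5:.3g} mm"
        )
    if domain_size < 5 * geometry.center_distance:
        raise ValueError(
            f"domain_size must be at least 5*D = {5 * geometry.center_distance:.3g} mm"
        )
    if outer_bc not in ("open", "insulating", "grounded"):
        raise ValueError(f"unknown outer_bc {outer_bc!r}")
    if outer_bc == "open":
        xs, phi_n, r1 = _solve_once(geometry, voltage, grid_spacing, domain_size, "insulating")
        _, phi_d, r2 = _solve_once(geometry, voltage, grid_spacing, domain_size, "grounded")
        return NumericFieldMap(geometry, voltage, xs, 0.5 * (phi_n + phi_d), max(r1, r2))
    xs, phi, resid = _solve_once(geometry, voltage, grid_spacing, domain_size, outer_bc)
    return NumericFieldMap(geometry, voltage, xs, phi, resid)


# ---------------------------------------------------------------------------
# isoline areas and inversion
# ---------------------------------------------------------------------------


def _cassini_oval_area(m2: float, b: float) -> float:
    """Closed-form area of the single-loop Cassini oval r₁r₂ = m² (m ≥ b):
    2 m² E((b²/m²)²), with E the complete elliptic integral (parameter
    convention). Tends to the circle area πm² as b → 0."""
    return float(2.0 * m2 * ellipe((b**2 / m2) ** 2))


def _polygonized_area(fmap, threshold: float, box: float, n: int = 1201) -> float:
    """Marching-squares area of {|E| ≥ threshold} inside [-box, box]².

    Conductor cross-sections count as enclosed: for the analytic map the
    line-charge continuation already exceeds any practical threshold there;
    for numeric maps the (zero-field) interiors are overwritten before
    contouring.
    """
    from skimage import measure

    xs = np.linspace(-box, box, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    if fmap.kind == "analytic":
        E = fmap._continued_magnitude(X, Y)
    else:
        E = fmap.magnitude(X, Y)
        E = np.where(fmap.geometry.inside_electrodes(X, Y), 10 * threshold, E)
    E = np.nan_to_num(E, posinf=1e12)
    h = xs[1] - xs[0]
    in_region = E >= threshold
    if (
        in_region[0, :].any()
        or in_region[-1, :].any()
        or in_region[:, 0].any()
        or in_region[:, -1].any()
    ):
        # region clipped by the sampling box: fall back to pixel counting
        return float(in_region.sum()) * h * h
    area = 0.0
    for contour in measure.find_contours(E, threshold):
        if not np.allclose(contour[0], contour[-1]):
            continue
        pts = contour * h  # to mm (origin shift irrelevant for shoelace)
        x, y = pts[:, 0], pts[:, 1]
        area += 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    return area


def _electrode_subtraction(fmap, threshold: float) -> float:
    """Electrode footprint area lying inside {|E| ≥ threshold}.

    Each conductor is tested on its boundary circle (the field minimum over
    the footprint under the analytic continuation); a fully-enclosed
    conductor contributes πa², a partially-enclosed one its sampled overlap.
    """
    g = fmap.geometry
    a, half = g.radius, g.center_distance / 2
    mag = fmap._continued_magnitude if fmap.kind == "analytic" else fmap.magnitude
    total = 0.0
    for cx in (half, -half):
        th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        ring = mag(cx + a * np.cos(th), a * np.sin(th))
        if np.all(ring >= threshold):
            total += math.pi * a**2
        elif np.any(ring >= threshold):
            rr = np.linspace(a / 40, a, 20)
            R, T = np.meshgrid(rr, th, indexing="ij")
            inside = mag(cx + R * np.cos(T), R * np.sin(T)) >= threshold
            total += float(inside.mean()) * math.pi * a**2
    return total


def isoline_area(
    fmap,
    threshold: float,
    subtract_electrodes: bool = False,
) -> IsolineResult:
    """Area of the region where |E| ≥ ``threshold`` (kV/cm).

    For the analytic map with a single-oval topology the closed-form Cassini
    area is used; other cases are polygonized by marching squares. With
    ``subtract_electrodes``, the conductor cross-sections inside the contour
    are removed (2πa² when both are enclosed).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    b = None
    if fmap.kind == "analytic":
        b = fmap.geometry.charge_half_separation
        m2 = fmap.cassini_parameter(threshold)
        topology = "single-oval" if m2 >= b**2 else "two-lobes"
        if topology == "single-oval":
            area = _cassini_oval_area(m2, b)
        else:
            box = math.sqrt(m2 + b**2) + 0.1
            area = _polygonized_area(fmap, threshold, box)
    else:
        box = fmap.xs[-1]
        area = _polygonized_area(fmap, threshold, box, n=len(fmap.xs))
        # topology by connectivity of the thresholded mask
        from scipy import ndimage

        X, Y = np.meshgrid(fmap.xs, fmap.xs, indexing="ij")
        mask = (
            np.where(
                fmap.geometry.inside_electrodes(X, Y), 10 * threshold,
                fmap.magnitude(X, Y),
            )
            >= threshold
        )
        nlab = ndimage.label(mask)[1]
        topology = "single-oval" if nlab <= 1 else "two-lobes"
    if subtract_electrodes:
        area = max(area - _electrode_subtraction(fmap, threshold), 0.0)
    return IsolineResult(
        threshold=threshold,
        enclosed_area=area,
        electrode_area_subtracted=subtract_electrodes,
        topology=topology,
    )


def _threshold_bracket(fmap) -> tuple[float, float]:
    """A (low, high) threshold bracket spanning the attainable area range."""
    g = fmap.geometry
    a, half = g.radius, g.center_distance / 2
    th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
    mag = fmap._continued_magnitude if fmap.kind == "analytic" else fmap.magnitude
    ring = np.concatenate(
        [np.asarray(mag(cx + a * np.cos(th), a * np.sin(th))) for cx in (half, -half)]
    )
    hi = float(np.max(ring)) * 0.999
    mid = float(mag(0.0, 0.0))
    return mid / 500.0, hi


def eft_from_area(
    fmap,
    death_area: float,
    subtract_electrodes: bool = False,
    tol: float = 1e-4,
) -> float:
    """Invert the isoline-area map: the threshold (kV/cm) whose contour
    encloses ``death_area`` mm².

    Root-bracketed bisection on the strictly decreasing area(threshold)
    curve; raises :class:`UnattainableAreaError` when the area exceeds the
    attainable range.
    """
    if not death_area > 0:
        raise ValueError("death_area must be positive")
    lo, hi = _threshold_bracket(fmap)

    def f(tau: float) -> float:
        return isoline_area(fmap, tau, subtract_electrodes).enclosed_area - death_area

    f_lo = f(lo)
    if f_lo < 0:
        raise UnattainableAreaError(death_area, f_lo + death_area)
    f_hi = f(hi)
    while f_hi > 0 and hi < 1e6:
        # threshold above every attainable contour shrinks the area to ~0;
        # extend the bracket until it straddles the root
        hi *= 2
        f_hi = f(hi)
    if f_hi > 0:
        raise UnattainableAreaError(death_area, 0.0)
    tau = brentq(f, lo, hi, xtol=1e-6, maxiter=200)
    # polish until the area tolerance is met (brentq xtol is on threshold)
    if abs(f(tau)) > tol:
        tau = brentq(f, max(lo, tau * 0.9), min(hi, tau * 1.1), xtol=1e-9, maxiter=200)
    return float(tau)


def lesion_area(fmap, eft: float, voltage: float | None = None) -> float:
    """Predicted lesion area (mm²): the isoline area at threshold ``eft``
    under ``voltage`` (defaults to the map's own applied voltage)."""
    if not eft > 0:
        raise ValueError("eft must be positive")
    if voltage is not None and voltage != fmap.voltage:
        fmap = fmap.at_voltage(voltage)
    hi = _threshold_bracket(fmap)[1]
    if eft >= hi:
        return 0.0
    return isoline_area(fmap, eft).enclosed_area
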