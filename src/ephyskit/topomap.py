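"""Spherical-spline topographies and scalp current density (SCD).

The interpolant over the unit sphere is the classic spherical spline: with
electrode positions E_i and measured potentials v_i,

    u(E) = c0 + sum_i c_i g_m(cos gamma(E, E_i)),

where gamma is the angle between two points and the kernel is the Legendre
series

    g_m(x) = (1/4pi) sum_{n>=1} (2n+1) / (n(n+1))^m  P_n(x).

The coefficients solve ``(G + lambda I) c + c0 = v`` subject to
``sum_i c_i = 0``; with ``lambda = 0`` the spline interpolates the data
exactly, a positive ``lambda`` trades fidelity for smoothness.

The surface Laplacian of the spline is available in closed form because the
Laplace-Beltrami operator maps P_n(cos gamma) to -n(n+1)/r^2 P_n(cos gamma):
term by term the exponent m drops to m - 1. The scalp current density
reported here is the *negative* surface Laplacian scaled to a head of radius
``r`` (meters),

    SCD(E) = +(1/r^2) sum_i c_i h_m(cos gamma(E, E_i)),
    h_m(x) = (1/4pi) sum_{n>=1} (2n+1) / (n(n+1))^(m-1) P_n(x),

so that a spherical-harmonic potential of degree n yields
``SCD = n(n+1)/r^2 * potential`` and a positive SCD marks a current source
(outward current). SCD is reference-free: adding a constant to all
potentials only shifts c0 and leaves every c_i, hence the SCD, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ContinuousRecord, EvokedRecord, Montage
from .errors import ParameterError

__all__ = ["SplineModel", "fit_spline", "interpolate", "interpolation_matrix",
           "scd", "scd_record", "project_map", "TopoMap2D", "legendre_kernel"]

DEFAULT_ORDER = 4
DEFAULT_TERMS = 50
DEFAULT_SCD_LAMBDA = 1e-5
DEFAULT_HEAD_RADIUS = 0.09  # m


def legendre_kernel(x: np.ndarray, m: int, n_terms: int = DEFAULT_TERMS,
                    tol: float = 1e-10) -> np.ndarray:
    """Evaluate ``(1/4pi) sum_n (2n+1)/(n(n+1))^m P_n(x)`` term by term.

    Uses the Legendre three-term recurrence; stops at ``n_terms`` or when a
    term's coefficient falls below ``tol``.
    """
    x = np.asarray(x, dtype=np.float64)
    p_prev = np.ones_like(x)   # P_0
    p_cur = x.copy()           # P_1
    total = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        coef = (2 * n + 1) / (n * (n + 1)) ** m
        total += coef * p_cur
        if coef < tol:
            break
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
    return total / (4.0 * np.pi)


@dataclass
class SplineModel:
    """Fitted spherical spline for one potential vector."""

    positions: np.ndarray  # n x 3 unit vectors
    m: int
    n_terms: int
    lam: float
    c: np.ndarray
    c0: float
    values: np.ndarray


def _solve_system(positions: np.ndarray, m: int, lam: float, n_terms: int
                  ) -> np.ndarray:
    """Inverse of the bordered spline system for the given electrode set."""
    n = positions.shape[0]
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    G = legendre_kernel(cosang, m, n_terms)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "singular spline system (coincident electrodes?): "
            f"{exc}") from None


def fit_spline(montage: Montage, values, m: int = DEFAULT_ORDER,
               lam: float = 0.0, n_terms: int = DEFAULT_TERMS) -> SplineModel:
    """Fit the spherical spline to one per-channel potential vector."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    n = len(montage)
    if values.size != n:
        raise ParameterError(f"{values.size} values for {n} electrodes")
    if n < 4:
        raise ParameterError("need at least 4 electrodes")
    if m < 2:
        raise ParameterError("spline order m must be >= 2")
    if lam < 0:
        raise ParameterError("regularization must be >= 0")
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    G = legendre_kernel(cosang, m, n_terms)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.concatenate([values, [0.0]])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "singular spline system (coincident electrodes?): "
            f"{exc}") from None
    return SplineModel(montage.positions.copy(), m, n_terms, lam,
                       sol[:n], float(sol[n]), values)


def interpolate(model: SplineModel, points) -> np.ndarray:
    """Evaluate the fitted potential at arbitrary points on the sphere."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    norms = np.linalg.norm(points, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ParameterError("zero-norm evaluation point")
    points = points / norms
    cosang = np.clip(points @ model.positions.T, -1.0, 1.0)
    G = legendre_kernel(cosang, model.m, model.n_terms)
    return G @ model.c + model.c0


def interpolation_matrix(montage: Montage, targets: np.ndarray,
                         m: int = DEFAULT_ORDER, lam: float = 0.0,
                         n_terms: int = DEFAULT_TERMS) -> np.ndarray:
    """Linear operator mapping electrode values to interpolated targets.

    The spline fit and evaluation are both linear in the data, so a fixed
    electrode set and fixed targets reduce to one matrix; used for
    bad-channel reconstruction over whole recordings.
    """
    n = len(montage)
    if n < 4:
        raise ParameterError("need at least 4 electrodes")
    Ainv = _solve_system(montage.positions, m, lam, n_terms)
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    targets = targets / np.linalg.norm(targets, axis=1, keepdims=True)
    cosang = np.clip(targets @ montage.positions.T, -1.0, 1.0)
    Gt = np.column_stack([legendre_kernel(cosang, m, n_terms),
                          np.ones(targets.shape[0])])
    return Gt @ Ainv[:, :n]


def scd_matrix(montage: Montage, m: int = DEFAULT_ORDER,
               lam: float = DEFAULT_SCD_LAMBDA,
               head_radius: float = DEFAULT_HEAD_RADIUS,
               n_terms: int = DEFAULT_TERMS) -> np.ndarray:
    """Linear operator mapping electrode potentials to SCD at electrodes."""
    if head_radius <= 0:
        raise ParameterError("head radius must be > 0")
    n = len(montage)
    if n < 4:
        raise ParameterError("need at least 4 electrodes")
    Ainv = _solve_system(montage.positions, m, lam, n_terms)
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    H = legendre_kernel(cosang, m - 1, n_terms)
    return (H @ Ainv[:n, :n]) / head_radius ** 2


def scd(montage: Montage, values, m: int = DEFAULT_ORDER,
        lam: float = DEFAULT_SCD_LAMBDA,
        head_radius: float = DEFAULT_HEAD_RADIUS,
        n_terms: int = DEFAULT_TERMS) -> np.ndarray:
    """Scalp current density at the electrodes for one potential vector.

    Units are input-units / m^2; positive values mark current sources.
    """
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    if values.size != len(montage):
        raise ParameterError(f"{values.size} values for {len(montage)} electrodes")
    return scd_matrix(montage, m, lam, head_radius, n_terms) @ values


def scd_record(x: ContinuousRecord | EvokedRecord, montage: Montage,
               m: int = DEFAULT_ORDER, lam: float = DEFAULT_SCD_LAMBDA,
               head_radius: float = DEFAULT_HEAD_RADIUS,
               n_terms: int = DEFAULT_TERMS):
    """Apply the SCD transform to every time sample of a record.

    Channel order must match the montage labels; units are rewritten to
    ``<unit>/m^2``.
    """
    mont = montage.subset(x.channel_names)  # also validates coverage
    T = scd_matrix(mont, m, lam, head_radius, n_terms)
    out = x.copy()
    out.data = T @ x.data
    out.channel_units = [f"{u}/m^2" for u in x.channel_units]
    return out


# ------------------------------------------------------------- 2-D mapping

@dataclass
class TopoMap2D:
    """Scalp map interpolated on a regular grid over the projected disc."""

    grid: np.ndarray        # res x res, NaN outside the mask
    x: np.ndarray           # grid coordinates along each axis
    y: np.ndarray
    projection: str
    electrode_xy: np.ndarray
    electrode_values: np.ndarray
    electrode_labels: list[str]

    def save_image(self, path, cmap: str = "RdBu_r") -> None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        extent = [self.x[0], self.x[-1], self.y[0], self.y[-1]]
        im = ax.imshow(self.grid, origin="lower", extent=extent, cmap=cmap)
        ax.scatter(self.electrode_xy[:, 0], self.electrode_xy[:, 1],
                   s=6, c="k")
        ax.set_aspect("equal")
        ax.set_title(f"{self.projection} projection")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(fig)


def _project(points: np.ndarray, projection: str) -> np.ndarray:
    x, y, z = points.T
    if projection == "orthogonal":
        return np.column_stack([x, y])
    if projection == "radial":
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        phi = np.arctan2(y, x)
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    raise ParameterError("projection must be 'radial' or 'orthogonal'")


def _back_project(u: np.ndarray, v: np.ndarray, projection: str) -> np.ndarray:
    if projection == "orthogonal":
        r2 = u ** 2 + v ** 2
        z = np.sqrt(np.clip(1.0 - r2, 0.0, None))
        return np.column_stack([u, v, z])
    theta = np.hypot(u, v)
    phi = np.arctan2(v, u)
    return np.column_stack([np.sin(theta) * np.cos(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(theta)])


def project_map(model: SplineModel, labels: list[str] | None = None,
                projection: str = "radial", grid_resolution: int = 64
                ) -> TopoMap2D:
    """Render the fitted spline as a 2-D scalp map.

    ``radial`` is the azimuthal-equidistant projection about the vertex
    (a point at polar angle theta lands at radius theta); ``orthogonal``
    simply drops the z coordinate. Grid points beyond the outermost
    electrode's projected radius are masked to NaN.
    """
    exy = _project(model.positions, projection)
    vals = interpolate(model, model.positions)
    rmax = float(np.max(np.hypot(exy[:, 0], exy[:, 1]))) * 1.02 + 1e-9
    axis = np.linspace(-rmax, rmax, grid_resolution)
    U, V = np.meshgrid(axis, axis)
    inside = np.hypot(U, V) <= rmax
    pts = _back_project(U[inside], V[inside], projection)
    grid = np.full(U.shape, np.nan)
    grid[inside] = interpolate(model, pts)
    if labels is None:
        labels = [f"E{i + 1}" for i in range(model.positions.shape[0])]
    return TopoMap2D(grid, axis, axis, projection, exy, vals, list(labels))


def depth_array_map(ev: EvokedRecord, contact_order: list[str] | None = None
                    ) -> np.ndarray:
    """Spatiotemporal map for a linear depth-electrode array.

    Rows follow ``contact_order`` (contact position along the shaft),
    columns are time samples; no spherical machinery is involved. The
    matrix can be rendered with any image tool or exported as ASCII.
    """
    if contact_order is None:
        return ev.data.copy()
    idx = [ev.channel_index(c) for c in contact_order]
    return ev.data[idx].copy()
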