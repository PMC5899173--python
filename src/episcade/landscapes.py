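"""Scalar performance functions over a 2D phenotype plane.

A :class:`Landscape` maps a pair of phenotypic coordinates (x, y) to a real
performance value.  The module provides the centred, stretched and rotated
Gaussian family used to illustrate how landscape geometry alone generates
sign epistasis, together with the geometric primitives that analysis rests
on: restricted-optimum lines (the locus of the best x for each fixed y and
vice versa), the global optimum, and a criterion that flags whether either
optimum line actually depends on the other coordinate — the necessary and
sufficient geometric condition for sign epistasis between mutations that
move along one axis only.

Coordinates are always the plane's *working* coordinates: for dissociation
constants this is log10(K) (see :mod:`episcade.cascade`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PhenotypeAxis",
    "Landscape",
    "GaussianParams",
    "OptimaLine",
    "BoundaryOptimumError",
    "make_rotated_gaussian",
    "restricted_optimum_line",
    "global_optimum",
    "sign_epistasis_criterion",
]

CascadePosition = Literal["upstream", "downstream", "abstract"]


class BoundaryOptimumError(RuntimeError):
    """Raised when a maximum is attained on the domain boundary and an
    interior optimum was required."""


@dataclass(frozen=True)
class PhenotypeAxis:
    """Metadata for one axis of a phenotype plane.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"X"`` or ``"log10 K_LacI"``.
    gene : str
        Gene identifier, or ``"abstract"`` for purely geometric landscapes.
    cascade_position : {"upstream", "downstream", "abstract"}
        Where the gene sits in the signalling hierarchy.  Must be
        ``"abstract"`` exactly when ``gene`` is ``"abstract"``.
    scale : {"linear", "log10"}
        Whether the working coordinate is the raw value or its log10.
    bounds : (float, float)
        Finite, strictly ordered working-coordinate bounds.
    """

    name: str
    gene: str = "abstract"
    cascade_position: CascadePosition = "abstract"
    scale: Literal["linear", "log10"] = "linear"
    bounds: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"axis bounds must be finite and ordered, got {self.bounds}")
        if (self.gene == "abstract") != (self.cascade_position == "abstract"):
            raise ValueError("cascade_position is 'abstract' iff gene is 'abstract'")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def span(self) -> float:
        return self.bounds[1] - self.bounds[0]


@dataclass(frozen=True)
class Landscape:
    """A scalar performance function f(x, y) with axis metadata.

    ``f`` must accept numpy arrays (broadcasting) and return finite values
    everywhere inside the axis bounds.
    """

    f: Callable[[np.ndarray, np.ndarray], np.ndarray]
    axis_x: PhenotypeAxis
    axis_y: PhenotypeAxis

    def __call__(self, x, y):
        return self.f(np.asarray(x, float), np.asarray(y, float))

    def grid(self, n: int = 201) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate on an ``n`` x ``n`` grid; returns (x, y, Z) with
        Z[i, j] = f(x[j], y[i])."""
        x = np.linspace(*self.axis_x.bounds, n)
        y = np.linspace(*self.axis_y.bounds, n)
        Z = self(x[None, :], y[:, None])
        if not np.all(np.isfinite(Z)):
            raise ValueError("landscape is not finite on its grid")
        return x, y, Z

    def to_csv(self, path, n: int = 201) -> None:
        """Export a grid evaluation as a CSV matrix: first row holds the x
        coordinates, first column the y coordinates (row = y, column = x)."""
        x, y, Z = self.grid(n)
        out = np.empty((n + 1, n + 1))
        out[0, 0] = np.nan
        out[0, 1:] = x
        out[1:, 0] = y
        out[1:, 1:] = Z
        np.savetxt(path, out, delimiter=",",
                   header=f"x-axis: {self.axis_x.name}; y-axis: {self.axis_y.name}",
                   comments="# ")


@dataclass(frozen=True)
class GaussianParams:
    """Rotation angle of the stretched Gaussian family, in radians,
    restricted to [0, pi)."""

    angle_a: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_a < np.pi):
            raise ValueError("angle must lie in [0, pi)")

    def matrix(self) -> np.ndarray:
        """The 2x2 quadratic-form matrix M of the rotated Gaussian.

        m11 = cos(a)^2/2 + 2 sin(a)^2,  m22 = sin(a)^2/2 + 2 cos(a)^2,
        m12 = m21 = -sin(2a)/4 + sin(2a) = (3/4) sin(2a).
        Note det(M) = 1 identically.
        """
        a = self.angle_a
        m11 = np.cos(a) ** 2 / 2.0 + 2.0 * np.sin(a) ** 2
        m22 = np.sin(a) ** 2 / 2.0 + 2.0 * np.cos(a) ** 2
        m12 = -np.sin(2 * a) / 4.0 + np.sin(2 * a)
        return np.array([[m11, m12], [m12, m22]])


def make_rotated_gaussian(params: GaussianParams,
                          bounds: tuple[float, float] = (-3.0, 3.0)) -> Landscape:
    """Centred stretched Gaussian fitness function rotated by ``params.angle_a``.

    F(X, Y) = exp(-(X, Y) M (X, Y)^t) / (2 pi det(M)), with the matrix entries
    of :meth:`GaussianParams.matrix`.  The global maximum is at the origin
    with value 1/(2 pi) since det(M) = 1 for every angle.
    """
    M = params.matrix()
    det = float(np.linalg.det(M))
    m11, m12, m22 = M[0, 0], M[0, 1], M[1, 1]

    def f(x, y):
        q = m11 * x * x + 2.0 * m12 * x * y + m22 * y * y
        return np.exp(-q) / (2.0 * np.pi * det)

    ax = PhenotypeAxis(name="X", bounds=bounds)
    ay = PhenotypeAxis(name="Y", bounds=bounds)
    return Landscape(f=f, axis_x=ax, axis_y=ay)


@dataclass
class OptimaLine:
    """A restricted-optimum line: for each fixed value of one coordinate,
    the value of the other coordinate that maximises performance.

    ``which = "x_opt"`` fixes y and optimises x (the line x_opt(y));
    ``which = "y_opt"`` fixes x and optimises y.  ``boundary`` flags samples
    whose 1D maximum sits on the domain boundary (the optimum is then not
    interior and the sample value is the clipped bound).
    """

    which: Literal["x_opt", "y_opt"]
    fixed: np.ndarray
    optimal: np.ndarray
    boundary: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.fixed = np.asarray(self.fixed, float)
        self.optimal = np.asarray(self.optimal, float)
        self.boundary = np.asarray(self.boundary, bool)

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.fixed.tolist(), self.optimal.tolist()))

    def interpolator(self) -> Callable[[np.ndarray], np.ndarray]:
        fx, opt = self.fixed, self.optimal
        return lambda v: np.interp(np.asarray(v, float), fx, opt)

    def variation(self, exclude_boundary: bool = False) -> float:
        """Peak-to-peak variation of the optimising coordinate."""
        vals = self.optimal[~self.boundary] if exclude_boundary else self.optimal
        if vals.size == 0:
            return float("nan")
        return float(np.ptp(vals))


def _refine_1d(g: Callable[[float], float], lo: float, hi: float,
               x0: float, step: float, xatol: float) -> float:
    """Bounded local refinement of a coarse-grid argmax."""
    a = max(lo, x0 - step)
    b = min(hi, x0 + step)
    res = minimize_scalar(lambda t: -g(t), bounds=(a, b), method="bounded",
                          options={"xatol": xatol})
    return float(res.x) if -res.fun >= g(x0) else float(x0)


def restricted_optimum_line(L: Landscape, which: Literal["x_opt", "y_opt"],
                            n_samples: int = 201, n_grid: int = 201,
                            xatol: float = 1e-8) -> OptimaLine:
    """Locus of the 1D restricted optimum along one coordinate.

    For ``which="x_opt"``: for each of ``n_samples`` fixed y values spanning
    the y axis, maximise f(., y) over x by a coarse grid scan (``n_grid``
    points) followed by bounded local refinement to ``xatol``.  Samples whose
    maximum is attained at (or within one refinement step of) an axis bound
    are flagged as boundary optima rather than raising — cascade landscapes
    can be monotone in a parameter over a finite window.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if which not in ("x_opt", "y_opt"):
        raise ValueError(f"which must be 'x_opt' or 'y_opt', got {which!r}")
    free_ax = L.axis_x if which == "x_opt" else L.axis_y
    fix_ax = L.axis_y if which == "x_opt" else L.axis_x
    fixed = np.linspace(*fix_ax.bounds, n_samples)
    grid = np.linspace(*free_ax.bounds, n_grid)
    step = grid[1] - grid[0]
    lo, hi = free_ax.bounds

    if which == "x_opt":
        Z = L(grid[None, :], fixed[:, None])   # rows: fixed y, cols: free x
    else:
        Z = L(fixed[None, :], grid[:, None]).T  # rows: fixed x, cols: free y
    if not np.all(np.isfinite(Z)):
        raise ValueError("landscape is not finite on its bounds")

    idx = np.argmax(Z, axis=1)
    optimal = np.empty(n_samples)
    boundary = np.zeros(n_samples, bool)
    for i, (v, j) in enumerate(zip(fixed, idx)):
        if which == "x_opt":
            g = lambda t: float(L(t, v))
        else:
            g = lambda t: float(L(v, t))
        x = _refine_1d(g, lo, hi, grid[j], step, xatol)
        optimal[i] = x
        boundary[i] = (x - lo) <= 10 * xatol or (hi - x) <= 10 * xatol
    return OptimaLine(which=which, fixed=fixed, optimal=optimal, boundary=boundary)


def global_optimum(L: Landscape, n_grid: int = 201, xatol: float = 1e-8,
                   require_interior: bool = True) -> tuple[float, float]:
    """Coordinates of the maximum of L inside its bounds.

    Coarse grid scan then alternating 1D bounded refinement.  If the maximum
    is attained on the boundary and ``require_interior`` is true, a
    :class:`BoundaryOptimumError` is raised (reported, not silently
    returned).
    """
    x, y, Z = L.grid(n_grid)
    iy, ix = np.unravel_index(np.argmax(Z), Z.shape)
    bx, by = float(x[ix]), float(y[iy])
    step = x[1] - x[0]
    stepy = y[1] - y[0]
    best = float(Z[iy, ix])
    # coordinate-wise refinement; landscapes here are smooth and unimodal
    # near the optimum, two sweeps reach xatol
    for _ in range(4):
        bx = _refine_1d(lambda t: float(L(t, by)), *L.axis_x.bounds, bx, step, xatol)
        by = _refine_1d(lambda t: float(L(bx, t)), *L.axis_y.bounds, by, stepy, xatol)
    val = float(L(bx, by))
    if val < best:  # refinement must never lose to the grid
        bx, by, val = float(x[ix]), float(y[iy]), best
    on_bx = min(bx - L.axis_x.bounds[0], L.axis_x.bounds[1] - bx) <= 10 * xatol
    on_by = min(by - L.axis_y.bounds[0], L.axis_y.bounds[1] - by) <= 10 * xatol
    if require_interior and (on_bx or on_by):
        raise BoundaryOptimumError(
            f"maximum of landscape attained at boundary near ({bx:.4g}, {by:.4g})")
    return bx, by


def sign_epistasis_criterion(L: Landscape, tol: float = 0.01,
                             n_samples: int = 101) -> dict:
    """Do the restricted-optimum lines depend on the other coordinate?

    ``x_effect_sign_epistasis`` is True iff x_opt(y) varies by more than
    ``tol`` times the x-axis span across the sampled y values (analogously
    for y).  A varying optimum line is exactly the geometric condition under
    which a mutation along that axis can flip the sign of its performance
    effect in a different background.  Boundary-optimum flags are propagated.
    """
    lx = restricted_optimum_line(L, "x_opt", n_samples=n_samples)
    ly = restricted_optimum_line(L, "y_opt", n_samples=n_samples)
    return {
        "x_effect_sign_epistasis": bool(lx.variation() > tol * L.axis_x.span),
        "y_effect_sign_epistasis": bool(ly.variation() > tol * L.axis_y.span),
        "x_opt_boundary_samples": int(lx.boundary.sum()),
        "y_opt_boundary_samples": int(ly.boundary.sum()),
    }
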