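"""Classification of epistasis on 2D performance landscapes.

A pair of mutations — one moving along each axis of a phenotype plane —
spans a 2x2 square of phenotypes.  Tracking the performance changes along
the two double-mutation trajectories from start to end corner yields four
signed effects: the x-mutation's effect in each y background and the
y-mutation's effect in each x background.  The sign pattern of these
effects defines the epistasis class:

* magnitude   — no effect flips sign between backgrounds;
* x_sign / y_sign — exactly one of the two mutations flips sign
  (labelled upstream_sign/downstream_sign when the axes carry cascade
  positions);
* reciprocal  — both mutations flip sign;
* neutral     — all four effects are below tolerance.

``epistasis_map`` paints every grid cell of a landscape with the class of
the square from that cell to a common end point (by default the global
optimum), which is how the colour-coded domain maps are built.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np

from .landscapes import Landscape, global_optimum

__all__ = [
    "Square",
    "EpistasisCall",
    "EpistasisMap",
    "classify_square",
    "classify_effects",
    "epistasis_map",
    "pleiotropic_slice",
    "count_pairwise_interactions",
    "panel_size",
    "double_mutant_reach",
    "CLASSES",
]

CLASSES = ("magnitude", "x_sign", "y_sign", "reciprocal", "neutral")

Klass = Literal["magnitude", "x_sign", "y_sign", "reciprocal", "neutral",
                "upstream_sign", "downstream_sign"]


@dataclass(frozen=True)
class Square:
    """A 2x2 phenotype square: both coordinates must change."""

    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self) -> None:
        if self.start[0] == self.end[0] or self.start[1] == self.end[1]:
            raise ValueError("square degenerate: both coordinates must change "
                             f"(start={self.start}, end={self.end})")


@dataclass(frozen=True)
class EpistasisCall:
    """One classified square with its four signed performance effects.

    ``effects`` holds ``dx_y0`` (x-effect in the start's y background),
    ``dx_y1`` (x-effect in the end's y background), ``dy_x0`` and ``dy_x1``.
    ``klass`` uses upstream_sign/downstream_sign when cascade positions were
    available on the axes, else x_sign/y_sign.
    """

    klass: str
    effects: Mapping[str, float]
    p_values: Mapping[str, float] | None = None


def classify_effects(dx_y0, dx_y1, dy_x0, dy_x1, tol_abs: float):
    """Core sign-flip rule on arrays of the four effects.

    Effects with |Δ| < ``tol_abs`` count as zero; a sign flip requires
    strictly opposite nonzero signs (an effect that is exactly zero, e.g. on
    an optimum line, does not count as a flip — those lines have measure
    zero).  Returns an integer class-code array indexing ``CLASSES``.
    """
    def sgn(v):
        v = np.asarray(v, float)
        return np.where(np.abs(v) < tol_abs, 0, np.sign(v)).astype(int)

    sx0, sx1, sy0, sy1 = sgn(dx_y0), sgn(dx_y1), sgn(dy_x0), sgn(dy_x1)
    x_flip = sx0 * sx1 == -1
    y_flip = sy0 * sy1 == -1
    any_effect = (sx0 != 0) | (sx1 != 0) | (sy0 != 0) | (sy1 != 0)
    code = np.zeros(np.shape(x_flip), int)            # magnitude
    code = np.where(x_flip & ~y_flip, 1, code)        # x_sign
    code = np.where(y_flip & ~x_flip, 2, code)        # y_sign
    code = np.where(x_flip & y_flip, 3, code)         # reciprocal
    code = np.where(~any_effect, 4, code)             # neutral
    return code


def _position_label(code: str, L: Landscape) -> str:
    if code == "x_sign" and L.axis_x.cascade_position != "abstract":
        return f"{L.axis_x.cascade_position}_sign"
    if code == "y_sign" and L.axis_y.cascade_position != "abstract":
        return f"{L.axis_y.cascade_position}_sign"
    return code


def _scale(L: Landscape, n: int = 101) -> float:
    _, _, Z = L.grid(n)
    return float(np.ptp(Z)) or 1.0


def classify_square(L: Landscape, s: Square, tol: float = 1e-9,
                    scale: float | None = None) -> EpistasisCall:
    """Classify one 2x2 square on a landscape.

    ``tol`` is relative to the landscape's dynamic range (``scale``; a grid
    peak-to-peak estimate when not supplied).  All four corners must lie
    inside the axis bounds.
    """
    (x0, y0), (x1, y1) = s.start, s.end
    for (x, y) in ((x0, y0), (x1, y1), (x0, y1), (x1, y0)):
        if not (L.axis_x.bounds[0] <= x <= L.axis_x.bounds[1]
                and L.axis_y.bounds[0] <= y <= L.axis_y.bounds[1]):
            raise ValueError(f"corner ({x}, {y}) outside landscape bounds")
    f00, f10 = float(L(x0, y0)), float(L(x1, y0))
    f01, f11 = float(L(x0, y1)), float(L(x1, y1))
    eff = {"dx_y0": f10 - f00, "dx_y1": f11 - f01,
           "dy_x0": f01 - f00, "dy_x1": f11 - f10}
    tol_abs = tol * (scale if scale is not None else _scale(L))
    code = int(classify_effects(eff["dx_y0"], eff["dx_y1"],
                                eff["dy_x0"], eff["dy_x1"], tol_abs))
    return EpistasisCall(klass=_position_label(CLASSES[code], L), effects=eff)


@dataclass
class EpistasisMap:
    """Per-cell epistasis classes for squares from every grid cell to a
    common end point."""

    x: np.ndarray
    y: np.ndarray
    codes: np.ndarray          # int codes into CLASSES; -1 = skipped cell
    end: tuple[float, float]
    landscape: Landscape = field(repr=False)

    @property
    def class_names(self) -> list[str]:
        return [_position_label(c, self.landscape) for c in CLASSES]

    def class_fractions(self, include_neutral: bool = True) -> dict[str, float]:
        """Fractions per class over classified (non-skipped) cells; sums
        to 1."""
        valid = self.codes >= 0
        total = int(valid.sum())
        names = self.class_names
        fr = {}
        for i, name in enumerate(names):
            if not include_neutral and name == "neutral":
                continue
            fr[name] = float((self.codes[valid] == i).sum()) / total
        if not include_neutral:
            ssum = sum(fr.values())
            fr = {k: (v / ssum if ssum else 0.0) for k, v in fr.items()}
        return fr

    def domain_present(self, klass: str, min_fraction: float = 0.01) -> bool:
        """A class forms a *domain* (not a resolution-scale sliver) when it
        covers at least ``min_fraction`` of classified cells."""
        return self.class_fractions().get(klass, 0.0) >= min_fraction

    def calls_with_points(self) -> list[tuple[tuple[float, float], str]]:
        names = self.class_names
        out = []
        for i, yv in enumerate(self.y):
            for j, xv in enumerate(self.x):
                c = self.codes[i, j]
                if c >= 0:
                    out.append(((float(xv), float(yv)), names[c]))
        return out

    def to_csv(self, path) -> None:
        names = self.class_names
        with open(path, "w") as fh:
            fh.write("x,y,class\n")
            for i, yv in enumerate(self.y):
                for j, xv in enumerate(self.x):
                    c = self.codes[i, j]
                    if c >= 0:
                        fh.write(f"{xv},{yv},{names[c]}\n")

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"end": list(self.end),
                       "class_fractions": self.class_fractions()}, fh, indent=2)

    def plot(self, ax=None):
        """Colour-coded domain map (grey magnitude, red downstream/x, green
        upstream/y, yellow reciprocal, white neutral)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        if ax is None:
            _, ax = plt.subplots()
        cmap = ListedColormap(["0.7", "tab:red", "tab:green", "gold", "white"])
        shown = np.ma.masked_less(self.codes, 0)
        ax.pcolormesh(self.x, self.y, shown, cmap=cmap, vmin=0, vmax=4)
        ax.plot(*self.end, "k*", ms=12)
        ax.set_xlabel(self.landscape.axis_x.name)
        ax.set_ylabel(self.landscape.axis_y.name)
        return ax


def epistasis_map(L: Landscape, grid: int = 201,
                  end: tuple[float, float] | str = "global_optimum",
                  tol: float = 1e-9) -> EpistasisMap:
    """Classify the square from every grid cell to a common end point.

    The end point defaults to the landscape's global optimum.  Cells sharing
    a coordinate with the end point are skipped (degenerate squares, code
    −1).  ``tol`` is relative to the map's dynamic range; maps of noiseless
    model landscapes use strict signs at essentially double precision.
    """
    x, y, Z = L.grid(grid)
    if end == "global_optimum":
        end = global_optimum(L, n_grid=grid)
    ex, ey = float(end[0]), float(end[1])
    if not (L.axis_x.bounds[0] <= ex <= L.axis_x.bounds[1]
            and L.axis_y.bounds[0] <= ey <= L.axis_y.bounds[1]):
        raise ValueError(f"end point {end} outside bounds")

    f_end = float(L(ex, ey))
    col_end = L(np.full_like(y, ex), y)        # f(x_end, y) per row
    row_end = L(x, np.full_like(x, ey))        # f(x, y_end) per col
    dx_y0 = col_end[:, None] - Z
    dx_y1 = (f_end - row_end)[None, :] + np.zeros_like(Z)
    dy_x0 = row_end[None, :] - Z
    dy_x1 = (f_end - col_end)[:, None] + np.zeros_like(Z)
    tol_abs = tol * (float(np.ptp(Z)) or 1.0)
    codes = classify_effects(dx_y0, dx_y1, dy_x0, dy_x1, tol_abs)
    degenerate = (x[None, :] == ex) | (y[:, None] == ey)
    codes = np.where(degenerate, -1, codes)
    return EpistasisMap(x=x, y=y, codes=codes, end=(ex, ey), landscape=L)


def pleiotropic_slice(build: Callable[..., Landscape],
                      coupling: Callable[[float], Mapping[str, float]],
                      coupling_axis: Literal["x", "y"] = "x",
                      **build_kwargs) -> Landscape:
    """Landscape in which moving along one axis also updates a secondary
    parameter of the same gene (intra-genic pleiotropy).

    ``build`` is a landscape builder accepting ``coupling``/``coupling_axis``
    keywords (e.g. :func:`episcade.cascade.r_landscape` with its cascade,
    window, parameter and bounds arguments pre-bound via functools.partial).
    Couplings touching the other gene's parameters are rejected by the
    builder — that would break the genetic-independence premise of the
    plane.
    """
    return build(coupling=coupling, coupling_axis=coupling_axis, **build_kwargs)


def count_pairwise_interactions(n_upstream_variants: int, n_downstream_variants: int) -> int:
    """Number of distinct 2x2 genotype squares in a complete variant panel:
    C(n_up, 2) * C(n_down, 2)."""
    if n_upstream_variants < 2 or n_downstream_variants < 2:
        raise ValueError("need at least two variants per gene")
    return math.comb(n_upstream_variants, 2) * math.comb(n_downstream_variants, 2)


def panel_size(n_upstream_variants: int, n_downstream_variants: int) -> int:
    """Number of cascade genotypes in the complete panel."""
    if n_upstream_variants < 1 or n_downstream_variants < 1:
        raise ValueError("need at least one variant per gene")
    return n_upstream_variants * n_downstream_variants


def double_mutant_reach(n_upstream_variants: int, n_downstream_variants: int) -> int:
    """Double-mutant destinations reachable from any one genotype:
    (n_up − 1)(n_down − 1)."""
    if n_upstream_variants < 2 or n_downstream_variants < 2:
        raise ValueError("need at least two variants per gene")
    return (n_upstream_variants - 1) * (n_downstream_variants - 1)
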