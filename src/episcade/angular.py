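"""Angular coordinate for phenotype planes and clustering statistics.

Epistasis domains on smooth landscapes are organised radially around the
global optimum, bounded by the two restricted-optimum lines.  To compare
maps across parameter planes and input ranges, each point P is assigned a
normalised angle θ: on the circle centred at the optimum through P, the
four intersections with the two optimum lines (anchors A–D, counter-
clockwise) are mapped to θ = 0, π/2, π, 3π/2, and P's own angle is linearly
interpolated between its bracketing anchors.  This "straightens" the curved
optimum lines onto the coordinate axes.

Anchor A is the intersection with the upstream-gene optimum line (the
y_opt line, optimal y for each fixed x) on the positive-x side of the
optimum; B, C, D follow counter-clockwise.  For the unrotated Gaussian the
optimum lines are the coordinate axes and θ reduces to the raw polar angle.

Per-bin enrichment of an epistasis class is tested against a binomial null:
classes assigned independently with their global frequencies f_E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .landscapes import Landscape, OptimaLine, global_optimum, restricted_optimum_line

__all__ = [
    "AngularFrame",
    "AngularHistogram",
    "AngleNormalisationError",
    "normalize_angle",
    "angular_histogram",
    "bin_enrichment_test",
]

TAU = 2.0 * np.pi


class AngleNormalisationError(ValueError):
    """The circle through P does not intersect both optimum lines twice
    within the sampled domain."""


@dataclass
class AngularFrame:
    """Geometric frame for angle normalisation: the global optimum plus the
    two restricted-optimum lines through it."""

    center: tuple[float, float]
    x_opt_line: OptimaLine
    y_opt_line: OptimaLine
    _x_of_y: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    _y_of_x: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._x_of_y is None:
            self._x_of_y = self.x_opt_line.interpolator()
        if self._y_of_x is None:
            self._y_of_x = self.y_opt_line.interpolator()

    @classmethod
    def from_landscape(cls, L: Landscape, n_samples: int = 201,
                       expand: float = 0.0) -> "AngularFrame":
        """Build the frame from a landscape's optimum geometry.

        ``expand`` widens each axis' sampling range by that fraction of its
        span on both sides before extracting the optimum lines, so that
        circles around the optimum stay inside the sampled region even when
        the optimum sits near the plotted window's edge.  This requires the
        landscape function to be evaluable beyond its nominal bounds (true
        for the model response-range and Gaussian families).
        """
        from dataclasses import replace as _dc_replace

        if expand > 0:
            def _wider(ax):
                lo, hi = ax.bounds
                e = expand * (hi - lo)
                return _dc_replace(ax, bounds=(lo - e, hi + e))
            L = Landscape(f=L.f, axis_x=_wider(L.axis_x), axis_y=_wider(L.axis_y))
        center = global_optimum(L)
        lx = restricted_optimum_line(L, "x_opt", n_samples=n_samples)
        ly = restricted_optimum_line(L, "y_opt", n_samples=n_samples)
        return cls(center=center, x_opt_line=lx, y_opt_line=ly)

    # -- circle/line intersections ------------------------------------
    def _roots(self, g: Callable[[float], float], n_scan: int = 720) -> list[float]:
        alphas = np.linspace(0.0, TAU, n_scan + 1)
        vals = np.array([g(a) for a in alphas])
        roots: list[float] = []
        for i in range(n_scan):
            v0, v1 = vals[i], vals[i + 1]
            if v0 == 0.0:
                roots.append(float(alphas[i]) % TAU)
            elif v0 * v1 < 0:
                roots.append(float(brentq(g, alphas[i], alphas[i + 1], xtol=1e-12)) % TAU)
        # dedupe the wrap point and collapse near-identical roots
        roots = sorted(roots)
        out: list[float] = []
        for r in roots:
            if not out or (r - out[-1]) % TAU > 1e-9:
                out.append(r)
        if len(out) > 1 and (out[0] - out[-1]) % TAU < 1e-9:
            out.pop()
        return out

    def anchors(self, radius: float) -> np.ndarray:
        """Raw angles of anchors A, B, C, D (counter-clockwise from A) on
        the circle of given radius around the optimum."""
        cx, cy = self.center
        y_fix = self.x_opt_line.fixed
        x_fix = self.y_opt_line.fixed
        if (cy - radius < y_fix.min() or cy + radius > y_fix.max()
                or cx - radius < x_fix.min() or cx + radius > x_fix.max()):
            raise AngleNormalisationError(
                f"circle of radius {radius:.4g} leaves the sampled optimum lines")

        gx = lambda a: (cx + radius * np.cos(a)) - float(self._x_of_y(cy + radius * np.sin(a)))
        gy = lambda a: (cy + radius * np.sin(a)) - float(self._y_of_x(cx + radius * np.cos(a)))
        rx = self._roots(gx)
        ry = self._roots(gy)
        if len(rx) != 2 or len(ry) != 2:
            missing = "x_opt" if len(rx) != 2 else "y_opt"
            raise AngleNormalisationError(
                f"expected two intersections per optimum line, got "
                f"{len(rx)} (x_opt) and {len(ry)} (y_opt); missing arc on {missing}")
        # anchor A: y_opt-line intersection on the positive-x side
        a_A = min(ry, key=lambda a: abs(np.angle(np.exp(1j * a))))
        if np.cos(a_A) <= 0:
            a_A = ry[0] if ry[0] != a_A else ry[1]
        others = [a for a in rx + ry if a != a_A]
        ccw = sorted(others, key=lambda a: (a - a_A) % TAU)
        anchors = np.array([a_A] + ccw)
        # anchors must alternate between the two lines (A, C on y_opt)
        on_y = [a in ry for a in anchors]
        if on_y != [True, False, True, False]:
            raise AngleNormalisationError(
                "optimum-line intersections do not alternate around the circle")
        return anchors


def normalize_angle(frame: AngularFrame, P: tuple[float, float]) -> float:
    """Normalised angular coordinate θ of P in [0, 2π).

    The anchors at the circle through P map to θ_A = 0, θ_B = π/2,
    θ_C = π, θ_D = 3π/2; P's raw polar angle is interpolated linearly
    between its bracketing anchors.
    """
    cx, cy = frame.center
    dx, dy = P[0] - cx, P[1] - cy
    r = float(np.hypot(dx, dy))
    if r == 0.0:
        raise AngleNormalisationError("P coincides with the optimum")
    alpha = float(np.arctan2(dy, dx)) % TAU
    anch = frame.anchors(r)
    thetas = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    rel = (alpha - anch[0]) % TAU
    rel_anch = (anch - anch[0]) % TAU   # [0, b, c, d] increasing
    idx = int(np.searchsorted(rel_anch, rel, side="right") - 1)
    lo = rel_anch[idx]
    hi = rel_anch[idx + 1] if idx < 3 else TAU
    t_lo = thetas[idx]
    frac = 0.0 if hi == lo else (rel - lo) / (hi - lo)
    return float((t_lo + frac * (np.pi / 2)) % TAU)


@dataclass
class AngularHistogram:
    """Counts of epistasis calls per angular bin and class."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]          # class -> per-bin counts
    f_E: dict[str, float]                  # global class frequencies
    n_skipped: int = 0
    skipped: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_population(self, b: int) -> int:
        return int(sum(c[b] for c in self.counts.values()))

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_csv(self, path, alpha: float = 0.05) -> None:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        with open(path, "w") as fh:
            fh.write("bin_center_rad,class,count,p_value,significant\n")
            for klass in self.counts:
                for b, c in enumerate(centers):
                    if self.bin_population(b) == 0:
                        fh.write(f"{c},{klass},0,nan,False\n")
                        continue
                    p = bin_enrichment_test(self, klass, b)
                    fh.write(f"{c},{klass},{int(self.counts[klass][b])},"
                             f"{p},{p < alpha}\n")


def angular_histogram(frame: AngularFrame,
                      calls: Sequence[tuple[tuple[float, float], str]],
                      n_bins: int = 8) -> AngularHistogram:
    """Bin epistasis calls by normalised angle.

    ``calls`` is a sequence of ((x, y), class).  Points that cannot be
    normalised (circle leaves the sampled region, or P at the optimum) are
    skipped and reported in ``skipped``.
    """
    edges = np.linspace(0.0, TAU, n_bins + 1)
    counts: dict[str, np.ndarray] = {}
    skipped = []
    kept = 0
    for point, klass in calls:
        try:
            theta = normalize_angle(frame, point)
        except AngleNormalisationError as err:
            skipped.append((point, klass, str(err)))
            continue
        b = min(int(np.searchsorted(edges, theta, side="right") - 1), n_bins - 1)
        counts.setdefault(klass, np.zeros(n_bins, int))[b] += 1
        kept += 1
    f_E = {k: float(c.sum()) / kept for k, c in counts.items()} if kept else {}
    return AngularHistogram(bin_edges=edges, counts=counts, f_E=f_E,
                            n_skipped=len(skipped), skipped=skipped)


def bin_enrichment_test(h: AngularHistogram, klass: str, b: int) -> float:
    """One-tailed binomial enrichment p-value for one class in one bin.

    With N_θ the bin population and f_E the class's overall frequency,
    p = P[X >= observed] for X ~ Binomial(N_θ, f_E).  Flag significance at
    p < 0.05.
    """
    if klass not in h.counts:
        raise KeyError(f"unknown class {klass!r}; histogram has {sorted(h.counts)}")
    N = h.bin_population(b)
    if N < 1:
        raise ValueError(f"bin {b} is empty")
    obs = int(h.counts[klass][b])
    return float(binom.sf(obs - 1, N, h.f_E[klass]))
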