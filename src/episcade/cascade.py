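"""Equilibrium input–output model of a transcriptional signalling cascade.

The cascade is an ordered composition of Hill stages.  Each stage describes
one regulatory layer: a regulator (repressor or activator) reading the
previous stage's output and driving the next gene's expression between a
minimum ``m`` and a maximum ``M``, with dissociation constant ``K`` and
cooperativity ``n``.  The reference architecture is the three-layer
arabinose cascade: an arabinose-responsive first stage produces TetR, TetR
represses the LacI gene, and LacI represses the fluorescent output.

Performance of a cascade over an input window [in_min, in_max] is the
response range R — the difference between the outputs at the two window
ends.  Because of conflicting sign conventions in the source material
(out_max − out_min versus Out(in_min) − Out(in_max)), R is reported as a
magnitude with the signed value and its orientation retained as metadata.

``r_landscape`` turns R into a 2D performance landscape over any pair of
stage parameters (dissociation constants are traversed in log10), which is
the object the epistasis-domain analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import yaml

from .landscapes import Landscape, PhenotypeAxis

__all__ = [
    "HillStage",
    "Cascade",
    "InputRange",
    "ResponseRange",
    "EnvFitnessParams",
    "stage_response",
    "cascade_output",
    "response_range_R",
    "fitness_proxy",
    "r_landscape",
    "default_cascade",
    "inverted_cascade",
    "activator_substituted",
    "default_plane",
    "FULL_WINDOW",
    "RESTRICTED_WINDOW",
    "load_cascade_config",
    "save_cascade_config",
]

Role = Literal["repressor", "activator"]


@dataclass(frozen=True)
class HillStage:
    """One regulatory layer of the cascade.

    ``M_max``/``m_min`` are the maximum/minimum expression driven by this
    stage's promoter (arbitrary fluorescence-equivalent units), ``K`` the
    regulator–operator dissociation constant in units of the stage's input,
    and ``n`` the Hill cooperativity.
    """

    name: str
    role: Role
    M_max: float
    m_min: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if self.role not in ("repressor", "activator"):
            raise ValueError(f"role must be repressor or activator, got {self.role!r}")
        if not self.M_max > self.m_min >= 0:
            raise ValueError(f"need M_max > m_min >= 0, got M={self.M_max}, m={self.m_min}")
        if not self.K > 0:
            raise ValueError(f"dissociation constant must be positive, got {self.K}")
        if not self.n > 0:
            raise ValueError(f"Hill coefficient must be positive, got {self.n}")

    def response(self, u):
        return stage_response(self, u)


def stage_response(s: HillStage, u):
    """Equilibrium Hill response of one stage to input level ``u`` >= 0.

    Repressor:  (M − m) / (1 + (u/K)^n) + m
    Activator:  (M − m) (u/K)^n / (1 + (u/K)^n) + m
    """
    u = np.asarray(u, float)
    if np.any(u < 0):
        raise ValueError("stage input must be non-negative")
    ratio = (u / s.K) ** s.n
    if s.role == "repressor":
        return (s.M_max - s.m_min) / (1.0 + ratio) + s.m_min
    return (s.M_max - s.m_min) * ratio / (1.0 + ratio) + s.m_min


@dataclass(frozen=True)
class InputRange:
    """External input window [in_min, in_max], in µM."""

    in_min: float
    in_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.in_min < self.in_max):
            raise ValueError(f"need 0 <= in_min < in_max, got ({self.in_min}, {self.in_max})")


FULL_WINDOW = InputRange(0.0, 100.0)
RESTRICTED_WINDOW = InputRange(50.0, 100.0)


@dataclass(frozen=True)
class ResponseRange:
    """|R| with its sign convention made explicit.

    ``signed`` is Out(in_min) − Out(in_max); ``orientation`` records which
    window end produced the larger output.
    """

    value: float
    signed: float
    orientation: Literal["in_min", "in_max"]


@dataclass(frozen=True)
class Cascade:
    """Ordered composition of Hill stages; the first stage reads the
    external input, each later stage reads its predecessor's output."""

    stages: tuple[HillStage, ...]
    input_name: str = "arabinose (uM)"

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("cascade needs at least one stage")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate stage names: {names}")

    def output(self, u):
        return cascade_output(self, u)

    def response_range(self, w: InputRange) -> ResponseRange:
        return response_range_R(self, w)

    def stage_index(self, name: str) -> int:
        for i, s in enumerate(self.stages):
            if s.name == name:
                return i
        raise KeyError(f"no stage named {name!r}; have {[s.name for s in self.stages]}")

    def with_stage_params(self, name: str, **params) -> "Cascade":
        """A copy of the cascade with one stage's parameters replaced."""
        i = self.stage_index(name)
        stages = list(self.stages)
        stages[i] = replace(stages[i], **params)
        return Cascade(stages=tuple(stages), input_name=self.input_name)


def cascade_output(C: Cascade, u):
    """Left-to-right composition of stage responses through all stages."""
    level = np.asarray(u, float)
    for s in C.stages:
        level = stage_response(s, level)
    return level


def response_range_R(C: Cascade, w: InputRange) -> ResponseRange:
    """Response range over an input window.

    Returns |Out(in_min) − Out(in_max)|; each stage is monotone, so the
    composed cascade is monotone in the external input and this equals
    max − min of the output over the window.
    """
    y_lo = float(cascade_output(C, w.in_min))
    y_hi = float(cascade_output(C, w.in_max))
    signed = y_lo - y_hi
    return ResponseRange(value=abs(signed), signed=signed,
                         orientation="in_min" if signed >= 0 else "in_max")


@dataclass(frozen=True)
class EnvFitnessParams:
    """Affine benefit/cost coefficients of the two-environment fitness
    proxy: F1 = a + c·y1, F2 = b − c·y2."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("cost-benefit coefficient c must be positive")


def fitness_proxy(p: EnvFitnessParams, y1: float, y2: float) -> tuple[float, float]:
    """Environment-averaged fitness and range for outputs y1, y2 in the two
    environments: F_av = (a + b)/2 − (c/2)(y2 − y1), R = y2 − y1.

    For fixed (a, b, c), fitness differences between genotypes are
    proportional to differences in R, which is why the response range serves
    as the fitness proxy throughout."""
    R = y2 - y1
    F_av = (p.a + p.b) / 2.0 - (p.c / 2.0) * R
    return F_av, R


# ---------------------------------------------------------------------------
# Default parameterisation
#
# The study's fitted stage parameters are not deposited; these defaults are
# calibrated so the (K_TetR, K_LacI) response-range landscape over the full
# 0-100 uM window shows the reference domain topology: a single interior
# optimum, a near-horizontal upstream (K_TetR) optimum line hence no
# upstream sign-epistasis domain, and a tilted downstream (K_LacI) optimum
# line hence a downstream sign-epistasis domain; restricting the window to
# 50-100 uM adds upstream and reciprocal domains.  See docs/methods.md for
# the calibration rationale (notably n_AraC = 1 and n_TetR = 5).
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = {
    "araC": dict(role="repressor", M_max=100.0, m_min=0.2, K=22.0, n=1.0),
    "tetR": dict(role="repressor", M_max=100.0, m_min=4.0, K=25.0, n=5.0),
    "lacI": dict(role="repressor", M_max=100.0, m_min=1.0, K=20.0, n=1.7),
}

#: working-coordinate (log10 K) plane bounds for the default stage order
DEFAULT_PLANE_BOUNDS = {"lacI": (1.0, 4.0), "tetR": (-1.5, 1.5)}
#: plane bounds calibrated for the inverted (lacI upstream) order
INVERTED_PLANE_BOUNDS = {"tetR": (-2.0, 1.2), "lacI": (1.02, 4.52)}


def default_cascade() -> Cascade:
    """The reference three-stage cascade, equations exactly as printed
    (the first stage is a decreasing Hill function of arabinose)."""
    return Cascade(stages=tuple(
        HillStage(name=n, **_DEFAULT_STAGES[n]) for n in ("araC", "tetR", "lacI")))


def inverted_cascade() -> Cascade:
    """Hierarchy-inverted cascade: lacI upstream of tetR.  Each gene keeps
    its own binding parameters (K, n) and promoter expression bounds."""
    return Cascade(stages=tuple(
        HillStage(name=n, **_DEFAULT_STAGES[n]) for n in ("araC", "lacI", "tetR")))


def activator_substituted(base: Cascade, gene: str) -> Cascade:
    """Replace one repressor stage by a generic activator with the same
    parameters (the printed activator functional form)."""
    i = base.stage_index(gene)
    stages = list(base.stages)
    stages[i] = replace(stages[i], role="activator")
    return Cascade(stages=tuple(stages), input_name=base.input_name)


def _param_bounds_ok(stage: HillStage, param: str, value: float) -> None:
    # reuse the dataclass validation by constructing the mutated stage
    replace(stage, **{param: value})


def r_landscape(C: Cascade, w: InputRange,
                param_x: tuple[str, str], param_y: tuple[str, str],
                bounds_x: tuple[float, float], bounds_y: tuple[float, float],
                coupling: Callable[[float], Mapping[str, float]] | None = None,
                coupling_axis: Literal["x", "y"] | None = None) -> Landscape:
    """Response-range landscape over a pair of stage parameters.

    ``param_x``/``param_y`` are (stage_name, parameter) pairs, e.g.
    ``("lacI", "K")``.  Dissociation constants are traversed in log10
    working coordinates; other parameters linearly.  Axis metadata records
    gene identity and cascade position (upstream/downstream by stage order)
    so epistasis classes can be labelled.

    ``coupling`` (with ``coupling_axis``) implements intra-genic pleiotropy:
    a deterministic map from the coupled axis' working coordinate to extra
    parameter overrides *of the same stage*, applied before evaluating R.
    """
    (sx, px), (sy, py) = param_x, param_y
    ix, iy = C.stage_index(sx), C.stage_index(sy)
    if sx == sy and coupling is None:
        raise ValueError("param_x and param_y must belong to different stages "
                         "(use coupling for intra-genic pleiotropy)")
    for (s, p, b) in ((sx, px, bounds_x), (sy, py, bounds_y)):
        if b[0] >= b[1]:
            raise ValueError(f"degenerate bounds {b} for {s}.{p}")
        stage = C.stages[C.stage_index(s)]
        log = p == "K"
        for v in b:
            _param_bounds_ok(stage, p, 10.0 ** v if log else v)
    if coupling is not None:
        if coupling_axis not in ("x", "y"):
            raise ValueError("coupling requires coupling_axis 'x' or 'y'")
        c_stage = sx if coupling_axis == "x" else sy
        probe = coupling(sum(bounds_x if coupling_axis == "x" else bounds_y) / 2.0)
        allowed = {"K", "n", "M_max", "m_min"}
        if not set(probe).issubset(allowed):
            raise ValueError(f"coupling may only set {sorted(allowed)}, got {sorted(probe)}")
        # pleiotropy must stay within the coupled gene: rebuilding another
        # stage's parameters would break the genetic-independence premise
        other = sy if coupling_axis == "x" else sx
        if c_stage == other:
            raise ValueError("coupling axis must differ from the other plane axis' stage")

    logx, logy = px == "K", py == "K"

    def f(x, y):
        x0, y0 = np.asarray(x, float), np.asarray(y, float)
        shape = np.broadcast_shapes(x0.shape, y0.shape)
        xb, yb = np.broadcast_arrays(np.atleast_1d(x0), np.atleast_1d(y0))
        out = np.empty(xb.shape)
        it = np.nditer([xb, yb], flags=["multi_index"])
        for xv, yv in it:
            vx = 10.0 ** float(xv) if logx else float(xv)
            vy = 10.0 ** float(yv) if logy else float(yv)
            cc = C.with_stage_params(sx, **{px: vx}).with_stage_params(sy, **{py: vy})
            if coupling is not None:
                coord = float(xv) if coupling_axis == "x" else float(yv)
                cc = cc.with_stage_params(c_stage, **dict(coupling(coord)))
            out[it.multi_index] = response_range_R(cc, w).value
        return out.reshape(shape) if shape else float(out.ravel()[0])

    pos = {True: "upstream", False: "downstream"}
    ax = PhenotypeAxis(name=f"{'log10 ' if logx else ''}{px}_{sx}", gene=sx,
                       cascade_position=pos[ix < iy], scale="log10" if logx else "linear",
                       bounds=bounds_x)
    ay = PhenotypeAxis(name=f"{'log10 ' if logy else ''}{py}_{sy}", gene=sy,
                       cascade_position=pos[iy < ix], scale="log10" if logy else "linear",
                       bounds=bounds_y)
    return Landscape(f=_vectorized_r(C, w, sx, px, sy, py, logx, logy,
                                     coupling, coupling_axis) or f,
                     axis_x=ax, axis_y=ay)


def _vectorized_r(C, w, sx, px, sy, py, logx, logy, coupling, coupling_axis):
    """Fast path: K/K planes without coupling evaluate in closed form over
    arrays (the generic path rebuilds a cascade per grid point)."""
    if coupling is not None or px != "K" or py != "K":
        return None

    def f(x, y):
        kx = 10.0 ** np.asarray(x, float)
        ky = 10.0 ** np.asarray(y, float)

        def out(u):
            val = np.asarray(u, float)
            for s in C.stages:
                K = kx if s.name == sx else (ky if s.name == sy else s.K)
                ratio = (val / K) ** s.n
                if s.role == "repressor":
                    val = (s.M_max - s.m_min) / (1.0 + ratio) + s.m_min
                else:
                    val = (s.M_max - s.m_min) * ratio / (1.0 + ratio) + s.m_min
            return val

        return np.abs(out(w.in_min) - out(w.in_max))

    return f


def default_plane(C: Cascade | None = None, w: InputRange = FULL_WINDOW) -> Landscape:
    """The calibrated (log10 K_LacI, log10 K_TetR) response-range landscape:
    x axis = downstream gene's K, y axis = upstream gene's K."""
    C = C or default_cascade()
    i_tet, i_lac = C.stage_index("tetR"), C.stage_index("lacI")
    bounds = DEFAULT_PLANE_BOUNDS if i_tet < i_lac else INVERTED_PLANE_BOUNDS
    down, up = ("lacI", "tetR") if i_tet < i_lac else ("tetR", "lacI")
    return r_landscape(C, w, (down, "K"), (up, "K"), bounds[down], bounds[up])


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def save_cascade_config(C: Cascade, path) -> None:
    doc = {
        "input_name": C.input_name,
        "stages": [dict(name=s.name, role=s.role, M=s.M_max, m=s.m_min,
                        K=s.K, n=s.n) for s in C.stages],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cascade_config(path) -> Cascade:
    """Read an ordered stage list from YAML/JSON: blocks of
    {name, role, M, m, K, n} plus an optional input_name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    stages = tuple(
        HillStage(name=b["name"], role=b["role"], M_max=float(b["M"]),
                  m_min=float(b["m"]), K=float(b["K"]), n=float(b["n"]))
        for b in doc["stages"])
    return Cascade(stages=stages, input_name=doc.get("input_name", "arabinose (uM)"))


def load_landscape_config(path) -> Landscape:
    """Build a landscape from a config naming a built-in family.

    ``family: gaussian`` takes ``angle`` (radians) and optional ``bounds``;
    ``family: cascade_R`` takes an optional inline ``cascade`` block (as in
    :func:`load_cascade_config`; default: the built-in cascade), a
    ``window`` [lo, hi] and an optional ``plane`` block with
    ``x``/``y``: [stage, parameter] and ``bounds_x``/``bounds_y``.
    """
    from .landscapes import GaussianParams, make_rotated_gaussian

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    family = doc.get("family")
    if family == "gaussian":
        bounds = tuple(doc.get("bounds", (-3.0, 3.0)))
        return make_rotated_gaussian(GaussianParams(float(doc["angle"])), bounds)
    if family == "cascade_R":
        if "cascade" in doc:
            stages = tuple(
                HillStage(name=b["name"], role=b["role"], M_max=float(b["M"]),
                          m_min=float(b["m"]), K=float(b["K"]), n=float(b["n"]))
                for b in doc["cascade"]["stages"])
            C = Cascade(stages=stages)
        else:
            C = default_cascade()
        w = InputRange(*doc.get("window", (0.0, 100.0)))
        if "plane" in doc:
            p = doc["plane"]
            return r_landscape(C, w, tuple(p["x"]), tuple(p["y"]),
                               tuple(p["bounds_x"]), tuple(p["bounds_y"]))
        return default_plane(C, w)
    raise ValueError(f"unknown landscape family {family!r}")
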