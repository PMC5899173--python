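"""Data-facing pipeline: smooth-response fits, noise, significance and
empirical epistasis calls for combinatorial dose-response panels.

The pipeline mirrors how the combinatorial-cascade experiment is analysed:

1. raw plate-reader traces are reduced to one normalised-fluorescence value
   per well ((δF/δt)/(δOD/δt) over the exponential-growth window, blank
   subtracted) — :func:`normalize_plate_series`;
2. each genotype's dose-response (default 16 inputs × 3 replicates) is
   fitted with the four-parameter smooth response
   a·[ara]^d / (b^d + [ara]^d) + c — :func:`fit_smooth_response`;
3. measurement noise is summarised as Δ, the RMS deviation between the
   per-input replicate means and the fitted curve — :func:`noise_rmsd`;
4. the response range R over an input window is read off the fitted curve,
   tested for strict positivity against Δ, and differences of R between
   genotypes are tested with a two-sided Welch t-test (df = 44 per leg:
   48 measurement points minus the four fitted parameters);
5. every 2×2 genotype square in the panel is classified by the sign-flip
   rule using only significant single-mutation steps, with NS for squares
   in which no step is significant.

The user-facing entry point is the statsmodels-style pair
:class:`PanelEpistasisModel` (constructed from a tidy dataframe) whose
``fit()`` returns :class:`PanelEpistasisResults` carrying per-genotype
estimates, the epistasis call table, input-range sweeps and ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm, t as t_dist

from .cascade import InputRange
from .epistasis import count_pairwise_interactions

__all__ = [
    "DoseResponseRecord",
    "SmoothFit",
    "NoiseEstimate",
    "EmpiricalCall",
    "PipelineConfig",
    "normalize_plate_series",
    "fit_smooth_response",
    "response_range",
    "noise_rmsd",
    "test_R_positive",
    "test_step_change",
    "call_pairwise_epistasis",
    "sweep_input_ranges",
    "PanelEpistasisModel",
    "PanelEpistasisResults",
]

EMPIRICAL_CLASSES = ("magnitude", "downstream_sign", "upstream_sign",
                     "reciprocal", "NS")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and conventions of the calling pipeline.

    ``alpha_step`` gates single-mutation steps (trajectory threshold,
    p < 10⁻³); ``alpha_response`` gates single-genotype response
    significance (p < 0.05).  ``orientation`` fixes the direction in which
    the signed response range is taken for the one-sided positivity test
    ("decreasing": output falls with input, as in the three-repressor
    composition).  ``se_factor`` maps Δ to the standard error of R
    (R is a difference of two fitted endpoint values, each with
    uncertainty ≈ Δ, hence √2).  ``df_leg`` is the Welch degrees of freedom
    per genotype leg.
    """

    alpha_step: float = 1e-3
    alpha_response: float = 0.05
    orientation: Literal["increasing", "decreasing"] = "decreasing"
    se_factor: float = math.sqrt(2.0)
    df_leg: float = 44.0


@dataclass
class DoseResponseRecord:
    """Per-genotype measured (or simulated) dose-response curve.

    ``replicates`` has shape (n_inputs, n_reps): every input must carry the
    same replicate count and inputs must be strictly increasing.
    """

    genotype: tuple[str, str]
    inputs: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, float)
        self.replicates = np.asarray(self.replicates, float)
        if self.inputs.ndim != 1 or np.any(np.diff(self.inputs) <= 0):
            raise ValueError("inputs must be a strictly increasing 1D array")
        if self.replicates.shape[0] != self.inputs.size or self.replicates.ndim != 2:
            raise ValueError("replicates must have shape (n_inputs, n_reps)")

    @property
    def n_inputs(self) -> int:
        return self.inputs.size

    @property
    def n_reps(self) -> int:
        return self.replicates.shape[1]

    def replicate_means(self) -> np.ndarray:
        return self.replicates.mean(axis=1)


@dataclass(frozen=True)
class SmoothFit:
    """Fitted smooth response a·x^d/(b^d + x^d) + c with b, d > 0."""

    a: float
    b: float
    c: float
    d: float
    resid_rms: float
    n_points: int
    converged: bool = True

    def __call__(self, x):
        x = np.asarray(x, float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (x / self.b) ** self.d, 0.0)
        return self.a * ratio / (1.0 + ratio) + self.c


@dataclass(frozen=True)
class NoiseEstimate:
    """Δ: RMS deviation of replicate means from the fitted smooth curve,
    over N input points."""

    delta: float
    N: int


@dataclass(frozen=True)
class EmpiricalCall:
    """One classified 2×2 genotype square from measured data."""

    up_0: str
    up_1: str
    down_0: str
    down_1: str
    klass: str
    effects: Mapping[str, float]
    p_values: Mapping[str, float]
    window: tuple[float, float]
    response_significant: Mapping[str, bool]


# ---------------------------------------------------------------------------
# plate normalisation
# ---------------------------------------------------------------------------

def normalize_plate_series(time: np.ndarray, od: np.ndarray, fluor: np.ndarray,
                           blank: float = 0.0,
                           window: tuple[int, int] | None = None,
                           od_frac: tuple[float, float] = (0.05, 0.5),
                           ) -> float:
    """Reduce aligned, background-subtracted OD/fluorescence traces to one
    normalised fluorescence value.

    Computes (δFluorescence/δt)/(δOD/δt) per timepoint over the
    exponential-growth window and averages it, then subtracts the
    auto-fluorescence ``blank``.  When ``window`` (index pair) is not given,
    the exponential window is taken as the timepoints with OD between
    ``od_frac`` fractions of the maximum.  Errors on non-monotone OD or a
    vanishing OD derivative inside the window.
    """
    time = np.asarray(time, float)
    od = np.asarray(od, float)
    fluor = np.asarray(fluor, float)
    if window is None:
        mask = (od >= od_frac[0] * od.max()) & (od <= od_frac[1] * od.max())
        idx = np.nonzero(mask)[0]
        if idx.size < 3:
            raise ValueError("no identifiable exponential-growth window")
        sl = slice(idx[0], idx[-1] + 1)
    else:
        sl = slice(window[0], window[1] + 1)
    if np.any(np.diff(od[sl]) <= 0):
        raise ValueError("OD series not strictly increasing in the growth window")
    d_od = np.gradient(od, time)[sl]
    d_fl = np.gradient(fluor, time)[sl]
    if np.any(d_od == 0):
        raise ValueError("zero OD derivative inside the growth window")
    return float(np.mean(d_fl / d_od)) - blank


# ---------------------------------------------------------------------------
# smooth-response fitting
# ---------------------------------------------------------------------------

def _hill4(x, a, b, c, d):
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / b) ** d, 0.0)
    return a * ratio / (1.0 + ratio) + c


def _hill4_jac(x, a, b, c, d):
    with np.errstate(divide="ignore", over="ignore"):
        r = np.where(x > 0, (x / b) ** d, 0.0)
        logxb = np.where(x > 0, np.log(x / b), 0.0)
    denom = (1.0 + r) ** 2
    da = r / (1.0 + r)
    db = -a * r * d / (b * denom)
    dc = np.ones_like(x)
    dd = a * r * logxb / denom
    return np.stack([da, db, dc, dd], axis=-1)


def fit_smooth_response(rec: DoseResponseRecord) -> SmoothFit:
    """Nonlinear least squares of the four-parameter smooth response on all
    replicate points.

    Initialisation is a deterministic multi-start: a 3×3 grid of (b, d)
    starts with b at the decade quantiles of the positive inputs and slope
    d ∈ {0.5, 1.5, 3}; a and c start from the data extremes.  The start
    with the lowest residual wins; ties break to the lowest b.  Records for
    which no start converges are returned flagged (``converged=False``)
    and are excluded downstream.
    """
    if np.unique(rec.inputs).size < 5:
        raise ValueError("need at least 5 distinct inputs for the 4-parameter fit")
    x = np.repeat(rec.inputs, rec.n_reps)
    y = rec.replicates.ravel()
    pos = rec.inputs[rec.inputs > 0]
    b_starts = np.quantile(pos, [0.2, 0.5, 0.8])
    d_starts = (0.5, 1.5, 3.0)
    y_lo = float(rec.replicate_means()[0])
    y_hi = float(rec.replicate_means()[-1])
    a0, c0 = y_hi - y_lo, y_lo
    span = float(np.ptp(y)) or 1.0
    lo_b, hi_b = pos.min() * 1e-3, pos.max() * 1e3
    bounds = ([-10 * span - abs(a0), lo_b, y.min() - 5 * span, 0.02],
              [10 * span + abs(a0), hi_b, y.max() + 5 * span, 12.0])

    best = None
    for b0, d0 in itertools.product(b_starts, d_starts):
        p0 = [a0 if a0 != 0 else span * 0.1, float(b0), c0, float(d0)]
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(_hill4, x, y, p0=p0, bounds=bounds,
                                jac=_hill4_jac, maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        rms = float(np.sqrt(np.mean((_hill4(x, *popt) - y) ** 2)))
        key = (rms, popt[1])
        if best is None or key < best[0]:
            best = (key, popt)
    if best is None:
        return SmoothFit(a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                         resid_rms=np.nan, n_points=y.size, converged=False)
    popt = best[1]
    return SmoothFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                     d=float(popt[3]), resid_rms=best[0][0], n_points=y.size)


def response_range(fit: SmoothFit, w: InputRange,
                   orientation: Literal["increasing", "decreasing"] = "increasing",
                   ) -> tuple[float, float]:
    """(|R|, signed R) of the fitted curve over a window.

    The fitted form is monotone, so |R| = |f(in_max) − f(in_min)|.  The
    signed value is taken in the stated orientation: "increasing" counts a
    rising response as positive, "decreasing" a falling one.
    """
    if not fit.converged:
        raise ValueError("cannot take the response range of a non-converged fit")
    rise = float(fit(w.in_max) - fit(w.in_min))
    signed = rise if orientation == "increasing" else -rise
    return abs(rise), signed


def noise_rmsd(rec: DoseResponseRecord, fit: SmoothFit) -> NoiseEstimate:
    """Δ between per-input replicate means and the fitted curve."""
    mu = rec.replicate_means()
    resid = mu - fit(rec.inputs)
    return NoiseEstimate(delta=float(np.sqrt(np.mean(resid ** 2))),
                         N=rec.n_inputs)


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

def test_R_positive(R_signed: float, delta: NoiseEstimate | float,
                    se_factor: float = math.sqrt(2.0),
                    df_correct: bool = True, n_params: int = 4) -> float:
    """One-sided normal test of 'R is strictly positive'.

    The standard error of R is ``se_factor``·Δ (√2 by default: R is the
    difference of two fitted endpoint values, each with uncertainty ≈ Δ).
    Because Δ is the RMS residual of replicate means around a curve with
    ``n_params`` fitted parameters, it underestimates the mean-level noise
    by √((N − p)/N); ``df_correct`` (default on) inflates the SE by
    √(N/(N − p)) to keep the test calibrated.  Returns the p-value; R = 0
    gives exactly 0.5.
    """
    if isinstance(delta, NoiseEstimate):
        d = delta.delta
        if df_correct and delta.N > n_params:
            d *= math.sqrt(delta.N / (delta.N - n_params))
    else:
        d = float(delta)
    se = se_factor * d
    if se == 0.0:
        return 0.5 if R_signed == 0 else (0.0 if R_signed > 0 else 1.0)
    return float(norm.sf(R_signed / se))


def test_step_change(R1: float, delta1: NoiseEstimate | float,
                     R2: float, delta2: NoiseEstimate | float,
                     df_leg: float = 44.0,
                     se_factor: float = math.sqrt(2.0),
                     df_correct: bool = True, n_params: int = 4) -> float:
    """Two-sided Welch t-test for a change of response range between two
    genotypes.

    Each genotype leg contributes variance (se_factor·Δ)² = 2Δ² with
    ``df_leg`` degrees of freedom (44: 48 measurement points minus the four
    smooth-fit parameters); the degrees of freedom combine by
    Welch–Satterthwaite.  ``df_correct`` applies the same √(N/(N − p))
    inflation of Δ as :func:`test_R_positive`.
    """
    def _d(delta):
        if isinstance(delta, NoiseEstimate):
            d = delta.delta
            if df_correct and delta.N > n_params:
                d *= math.sqrt(delta.N / (delta.N - n_params))
            return d
        return float(delta)

    d1, d2 = _d(delta1), _d(delta2)
    v1, v2 = (se_factor * d1) ** 2, (se_factor * d2) ** 2
    if v1 + v2 == 0.0:
        return 1.0 if R1 == R2 else 0.0
    t_stat = (R1 - R2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / df_leg + v2 ** 2 / df_leg)
    return float(2.0 * t_dist.sf(abs(t_stat), df))


# ---------------------------------------------------------------------------
# pairwise calling
# ---------------------------------------------------------------------------

@dataclass
class _FittedGenotype:
    record: DoseResponseRecord
    fit: SmoothFit
    delta: NoiseEstimate

    def R(self, w: InputRange, orientation: str) -> tuple[float, float]:
        return response_range(self.fit, w, orientation)


def _fit_panel(panel: Sequence[DoseResponseRecord]) -> dict[tuple[str, str], _FittedGenotype]:
    out = {}
    for rec in panel:
        fit = fit_smooth_response(rec)
        if not fit.converged:
            continue
        out[rec.genotype] = _FittedGenotype(rec, fit, noise_rmsd(rec, fit))
    return out


def _check_complete(panel: Sequence[DoseResponseRecord]) -> tuple[list[str], list[str]]:
    ups = sorted({r.genotype[0] for r in panel})
    downs = sorted({r.genotype[1] for r in panel})
    have = {r.genotype for r in panel}
    missing = [f"{u}×{d}" for u in ups for d in downs if (u, d) not in have]
    if missing:
        raise ValueError(f"incomplete genotype grid; missing: {missing}")
    return ups, downs


def call_pairwise_epistasis(panel: Sequence[DoseResponseRecord], w: InputRange,
                            config: PipelineConfig = PipelineConfig(),
                            ) -> tuple[list[EmpiricalCall], dict[str, float]]:
    """Classify every 2×2 genotype square of a complete panel.

    For each square the four response ranges over ``w`` are compared: the
    downstream mutation's effect in both upstream backgrounds and vice
    versa, each step tested with the Welch test at ``config.alpha_step``.
    Steps that are not significant count as zero; a sign flip requires two
    significant opposing steps.  A square with no significant step at all is
    NS.  Per-genotype response positivity (at ``config.alpha_response``) is
    annotated on every call.

    Returns the calls plus class fractions over all emitted calls (NS
    included); fractions sum to 1.
    """
    ups, downs = _check_complete(panel)
    fitted = _fit_panel(panel)
    return _classify_fitted(fitted, ups, downs, w, config)


def _classify_fitted(fitted: Mapping[tuple[str, str], _FittedGenotype],
                     ups: Sequence[str], downs: Sequence[str],
                     w: InputRange, config: PipelineConfig,
                     ) -> tuple[list[EmpiricalCall], dict[str, float]]:
    dropped = [g for g in ((u, d) for u in ups for d in downs) if g not in fitted]
    if dropped:
        raise ValueError(f"smooth fit failed for genotypes: {dropped}")

    Rmag = {g: f.R(w, config.orientation)[0] for g, f in fitted.items()}
    Rsig = {g: f.R(w, config.orientation)[1] for g, f in fitted.items()}
    resp_ok = {g: test_R_positive(Rsig[g], fitted[g].delta, config.se_factor)
               < config.alpha_response for g in fitted}

    def step_p(g1, g2):
        return test_step_change(Rmag[g1], fitted[g1].delta,
                                Rmag[g2], fitted[g2].delta,
                                config.df_leg, config.se_factor)

    calls = []
    for u0, u1 in itertools.combinations(ups, 2):
        for d0, d1 in itertools.combinations(downs, 2):
            # x axis = downstream mutation, y axis = upstream mutation
            eff = {
                "dx_y0": Rmag[(u0, d1)] - Rmag[(u0, d0)],
                "dx_y1": Rmag[(u1, d1)] - Rmag[(u1, d0)],
                "dy_x0": Rmag[(u1, d0)] - Rmag[(u0, d0)],
                "dy_x1": Rmag[(u1, d1)] - Rmag[(u0, d1)],
            }
            pv = {
                "dx_y0": step_p((u0, d1), (u0, d0)),
                "dx_y1": step_p((u1, d1), (u1, d0)),
                "dy_x0": step_p((u1, d0), (u0, d0)),
                "dy_x1": step_p((u1, d1), (u0, d1)),
            }
            sig = {k: pv[k] < config.alpha_step for k in pv}
            s = {k: (np.sign(eff[k]) if sig[k] else 0.0) for k in eff}
            if not any(sig.values()):
                klass = "NS"
            else:
                x_flip = s["dx_y0"] * s["dx_y1"] == -1
                y_flip = s["dy_x0"] * s["dy_x1"] == -1
                if x_flip and y_flip:
                    klass = "reciprocal"
                elif x_flip:
                    klass = "downstream_sign"
                elif y_flip:
                    klass = "upstream_sign"
                else:
                    klass = "magnitude"
            calls.append(EmpiricalCall(
                up_0=u0, up_1=u1, down_0=d0, down_1=d1, klass=klass,
                effects=eff, p_values=pv, window=(w.in_min, w.in_max),
                response_significant={f"{u}-{d}": resp_ok[(u, d)]
                                      for u in (u0, u1) for d in (d0, d1)}))

    n = len(calls)
    fractions = {k: sum(c.klass == k for c in calls) / n
                 for k in EMPIRICAL_CLASSES}
    return calls, fractions


def sweep_input_ranges(panel: Sequence[DoseResponseRecord],
                       windows: Sequence[InputRange],
                       config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Class fractions per input window (the stacked-histogram table).

    Each genotype is fitted once; the windows only move the evaluation
    points on the fitted curves.
    """
    span = (min(r.inputs.min() for r in panel), max(r.inputs.max() for r in panel))
    ups, downs = _check_complete(panel)
    fitted = _fit_panel(panel)
    rows = []
    for w in windows:
        if w.in_min < span[0] or w.in_max > span[1]:
            raise ValueError(f"window {w} outside measured span {span}")
        _, fr = _classify_fitted(fitted, ups, downs, w, config)
        rows.append({"in_min": w.in_min, "in_max": w.in_max, **fr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class PanelEpistasisModel:
    """Epistasis-calling model for a combinatorial dose-response panel.

    Construct from records or a tidy dataframe with columns
    ``genotype_up, genotype_down, input_uM, replicate, output``, then call
    :meth:`fit`.

    Examples
    --------
    >>> model = PanelEpistasisModel.from_dataframe(data)   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, records: Sequence[DoseResponseRecord],
                 config: PipelineConfig = PipelineConfig()):
        self.records = list(records)
        self.config = config
        self.ups, self.downs = _check_complete(self.records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: PipelineConfig = PipelineConfig(),
                       ) -> "PanelEpistasisModel":
        required = {"genotype_up", "genotype_down", "input_uM", "replicate", "output"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataframe lacks columns {sorted(missing)}")
        records = []
        for (u, d), g in df.groupby(["genotype_up", "genotype_down"], sort=True):
            wide = g.pivot_table(index="input_uM", columns="replicate",
                                 values="output")
            if wide.isna().any().any():
                raise ValueError(f"unequal replicate counts for genotype {(u, d)}")
            records.append(DoseResponseRecord(
                genotype=(str(u), str(d)), inputs=wide.index.to_numpy(),
                replicates=wide.to_numpy()))
        return cls(records, config)

    def fit(self) -> "PanelEpistasisResults":
        fitted = _fit_panel(self.records)
        dropped = [r.genotype for r in self.records if r.genotype not in fitted]
        return PanelEpistasisResults(self, fitted, dropped)


class PanelEpistasisResults:
    """Fitted panel: per-genotype smooth fits, noise and response ranges,
    plus epistasis calls on demand."""

    def __init__(self, model: PanelEpistasisModel,
                 fitted: dict[tuple[str, str], _FittedGenotype],
                 dropped: list[tuple[str, str]]):
        self.model = model
        self._fitted = fitted
        self.dropped = dropped
        full = InputRange(min(r.inputs.min() for r in model.records),
                          max(r.inputs.max() for r in model.records))
        self.full_window = full
        rows = []
        for g, f in fitted.items():
            Rm, Rs = f.R(full, model.config.orientation)
            p = test_R_positive(Rs, f.delta, model.config.se_factor)
            rows.append(dict(genotype_up=g[0], genotype_down=g[1],
                             a=f.fit.a, b=f.fit.b, c=f.fit.c, d=f.fit.d,
                             delta=f.delta.delta, R=Rm, R_signed=Rs,
                             p_R_positive=p,
                             responding=p < model.config.alpha_response))
        self.fits = pd.DataFrame(rows).set_index(["genotype_up", "genotype_down"])

    @property
    def n_responding(self) -> int:
        return int(self.fits["responding"].sum())

    def calls(self, window: InputRange | None = None,
              ) -> tuple[list[EmpiricalCall], dict[str, float]]:
        w = window or self.full_window
        return _classify_fitted(self._fitted, self.model.ups, self.model.downs,
                                w, self.model.config)

    def calls_frame(self, window: InputRange | None = None) -> pd.DataFrame:
        calls, _ = self.calls(window)
        return pd.DataFrame([dict(up_0=c.up_0, up_1=c.up_1, down_0=c.down_0,
                                  down_1=c.down_1, klass=c.klass,
                                  **{f"p_{k}": v for k, v in c.p_values.items()})
                             for c in calls])

    def sweep(self, windows: Sequence[InputRange]) -> pd.DataFrame:
        span = (min(r.inputs.min() for r in self.model.records),
                max(r.inputs.max() for r in self.model.records))
        rows = []
        for w in windows:
            if w.in_min < span[0] or w.in_max > span[1]:
                raise ValueError(f"window {w} outside measured span {span}")
            _, fr = self.calls(w)
            rows.append({"in_min": w.in_min, "in_max": w.in_max, **fr})
        return pd.DataFrame(rows)

    def summary(self, window: InputRange | None = None) -> str:
        w = window or self.full_window
        _, fr = self.calls(w)
        n_up, n_down = len(self.model.ups), len(self.model.downs)
        lines = [
            "Combinatorial cascade panel — epistasis summary",
            "=" * 55,
            f"panel:            {n_up} upstream × {n_down} downstream variants "
            f"({n_up * n_down} genotypes)",
            f"pairwise squares: {count_pairwise_interactions(n_up, n_down)}",
            f"input window:     {w.in_min:g}–{w.in_max:g} µM",
            f"responding genotypes (p < {self.model.config.alpha_response:g}): "
            f"{self.n_responding}/{len(self.fits)}",
            "-" * 55,
            "class fractions over all squares:",
        ]
        for k in EMPIRICAL_CLASSES:
            lines.append(f"  {k:<16s} {fr[k]:6.1%}")
        lines.append("-" * 55)
        lines.append(f"median fitted Hill slope d: {self.fits['d'].median():.2f}; "
                     f"median noise Δ: {self.fits['delta'].median():.3g}")
        return "\n".join(lines)

    def plot_responses(self, axes=None):
        """Grid of dose-response curves with fits, one panel per genotype."""
        import matplotlib.pyplot as plt

        n_up, n_down = len(self.model.ups), len(self.model.downs)
        if axes is None:
            _, axes = plt.subplots(n_up, n_down, sharex=True, sharey=True,
                                   figsize=(2 * n_down, 1.6 * n_up))
        axes = np.atleast_2d(axes)
        xs = None
        for i, u in enumerate(self.model.ups):
            for j, d in enumerate(self.model.downs):
                ax = axes[i, j]
                f = self._fitted.get((u, d))
                if f is None:
                    continue
                rec = f.record
                xs = np.linspace(rec.inputs.min(), rec.inputs.max(), 100)
                ax.plot(rec.inputs, rec.replicates, ".", ms=3, color="0.6")
                ax.plot(xs, f.fit(xs), "-", color="tab:blue")
                ax.set_title(f"{u}–{d}", fontsize=7)
        return axes
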