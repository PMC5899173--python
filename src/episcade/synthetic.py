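"""Synthetic mutant panels and dose-response datasets with ground truth.

The generator emulates the study design the analysis assumes: a panel of
upstream-gene variants (default 5, tetR-like) crossed with downstream-gene
variants (default 7, lacI-like) — 35 cascade genotypes — each measured at
16 arabinose concentrations spanning 0–100 µM (log-spaced plus an explicit
zero) in 3 biological replicates, with additive Gaussian measurement noise
on the normalised-fluorescence output.  Variants differ in their
dissociation constant (log-uniform around wild type), Hill cooperativity
and, slightly, expression bounds; one variant per gene is the wild type at
the range midpoint.

Every stochastic operation is a pure function of (spec, seed).  Alongside
the tidy measurement table the generators emit full ground truth: the
noiseless response curves and the theoretical epistasis class of every 2x2
variant square, computed with the same classifier used for model
landscapes, so end-to-end recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import Cascade, HillStage, InputRange, default_cascade, response_range_R
from .epistasis import CLASSES, classify_effects

__all__ = [
    "VariantPanelSpec",
    "MeasurementSpec",
    "sample_variant_panel",
    "simulate_panel_measurements",
    "make_null_dataset",
    "theoretical_square_classes",
    "default_inputs",
]


def default_inputs(n: int = 16, top: float = 100.0) -> np.ndarray:
    """Default input grid: an explicit zero plus log-spaced concentrations
    up to ``top`` µM (Hill responses are log-sensitive)."""
    return np.concatenate([[0.0], np.logspace(-1, np.log10(top), n - 1)])


@dataclass(frozen=True)
class VariantPanelSpec:
    """Design of the combinatorial variant panel.

    ``k_log10_span`` is the total log10 spread of dissociation constants
    (2 decades by default, centred on wild type, enough to populate all
    epistasis domains); ``n_rel_span`` and ``expr_rel_span`` are relative
    spreads of the Hill coefficient and of the expression bounds.
    """

    n_upstream: int = 5
    n_downstream: int = 7
    k_log10_span: float = 2.0
    n_rel_span: float = 0.3
    expr_rel_span: float = 0.1
    include_wildtype: bool = True

    def __post_init__(self) -> None:
        if self.n_upstream < 2 or self.n_downstream < 2:
            raise ValueError("need at least two variants per gene")
        if self.k_log10_span < 0 or self.n_rel_span < 0 or self.expr_rel_span < 0:
            raise ValueError("spans must be non-negative")


@dataclass(frozen=True)
class MeasurementSpec:
    """Measurement design: input grid, replication and noise."""

    inputs: tuple[float, ...] = tuple(default_inputs())
    n_reps: int = 3
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_reps < 1:
            raise ValueError("need at least one replicate")
        inputs = np.asarray(self.inputs, float)
        if inputs.ndim != 1 or np.any(np.diff(inputs) <= 0):
            raise ValueError("inputs must be strictly increasing")


def _sample_gene_variants(rng: np.random.Generator, wt: HillStage, n_var: int,
                          spec: VariantPanelSpec, gene: str) -> list[HillStage]:
    half = spec.k_log10_span / 2.0
    variants = []
    for i in range(n_var):
        if i == 0 and spec.include_wildtype:
            variants.append(replace(wt, name=f"{gene}_1"))
            continue
        K = wt.K * 10.0 ** rng.uniform(-half, half)
        n = wt.n * (1.0 + rng.uniform(-spec.n_rel_span, spec.n_rel_span))
        M = wt.M_max * (1.0 + rng.uniform(-spec.expr_rel_span, spec.expr_rel_span))
        m = wt.m_min * (1.0 + rng.uniform(-spec.expr_rel_span, spec.expr_rel_span))
        variants.append(replace(wt, name=f"{gene}_{i + 1}", K=K, n=n,
                                M_max=M, m_min=min(m, M / 2), ))
    return variants


def sample_variant_panel(spec: VariantPanelSpec, seed: int,
                         cascade: Cascade | None = None,
                         upstream_gene: str = "tetR",
                         downstream_gene: str = "lacI",
                         ) -> tuple[dict[str, list[HillStage]], pd.DataFrame]:
    """Draw the variant panel for both mutated genes.

    Returns ``(variants, truth)`` where ``variants`` maps gene name to its
    variant :class:`HillStage` list (variant 1 = wild type when
    ``include_wildtype``) and ``truth`` tabulates every variant's
    parameters.  Deterministic under ``seed``.
    """
    cascade = cascade or default_cascade()
    rng = np.random.default_rng(seed)
    panel = {}
    rows = []
    for gene, n_var in ((upstream_gene, spec.n_upstream),
                        (downstream_gene, spec.n_downstream)):
        wt = cascade.stages[cascade.stage_index(gene)]
        panel[gene] = _sample_gene_variants(rng, wt, n_var, spec, gene)
        for v in panel[gene]:
            rows.append(dict(gene=gene, variant=v.name, K=v.K, n=v.n,
                             M_max=v.M_max, m_min=v.m_min,
                             wildtype=v.name.endswith("_1") and spec.include_wildtype))
    return panel, pd.DataFrame(rows)


def _genotype_cascade(cascade: Cascade, up: HillStage, down: HillStage,
                      upstream_gene: str, downstream_gene: str) -> Cascade:
    return (cascade
            .with_stage_params(upstream_gene, K=up.K, n=up.n,
                               M_max=up.M_max, m_min=up.m_min)
            .with_stage_params(downstream_gene, K=down.K, n=down.n,
                               M_max=down.M_max, m_min=down.m_min))


def theoretical_square_classes(variants: Mapping[str, list[HillStage]],
                               cascade: Cascade, window: InputRange,
                               upstream_gene: str = "tetR",
                               downstream_gene: str = "lacI",
                               tol: float = 1e-9) -> pd.DataFrame:
    """Ground-truth epistasis class of every 2x2 variant square.

    Performance of a genotype is the model response range |R| over
    ``window``; squares are classified by the same sign-flip rule used for
    landscape maps.  The x role is the downstream gene, so ``x_sign`` maps
    to downstream sign epistasis.
    """
    ups = variants[upstream_gene]
    downs = variants[downstream_gene]
    R = np.array([[response_range_R(
        _genotype_cascade(cascade, u, d, upstream_gene, downstream_gene),
        window).value for d in downs] for u in ups])
    scale = float(np.ptp(R)) or 1.0
    rows = []
    label = {"x_sign": "downstream_sign", "y_sign": "upstream_sign"}
    for i0 in range(len(ups)):
        for i1 in range(i0 + 1, len(ups)):
            for j0 in range(len(downs)):
                for j1 in range(j0 + 1, len(downs)):
                    # x = downstream index, y = upstream index
                    dx_y0 = R[i0, j1] - R[i0, j0]
                    dx_y1 = R[i1, j1] - R[i1, j0]
                    dy_x0 = R[i1, j0] - R[i0, j0]
                    dy_x1 = R[i1, j1] - R[i0, j1]
                    code = int(classify_effects(dx_y0, dx_y1, dy_x0, dy_x1,
                                                tol * scale))
                    klass = CLASSES[code]
                    rows.append(dict(
                        up_0=ups[i0].name, up_1=ups[i1].name,
                        down_0=downs[j0].name, down_1=downs[j1].name,
                        klass=label.get(klass, klass)))
    return pd.DataFrame(rows)


def simulate_panel_measurements(variants: Mapping[str, list[HillStage]],
                                cascade_template: Cascade,
                                mspec: MeasurementSpec,
                                upstream_gene: str = "tetR",
                                downstream_gene: str = "lacI",
                                sigma_scales_with_output: bool = False,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the tidy per-replicate measurement table for a full panel.

    Returns ``(data, truth_curves)``.  ``data`` has the schema consumed by
    the empirical pipeline — columns genotype_up, genotype_down, input_uM,
    replicate, output — with i.i.d. Gaussian noise of sd ``noise_sigma``
    per replicate reading (optionally scaled by the local output level
    relative to the genotype's maximum).  ``truth_curves`` holds the
    noiseless model output per genotype and input.
    """
    rng = np.random.default_rng(mspec.seed)
    inputs = np.asarray(mspec.inputs, float)
    rows = []
    truth = []
    for u in variants[upstream_gene]:
        for d in variants[downstream_gene]:
            cc = _genotype_cascade(cascade_template, u, d,
                                   upstream_gene, downstream_gene)
            clean = np.asarray(cc.output(inputs), float)
            for x, y in zip(inputs, clean):
                truth.append(dict(genotype_up=u.name, genotype_down=d.name,
                                  input_uM=x, output=y))
            if sigma_scales_with_output:
                sig = mspec.noise_sigma * clean / clean.max()
            else:
                sig = np.full_like(clean, mspec.noise_sigma)
            noise = rng.normal(0.0, 1.0, size=(mspec.n_reps, inputs.size))
            for r in range(mspec.n_reps):
                for j, x in enumerate(inputs):
                    rows.append(dict(genotype_up=u.name, genotype_down=d.name,
                                     input_uM=x, replicate=r + 1,
                                     output=clean[j] + sig[j] * noise[r, j]))
    return pd.DataFrame(rows), pd.DataFrame(truth)


def make_null_dataset(mspec: MeasurementSpec, n_genotypes: int = 100,
                      level: float = 50.0) -> pd.DataFrame:
    """Flat-response genotypes plus noise, for type-I-error calibration.

    Every genotype's true response is the constant ``level`` at all inputs;
    any detected response range is a false positive.
    """
    rng = np.random.default_rng(mspec.seed)
    inputs = np.asarray(mspec.inputs, float)
    rows = []
    for g in range(n_genotypes):
        noise = rng.normal(0.0, mspec.noise_sigma,
                           size=(mspec.n_reps, inputs.size))
        for r in range(mspec.n_reps):
            for j, x in enumerate(inputs):
                rows.append(dict(genotype_up=f"null_{g + 1}", genotype_down="flat",
                                 input_uM=x, replicate=r + 1,
                                 output=level + noise[r, j]))
    return pd.DataFrame(rows)
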