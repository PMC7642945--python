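"""Synthetic multi-environment ordinal genomic data from the liability model.

Generates marker dosages, builds the E + G (+ GE) design through the same
machinery used for real data, draws coefficients so a target share of latent
variance is genetic, and thresholds the liabilities into ordinal categories.
Every generator is a pure function of (scenario, seed).

Default scenario: 100 lines genotyped at 500 biallelic markers, evaluated in
15 environments (1500 records), a 5-level trait with uniform marginal
category frequencies, and half the latent variance explained by the linear
predictor — mirroring the scale of multi-environment wheat screening
nurseries where 5-level ordinal scores (days-to-heading classes, rust or
lodging scales) are typical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, DesignSpec, MarkerMatrix, Relationship, \
    build_design, compute_grm, scale_markers
from .ecm import FitResult, OrdinalDataset, ThresholdState

__all__ = ["SimScenario", "SimTruth", "simulate_markers", "simulate_trial",
           "simulate_from_fit"]


@dataclass
class SimScenario:
    n_lines: int = 100
    n_markers: int = 500
    n_envs: int = 15
    C: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    R2_target: float = 0.5
    category_probs: tuple[float, ...] | None = None  # None -> uniform
    with_GE: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need at least two categories")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        if self.category_probs is None:
            self.category_probs = tuple([1.0 / self.C] * self.C)
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape[0] != self.C or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("category_probs must have C entries summing to 1")
        if np.any(probs <= 0):
            raise ValueError("category_probs must be strictly positive")
        if not 0.0 < self.R2_target < 1.0:
            raise ValueError("R2_target must lie in (0, 1)")


@dataclass
class SimTruth:
    """Generating parameters and per-record latent quantities."""

    beta_true: np.ndarray
    gamma_true: np.ndarray
    eta_true: np.ndarray
    liabilities: np.ndarray
    design: DesignMatrix = field(repr=False, default=None)
    relationship: Relationship = field(repr=False, default=None)


def simulate_markers(scenario: SimScenario,
                     rng: np.random.Generator | None = None) -> MarkerMatrix:
    """Binomial(2, maf_j) dosages per marker, standardised downstream.

    Allele frequencies are drawn uniformly from ``maf_range``; markers that
    come out monomorphic in the sample are dropped by the scaling step.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    maf = rng.uniform(*scenario.maf_range, size=scenario.n_markers)
    raw = rng.binomial(2, maf, size=(scenario.n_lines, scenario.n_markers))
    line_ids = [f"L{i + 1:04d}" for i in range(scenario.n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(scenario.n_markers)]
    return scale_markers(raw.astype(float), line_ids, marker_ids)


def simulate_trial(scenario: SimScenario
                   ) -> tuple[OrdinalDataset, SimTruth]:
    """Draw a complete multi-environment ordinal trial from the liability model.

    Liabilities are ``l_i = -eta_i + eps_i`` with ``eps ~ N(0, 1)`` and
    ``eta = X beta``; per-column coefficient variance is set so the expected
    linear-predictor share of the total latent variance matches
    ``1 - R2_target`` (total ``Vl = 1 / R2_target``).  Cut-points are placed
    at the ``category_probs`` quantiles of the marginal liability
    distribution, so the marginal category frequencies hit their targets.
    """
    rng = np.random.default_rng(scenario.seed)
    markers = simulate_markers(scenario, rng)
    rel = compute_grm(markers)

    env_ids = [f"E{e + 1:02d}" for e in range(scenario.n_envs)]
    records = pd.DataFrame(
        [(line, env) for env in env_ids for line in markers.line_ids],
        columns=["line", "env"])
    blocks = ["E", "G", "GE"] if scenario.with_GE else ["E", "G"]
    design = build_design(records, rel, DesignSpec(blocks=blocks))

    msq = float(np.sum(design.X ** 2) / design.n_records)
    var_eta_target = (1.0 - scenario.R2_target) / scenario.R2_target
    sigma_b = np.sqrt(var_eta_target / msq)
    beta_true = rng.normal(0.0, sigma_b, size=design.p)
    # environment main effects sum to zero: the overall location belongs to
    # the cut-points, and the G/GE columns already have zero record means
    e_cols = np.asarray(design.column_block) == "E"
    if e_cols.any():
        beta_true[e_cols] -= beta_true[e_cols].mean()
    eta = design.X @ beta_true
    # rescale the realised predictor so the sample variance split equals the
    # target exactly (the usual device for hitting a target heritability)
    v = float(np.var(eta))
    if v <= 0:
        raise ValueError("degenerate design: predictor has zero variance")
    beta_true *= np.sqrt(var_eta_target / v)
    eta = design.X @ beta_true
    liab = -eta + rng.normal(size=design.n_records)

    v_l = var_eta_target + 1.0
    cum = np.cumsum(scenario.category_probs)[:-1]
    gamma_true = np.sqrt(v_l) * stats.norm.ppf(cum)
    y = 1 + np.searchsorted(gamma_true, liab)

    data = OrdinalDataset(y=y, X=design.X, C=scenario.C,
                          column_ids=design.column_block,
                          record_map=design.record_map)
    truth = SimTruth(beta_true=beta_true, gamma_true=gamma_true,
                     eta_true=eta, liabilities=liab, design=design,
                     relationship=rel)
    return data, truth


def simulate_from_fit(fit: FitResult, design: DesignMatrix,
                      seed: int = 0) -> OrdinalDataset:
    """Parametric-bootstrap responses from a fitted model at a given design."""
    thr: ThresholdState = fit.thresholds
    gamma = thr.gamma
    if np.any(np.diff(gamma) <= 0):
        raise ValueError("fitted cut-points must be strictly increasing")
    rng = np.random.default_rng(seed)
    eta = design.X @ fit.coefficients.beta
    liab = -eta + rng.normal(size=design.n_records)
    y = 1 + np.searchsorted(gamma, liab)
    return OrdinalDataset(y=y, X=design.X, C=thr.C,
                          column_ids=design.column_block,
                          record_map=design.record_map)
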