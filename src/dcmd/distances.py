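"""Distributional L2 distances between sample-specific distributions.

Two metrics are provided, both quadratic forms in the difference of
posterior component weights:

* **D-L2** — the discrete L2 norm between category pmfs,
  ``sum_x [P_a(x) - P_b(x)]^2`` over x = z, 0..C, C+, which equals
  ``(w_a - w_b) (P P') (w_a - w_b)'`` for the component pmf matrix P.
* **CC-L2** — the continuous cumulative L2 norm,
  ``int_0^C [F_a(x) - F_b(x)]^2 dx`` between mixture CDFs, which equals
  ``(w_a - w_b) G (w_a - w_b)'`` with Gram matrix
  ``G[m1, m2] = int_0^C F_m1(x) F_m2(x) dx`` over component CDFs.

Point-mass CDF conventions on [0, C]: the structural-zero mass has F == 1
(all its mass is at zero) and the high-count mass has F == 0 (all its mass
lies above C).  Distances are used as squared norms, exactly as defined;
per-OTU distances add across OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammainc

from .mixture import ComponentSet
from .sample_dist import ComponentPMFMatrix, SampleDistribution, component_pmf_matrix


@dataclass
class GramMatrix:
    """Symmetric PSD matrix of pairwise component CDF inner products on [0, C]."""

    G: np.ndarray
    components: ComponentSet


@dataclass
class DistanceMatrix:
    """Symmetric pairwise total distances with zero diagonal."""

    D: np.ndarray
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def _check_same_components(a: SampleDistribution, b: SampleDistribution) -> None:
    if a.components != b.components:
        raise ValueError("sample distributions come from different component sets")


def d_l2(a: SampleDistribution, b: SampleDistribution) -> float:
    """Discrete L2 distance: sum over categories of squared pmf differences."""
    _check_same_components(a, b)
    diff = a.pmf - b.pmf
    return float(diff @ diff)


def d_l2_gram(components: ComponentSet, P: ComponentPMFMatrix | None = None) -> GramMatrix:
    """Weight-space Gram matrix P P' realizing D-L2 as a quadratic form."""
    if P is None:
        P = component_pmf_matrix(components)
    return GramMatrix(G=P.P @ P.P.T, components=components)


def cc_l2_gram(components: ComponentSet, quadrature_step: float = 0.01) -> GramMatrix:
    """Gram matrix of component CDF products on [0, C] by trapezoid quadrature.

    Gamma components use the continuous Gamma(alpha, beta) CDF; the
    structural-zero mass has CDF 1 on [0, C]; the high-count mass has CDF 0.
    """
    C = float(components.C)
    n_pts = max(int(round(C / quadrature_step)) + 1, 2)
    x = np.linspace(0.0, C, n_pts)
    n = components.n_components
    F = np.zeros((n, n_pts))
    alphas = components.alphas()[:, None]
    betas = components.betas()[:, None]
    F[components.gamma_slice] = gammainc(alphas, betas * x[None, :])
    if components.has_zero_mass:
        F[components.zero_index] = 1.0
    # high-count mass row stays 0: its CDF vanishes below C
    wts = np.full(n_pts, x[1] - x[0])
    wts[0] *= 0.5
    wts[-1] *= 0.5
    G = (F * wts) @ F.T
    G = 0.5 * (G + G.T)
    return GramMatrix(G=G, components=components)


def cc_l2(a: SampleDistribution, b: SampleDistribution, G: GramMatrix) -> float:
    """Continuous cumulative L2 distance as the quadratic form (dw) G (dw)'."""
    _check_same_components(a, b)
    if G.components != a.components:
        raise ValueError("Gram matrix belongs to a different component set")
    dw = a.w - b.w
    return max(float(dw @ G.G @ dw), 0.0)


def pairwise_quadratic(
    W_a: np.ndarray, W_b: np.ndarray, G: np.ndarray
) -> np.ndarray:
    """All pairwise quadratic-form distances between weight-row matrices.

    Returns D with D[i, j] = (W_a[i] - W_b[j]) G (W_a[i] - W_b[j])'.
    """
    GA = W_a @ G
    sa = np.einsum("ij,ij->i", GA, W_a)
    sb = np.einsum("ij,ij->i", W_b @ G, W_b)
    D = sa[:, None] + sb[None, :] - 2.0 * (GA @ W_b.T)
    return np.clip(D, 0.0, None)


def total_distance(
    samples_a: Sequence[SampleDistribution],
    samples_b: Sequence[SampleDistribution],
    metric: str = "d_l2",
    grams: Sequence[GramMatrix] | None = None,
) -> float:
    """Total distance between two samples: the sum of per-OTU distances.

    ``samples_a`` and ``samples_b`` list one distribution per OTU, in the
    same OTU order.  ``metric`` is ``'d_l2'`` or ``'cc_l2'``; the latter
    needs per-OTU Gram matrices.
    """
    if len(samples_a) != len(samples_b):
        raise ValueError("samples cover different OTU sets")
    for da, db in zip(samples_a, samples_b):
        _check_same_components(da, db)
    if metric == "d_l2":
        return float(sum(d_l2(da, db) for da, db in zip(samples_a, samples_b)))
    if metric == "cc_l2":
        if grams is None:
            grams = [cc_l2_gram(da.components) for da in samples_a]
        return float(
            sum(cc_l2(da, db, g) for da, db, g in zip(samples_a, samples_b, grams))
        )
    raise ValueError(f"unknown metric {metric!r}")
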