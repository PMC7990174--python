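"""Sample-specific distributions conditional on a fitted mixture.

Each observed count ``n_i`` is converted into a posterior over the mixture
components given the sample's resolution ``t_i`` and the fitted joint
weights, and thence into a discrete pmf ``P_i`` over the count categories
x = z, 0, 1, ..., C, C+ (``z`` is the structural-zero category, kept
distinct from an observed zero).  These distributions, rather than the raw
counts, are the objects the distance metrics compare.

The posterior uses each sample's own resolution; the category pmf matrix
``P`` is evaluated at unit resolution, so that resolution differences enter
only through the posterior weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .mixture import ComponentSet, FittedMixture, nb_pmf_grid


@dataclass
class ComponentPMFMatrix:
    """Rows: components (z, Gammas, C+); columns: categories z, 0..C, C+.

    Gamma rows are NB(alpha_m, beta_m/(1+beta_m)) over x = 0..C with the
    residual tail mass in the C+ column; the point-mass rows are category
    indicators, so each row sums to one.
    """

    P: np.ndarray
    components: ComponentSet

    @property
    def category_labels(self) -> list[str]:
        return ["z"] + [str(x) for x in range(self.components.C + 1)] + ["C+"]


@dataclass
class SampleDistribution:
    """Posterior component weights and induced category pmf for one sample."""

    w: np.ndarray
    pmf: np.ndarray
    components: ComponentSet


def component_pmf_matrix(mixture: FittedMixture | ComponentSet) -> ComponentPMFMatrix:
    """Category probabilities per component at unit resolution.

    Accepts a fitted mixture or a bare component set (the matrix depends
    only on the components).
    """
    comp = mixture if isinstance(mixture, ComponentSet) else mixture.components
    C = comp.C
    n = comp.n_components
    P = np.zeros((n, C + 3))  # columns: z, 0..C, C+
    pmf = nb_pmf_grid(comp.alphas(), comp.betas(), np.array([1.0]), C)[:, :, 0]
    gs = comp.gamma_slice
    P[gs, 1 : C + 2] = pmf
    P[gs, C + 2] = np.clip(1.0 - pmf.sum(axis=1), 0.0, None)
    if comp.has_zero_mass:
        P[comp.zero_index, 0] = 1.0
    if comp.has_high_mass:
        P[comp.high_index, C + 2] = 1.0
    return ComponentPMFMatrix(P=P, components=comp)


def component_posterior(n: int, t: float, mixture: FittedMixture) -> np.ndarray:
    """Posterior component weights w_i for observed count ``n`` at resolution ``t``.

    Gamma components contribute w_m * NB(n; alpha_m, beta_m/(t+beta_m));
    the zero mass contributes w_z * 1(n = 0) and the high mass
    w_{C+} * 1(n > C); the vector is normalized to the simplex.
    """
    if n < 0 or t <= 0:
        raise ValueError("need n >= 0 and t > 0")
    comp = mixture.components
    p = np.zeros(comp.n_components)
    alphas, betas = comp.alphas(), comp.betas()
    probs = betas / (t + betas)
    p[comp.gamma_slice] = mixture.w[comp.gamma_slice] * nbinom.pmf(n, alphas, probs)
    if comp.has_zero_mass and n == 0:
        p[comp.zero_index] = mixture.w[comp.zero_index]
    if comp.has_high_mass and n > comp.C:
        p[comp.high_index] = mixture.w[comp.high_index]
    s = p.sum()
    if s <= 0:
        raise ValueError(
            f"count {n} has zero likelihood under every component of the fitted mixture"
        )
    return p / s


def posterior_weights(counts, t, mixture: FittedMixture) -> np.ndarray:
    """Vectorized ``component_posterior`` over samples: returns (I, n_components)."""
    counts = np.asarray(counts)
    t = np.asarray(t, dtype=float)
    comp = mixture.components
    I = counts.size
    W = np.zeros((I, comp.n_components))
    alphas, betas = comp.alphas(), comp.betas()
    probs = betas[None, :] / (t[:, None] + betas[None, :])
    W[:, comp.gamma_slice] = mixture.w[comp.gamma_slice] * nbinom.pmf(
        counts[:, None], alphas[None, :], probs
    )
    if comp.has_zero_mass:
        W[counts == 0, comp.zero_index] = mixture.w[comp.zero_index]
    if comp.has_high_mass:
        W[counts > comp.C, comp.high_index] = mixture.w[comp.high_index]
    s = W.sum(axis=1)
    bad = s <= 0
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"sample index {i} (count {counts[i]}) has zero likelihood under the mixture"
        )
    return W / s[:, None]


def sample_pmf(w_i: np.ndarray, P: ComponentPMFMatrix) -> np.ndarray:
    """Category pmf P_i = w_i' P; P_i(z) = w_iz and the C+ column carries the
    residual 1 - [sum_{x<=C} P_i(x) + P_i(z)]."""
    w_i = np.asarray(w_i, dtype=float)
    if w_i.shape != (P.P.shape[0],):
        raise ValueError("sample weights do not match the pmf matrix")
    pmf = w_i @ P.P
    if pmf[-1] < -1e-10:
        raise ValueError("negative residual mass at C+: inconsistent pmf matrix")
    return np.clip(pmf, 0.0, None)


def sample_distribution(
    n: int, t: float, mixture: FittedMixture, P: ComponentPMFMatrix | None = None
) -> SampleDistribution:
    """Posterior weights and category pmf for one observed count."""
    if P is None:
        P = component_pmf_matrix(mixture)
    w_i = component_posterior(n, t, mixture)
    return SampleDistribution(w=w_i, pmf=sample_pmf(w_i, P), components=mixture.components)


def distributions_to_frame(
    dists: list[SampleDistribution], sample_ids: list[str]
) -> pd.DataFrame:
    """Wide table of per-sample category probabilities (for inspection)."""
    if not dists:
        raise ValueError("no distributions")
    C = dists[0].components.C
    cols = ["z"] + [str(x) for x in range(C + 1)] + ["C+"]
    return pd.DataFrame(
        np.vstack([d.pmf for d in dists]), index=sample_ids, columns=cols
    )
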