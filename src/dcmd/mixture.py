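"""Poisson-Gamma mixture models for one OTU's counts.

Counts ``n_i`` are modelled as Poisson with rate ``r*_i t_i`` where the
normalized rate ``r*`` follows a mixture ``G`` over an ordered component set

    Omega = (G_z, G_1, ..., G_M, G_{C+})

of a structural-zero point mass, Gamma(alpha_m, beta_m) components, and a
high-count point mass absorbing counts above the truncation point ``C``.
Conditional on the resolution ``t_i``, a Gamma(alpha, beta) component yields
a negative binomial count, NB(alpha, beta/(t_i + beta)).

Component weights are estimated by least squares between observed and
expected aggregate count frequencies over x = 0..C, C+, constrained to the
probability simplex.  Model uncertainty near zero is handled by averaging a
set of nested candidate models (progressively dropping the lowest-mean
Gamma components) with weights given by bootstrap selection frequencies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import nbinom

from ._solver import fit_simplex_weights, simplex_lsq_normal
from .otu_table import Resolutions

logger = logging.getLogger(__name__)

#: low-rate components eligible for exclusion in nested candidates have
#: mean strictly below this (Gamma(1,2), Gamma(1,1), Gamma(2,1), Gamma(3,1))
_DROPPABLE_MEAN_LIMIT = 4.0


@dataclass(frozen=True)
class GammaComponent:
    """Gamma(alpha, beta) rate component with shape ``alpha``, rate ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0 and
                math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("Gamma parameters must be finite and positive")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class ComponentSet:
    """Ordered mixture components: zero mass, Gammas (ascending mean), C+ mass."""

    gammas: tuple[GammaComponent, ...]
    C: int
    has_zero_mass: bool = True
    has_high_mass: bool = True

    def __post_init__(self):
        if len(self.gammas) == 0:
            raise ValueError("component set needs at least one Gamma component")
        means = [g.mean for g in self.gammas]
        if any(b < a for a, b in zip(means, means[1:])):
            object.__setattr__(
                self, "gammas", tuple(sorted(self.gammas, key=lambda g: g.mean))
            )
        if self.C < 1:
            raise ValueError("truncation point C must be a positive integer")

    @property
    def n_components(self) -> int:
        return len(self.gammas) + int(self.has_zero_mass) + int(self.has_high_mass)

    @property
    def labels(self) -> list[str]:
        out = ["z"] if self.has_zero_mass else []
        out += [f"G({g.alpha:g},{g.beta:g})" for g in self.gammas]
        if self.has_high_mass:
            out.append("C+")
        return out

    @property
    def zero_index(self) -> Optional[int]:
        return 0 if self.has_zero_mass else None

    @property
    def gamma_slice(self) -> slice:
        start = int(self.has_zero_mass)
        return slice(start, start + len(self.gammas))

    @property
    def high_index(self) -> Optional[int]:
        return self.n_components - 1 if self.has_high_mass else None

    def alphas(self) -> np.ndarray:
        return np.array([g.alpha for g in self.gammas])

    def betas(self) -> np.ndarray:
        return np.array([g.beta for g in self.gammas])

    def drop_lowest(self, n_drop: int) -> "ComponentSet":
        """The nested subset excluding the ``n_drop`` lowest-mean Gammas."""
        if n_drop >= len(self.gammas):
            raise ValueError("cannot drop every Gamma component")
        return ComponentSet(
            gammas=self.gammas[n_drop:],
            C=self.C,
            has_zero_mass=self.has_zero_mass,
            has_high_mass=self.has_high_mass,
        )


@dataclass(frozen=True)
class CandidateModel:
    """Nested candidate Phi_l: the full set minus a prefix of low-mean Gammas."""

    components: ComponentSet
    index: int
    n_dropped: int = 0


@dataclass
class AggregateCounts:
    """Observed frequencies y_x over x = 0..C plus the C+ overflow bin."""

    y: np.ndarray  # length C + 2: [y_0, ..., y_C, y_{C+}]
    I: int
    C: int

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.C + 2,):
            raise ValueError("aggregate vector must have length C + 2")
        if abs(self.y.sum() - self.I) > 1e-6 * max(self.I, 1):
            raise ValueError("aggregate frequencies must sum to the sample count")


@dataclass
class FittedMixture:
    """Bootstrap-averaged mixture fit for one OTU.

    ``w`` is the joint weight vector over the full component set,
    ``w = sum_l v(l) w_l`` with v(l) the bootstrap selection proportion of
    candidate l and w_l that candidate's weights refit on the original data
    (zeros for components a candidate excludes).
    """

    components: ComponentSet
    w: np.ndarray
    model_probs: np.ndarray
    per_model_w: np.ndarray  # (L, n_components)
    objective: float = float("nan")

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.model_probs = np.asarray(self.model_probs, dtype=float)
        self.per_model_w = np.asarray(self.per_model_w, dtype=float)
        if self.w.shape != (self.components.n_components,):
            raise ValueError("weight vector does not match the component set")
        if abs(self.w.sum() - 1.0) > 1e-8 or np.any(self.w < -1e-12):
            raise ValueError("weights must lie on the probability simplex")

    def to_dict(self) -> dict:
        return {
            "components": {
                "alphas": [g.alpha for g in self.components.gammas],
                "betas": [g.beta for g in self.components.gammas],
                "C": self.components.C,
                "has_zero_mass": self.components.has_zero_mass,
                "has_high_mass": self.components.has_high_mass,
            },
            "w": self.w.tolist(),
            "model_probs": self.model_probs.tolist(),
            "per_model_w": self.per_model_w.tolist(),
            "objective": self.objective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMixture":
        comp = d["components"]
        cs = ComponentSet(
            gammas=tuple(
                GammaComponent(a, b) for a, b in zip(comp["alphas"], comp["betas"])
            ),
            C=comp["C"],
            has_zero_mass=comp["has_zero_mass"],
            has_high_mass=comp["has_high_mass"],
        )
        return cls(
            components=cs,
            w=np.array(d["w"]),
            model_probs=np.array(d["model_probs"]),
            per_model_w=np.array(d["per_model_w"]),
            objective=d["objective"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedMixture":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# component specification


def specify_components(
    counts,
    resolutions: Optional[Resolutions] = None,
    quantile_p: float = 0.85,
    n_high: int = 12,
    extra_low: Sequence[GammaComponent] = (GammaComponent(1.0, 2.0),),
    c_min: int = 8,
) -> ComponentSet:
    """Data-driven full component set for one OTU.

    Low and integer counts get unit-rate posteriors Gamma(k, 1), k = 1..7,
    preceded by the sharper Gamma(1, 2); high counts get ``n_high`` shapes
    log-uniform on [8, C] with unit rate, where C is the ``quantile_p``
    quantile of the positive counts, floored at ``c_min``.  A zero point
    mass is included whenever the OTU has observed zeros; the C+ point mass
    absorbs counts above C.
    """
    counts = np.asarray(counts)
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("all-zero OTU: no mixture to fit")
    C = max(int(c_min), int(math.ceil(np.quantile(positive, quantile_p))))
    gammas = list(extra_low) + [GammaComponent(float(k), 1.0) for k in range(1, 8)]
    grid = np.unique(np.geomspace(8.0, float(C), n_high))
    gammas += [GammaComponent(float(a), 1.0) for a in grid]
    return ComponentSet(
        gammas=tuple(sorted(gammas, key=lambda g: g.mean)),
        C=C,
        has_zero_mass=bool(np.any(counts == 0)),
        has_high_mass=True,
    )


def build_nested_models(full: ComponentSet, n_models: int = 5) -> list[CandidateModel]:
    """Nested candidates: model 1 is the full set; model l drops the l-1
    lowest-mean Gammas among those with mean below 4.  Point masses are
    never dropped."""
    droppable = sum(1 for g in full.gammas if g.mean < _DROPPABLE_MEAN_LIMIT)
    if n_models < 1:
        raise ValueError("need at least one candidate model")
    if n_models > droppable + 1:
        raise ValueError(
            f"n_models={n_models} exceeds droppable low-rate prefix ({droppable}) + 1"
        )
    return [
        CandidateModel(components=full.drop_lowest(d), index=d + 1, n_dropped=d)
        for d in range(n_models)
    ]


# ---------------------------------------------------------------------------
# negative binomial probabilities


def nb_count_prob(x: int, component: GammaComponent, t: float) -> float:
    """P(X = x) for the Poisson-Gamma count at resolution t:
    NB with size alpha and success probability beta / (t + beta)."""
    if x < 0 or t <= 0:
        raise ValueError("need x >= 0 and t > 0")
    p = component.beta / (t + component.beta)
    return float(nbinom.pmf(x, component.alpha, p))


def nb_pmf_grid(
    alphas: np.ndarray, betas: np.ndarray, t: np.ndarray, C: int
) -> np.ndarray:
    """NB pmf table P(X = x | alpha_m, beta_m, t_i) of shape (M, C+1, I).

    Uses the stable pmf recurrence
    P(x+1) = P(x) * (x + alpha) / (x + 1) * (1 - p), p = beta/(t + beta).
    """
    alphas = np.asarray(alphas, dtype=float)[:, None]
    betas = np.asarray(betas, dtype=float)[:, None]
    t = np.asarray(t, dtype=float)[None, :]
    p = betas / (t + betas)
    out = np.empty((alphas.shape[0], C + 1, t.shape[1]))
    out[:, 0, :] = p ** alphas
    q = 1.0 - p
    for x in range(C):
        out[:, x + 1, :] = out[:, x, :] * ((x + alphas) / (x + 1.0)) * q
    return out


# ---------------------------------------------------------------------------
# aggregate counts and the least-squares design


def aggregate_counts(counts, C: int) -> AggregateCounts:
    """Observed frequency vector y over x = 0..C, C+ for one OTU."""
    counts = np.asarray(counts)
    capped = np.minimum(counts, C + 1)
    y = np.bincount(capped, minlength=C + 2).astype(float)
    return AggregateCounts(y=y, I=counts.size, C=C)


class OTUDesign:
    """Precomputed per-OTU quantities for weight fitting and bootstrap.

    Holds the NB probability tensor over (component, count category, sample)
    so that aggregate designs for arbitrary sample reweightings (bootstrap
    resamples) are single matrix-vector products.
    """

    def __init__(self, counts, resolutions: Resolutions, full: ComponentSet):
        counts = np.asarray(counts)
        self.counts = counts
        self.full = full
        self.I = counts.size
        self.C = full.C
        t = np.asarray(resolutions.t, dtype=float)
        if t.shape != counts.shape:
            raise ValueError("counts and resolutions are misaligned")
        self.pmf_tensor = nb_pmf_grid(full.alphas(), full.betas(), t, self.C)
        M = len(full.gammas)
        self._pmf2d = self.pmf_tensor.reshape(M * (self.C + 1), self.I)
        # indicator of count categories per sample, for resampled aggregates
        capped = np.minimum(counts, self.C + 1)
        self._cat = capped
        self.y = aggregate_counts(counts, self.C).y
        self._col_labels = full.labels

    def design(self, freq: Optional[np.ndarray] = None) -> np.ndarray:
        """Design matrix A with A[x, m] = I * p_xm for the full set.

        ``freq`` reweights samples (bootstrap multiplicities); None means
        the original data.  Rows are x = 0..C, C+; columns follow the
        component order (z, Gammas, C+).  The zero mass contributes only to
        x = 0 and the C+ column only to the overflow row; Gamma columns
        carry the residual tail mass in the overflow row.
        """
        full = self.full
        M = len(full.gammas)
        if freq is None:
            pxm = self._pmf2d.mean(axis=1).reshape(M, self.C + 1)
            I_eff = float(self.I)
        else:
            freq = np.asarray(freq, dtype=float)
            I_eff = float(freq.sum())
            pxm = (self._pmf2d @ freq).reshape(M, self.C + 1) / I_eff
        A = np.zeros((self.C + 2, full.n_components))
        gs = full.gamma_slice
        A[: self.C + 1, gs] = pxm.T
        A[self.C + 1, gs] = np.clip(1.0 - pxm.sum(axis=1), 0.0, None)
        if full.has_zero_mass:
            A[0, full.zero_index] = 1.0
        if full.has_high_mass:
            A[self.C + 1, full.high_index] = 1.0
        return A * I_eff

    def aggregate(self, freq: Optional[np.ndarray] = None) -> np.ndarray:
        if freq is None:
            return self.y
        freq = np.asarray(freq, dtype=float)
        return np.bincount(self._cat, weights=freq, minlength=self.C + 2)

    def candidate_columns(self, cand: CandidateModel) -> np.ndarray:
        """Column indices of a nested candidate within the full design."""
        full = self.full
        cols = []
        if full.has_zero_mass:
            cols.append(full.zero_index)
        start = full.gamma_slice.start
        cols.extend(range(start + cand.n_dropped, start + len(full.gammas)))
        if full.has_high_mass:
            cols.append(full.high_index)
        return np.asarray(cols)


def expected_aggregate(
    model: CandidateModel,
    w: np.ndarray,
    resolutions: Resolutions,
    counts=None,
    I: Optional[int] = None,
) -> np.ndarray:
    """Expected aggregate frequencies y^E over x = 0..C, C+ under weights w.

    ``I`` (or the length of ``counts``) sets the sample count; resolutions
    supply the t_i at which the NB probabilities are averaged.
    """
    w = np.asarray(w, dtype=float)
    comp = model.components
    if w.shape != (comp.n_components,):
        raise ValueError("weight vector does not match the candidate's components")
    t = np.asarray(resolutions.t, dtype=float)
    n = t.size if I is None else I
    pmf = nb_pmf_grid(comp.alphas(), comp.betas(), t, comp.C)
    pxm = pmf.mean(axis=2)  # (M, C+1)
    A = np.zeros((comp.C + 2, comp.n_components))
    gs = comp.gamma_slice
    A[: comp.C + 1, gs] = pxm.T
    A[comp.C + 1, gs] = np.clip(1.0 - pxm.sum(axis=1), 0.0, None)
    if comp.has_zero_mass:
        A[0, comp.zero_index] = 1.0
    if comp.has_high_mass:
        A[comp.C + 1, comp.high_index] = 1.0
    return n * (A @ w)


def fit_weights(
    model: CandidateModel,
    agg: AggregateCounts,
    resolutions: Resolutions,
):
    """Constrained least squares for one candidate model.

    Minimizes sum_x [y_x - y^E_x(w)]^2 over the probability simplex and
    returns ``(w, objective)``.
    """
    comp = model.components
    if agg.C != comp.C:
        raise ValueError("aggregate and component set disagree on C")
    t = np.asarray(resolutions.t, dtype=float)
    pmf = nb_pmf_grid(comp.alphas(), comp.betas(), t, comp.C)
    pxm = pmf.mean(axis=2)
    A = np.zeros((comp.C + 2, comp.n_components))
    gs = comp.gamma_slice
    A[: comp.C + 1, gs] = pxm.T
    A[comp.C + 1, gs] = np.clip(1.0 - pxm.sum(axis=1), 0.0, None)
    if comp.has_zero_mass:
        A[0, comp.zero_index] = 1.0
    if comp.has_high_mass:
        A[comp.C + 1, comp.high_index] = 1.0
    A = A * agg.I
    return fit_simplex_weights(A, agg.y)


# ---------------------------------------------------------------------------
# bootstrap model averaging


def bootstrap_model_average(
    counts,
    resolutions: Resolutions,
    candidates: list[CandidateModel],
    B: int = 100,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    select_against: str = "original",
) -> FittedMixture:
    """Average nested candidates by bootstrap selection frequency.

    For each of ``B`` bootstrap resamples (samples drawn with replacement,
    counts and resolutions jointly), every candidate is refit on the
    resample and the candidate whose refit weights minimize the
    least-squares objective against the *original* aggregate is recorded as
    selected.  ``v(l)`` is the selection proportion; per-candidate weights
    ``w_l`` are refit on the original data and combined as
    ``w = sum_l v(l) w_l``.

    ``select_against='resample'`` instead scores candidates on the
    resampled aggregate (a variant some bootstrap model-selection schemes
    use).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if select_against not in ("original", "resample"):
        raise ValueError("select_against must be 'original' or 'resample'")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    full = candidates[0].components
    for cand in candidates:
        if cand.components.C != full.C:
            raise ValueError("candidates must share the truncation point C")
    if candidates[0].n_dropped != 0:
        raise ValueError("the first candidate must be the full model")

    design = OTUDesign(counts, resolutions, full)
    A0 = design.design()
    y0 = design.y
    L = len(candidates)
    col_idx = [design.candidate_columns(c) for c in candidates]

    # per-candidate weights on the original data
    per_model_w = np.zeros((L, full.n_components))
    original_obj = np.empty(L)
    for l, cand in enumerate(candidates):
        A_l = A0[:, col_idx[l]]
        w_l, obj_l = fit_simplex_weights(A_l, y0)
        per_model_w[l, col_idx[l]] = w_l
        original_obj[l] = obj_l

    if L == 1:
        v = np.array([1.0])
        w = per_model_w[0]
        return FittedMixture(full, w, v, per_model_w, objective=original_obj[0])

    selected = np.zeros(L)
    nonzero = (counts > 0).astype(float)
    I = counts.size
    b = 0
    redraws = 0
    while b < B:
        idx = rng.integers(0, I, size=I)
        freq = np.bincount(idx, minlength=I).astype(float)
        if freq @ nonzero == 0:
            redraws += 1
            if redraws > 1000:
                raise RuntimeError("bootstrap cannot draw a non-degenerate resample")
            logger.debug("degenerate all-zero bootstrap resample redrawn")
            continue
        A_b = design.design(freq)
        y_b = design.aggregate(freq)
        best_l, best_obj = 0, np.inf
        for l in range(L):
            cols = col_idx[l]
            A_bl = A_b[:, cols]
            w_bl, _ = fit_simplex_weights(A_bl, y_b)
            if select_against == "original":
                resid = A0[:, cols] @ w_bl - y0
            else:
                resid = A_bl @ w_bl - y_b
            obj = float(resid @ resid)
            if obj < best_obj:
                best_obj, best_l = obj, l
        selected[best_l] += 1
        b += 1

    v = selected / selected.sum()
    w = v @ per_model_w
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    resid = A0 @ w - y0
    return FittedMixture(full, w, v, per_model_w, objective=float(resid @ resid))


def fit_mixture(
    counts,
    resolutions: Resolutions,
    B: int = 100,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    n_models: int = 5,
    **component_config,
) -> FittedMixture:
    """Specify components, build nested candidates, and bootstrap-average."""
    full = specify_components(counts, resolutions, **component_config)
    candidates = build_nested_models(full, n_models=n_models)
    return bootstrap_model_average(
        counts, resolutions, candidates, B=B, seed=seed, rng=rng
    )
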