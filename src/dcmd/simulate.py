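"""Synthetic OTU datasets with class-structured mixture rates.

Each OTU gets a latent rate mixture with M components (M ~ Unif{5..15}).
A sample's component is chosen by drawing from Beta(alpha_b, beta_b) and
binning [0, 1] into M uniform intervals; the class-specific alpha_b shifts
mass across bins (higher alpha_b -> higher-rate components -> denser
counts), while beta_b ~ Unif(2, 6.5) controls dispersion and is shared by
the classes of an OTU, so classes differ only through alpha_b.  Bins below
a small midpoint threshold are structural zeros (absent taxon); above it,
bin mean rates run log-uniformly up to ``lambda_max``.  The realized
sample rate is Gamma-distributed around the bin mean with shape ``kappa``,
and the observed count is Poisson(rate * t_i) with per-sample resolution
t_i ~ Unif(2/3, 5/4).

The rate-ladder parameters are calibrated once (see
:func:`calibrate_rate_map`) so that the per-class zero proportions and mean
counts of the benchmark scenarios match their target summary statistics;
the calibrated values are frozen in :data:`DEFAULT_RATE_MAP`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .otu_table import OTUTable

#: nominal sequencing depth of a resolution-1 sample, used to encode the
#: drawn resolutions as integer per-sample totals in the output table
DEPTH_SCALE = 100_000


@dataclass(frozen=True)
class RateMap:
    """Monotone bin -> rate-distribution mapping.

    Bins with midpoint u = (m + 1/2) / M below ``zero_below`` are
    structural-zero components (the taxon is absent, rate exactly 0 —
    mirroring the zero point mass of the analysis model).  Above the
    threshold, mean rates run log-uniformly from ``lambda_lo`` to
    ``lambda_max``; the realized sample rate is Gamma(kappa, kappa / mean)
    around that mean (mean preserved; smaller ``kappa`` gives
    heavier-tailed rates and more sampling zeros at a given mean).
    """

    zero_below: float = 0.106
    lambda_lo: float = 0.672
    lambda_max: float = 399.4
    kappa: float = 4.0

    def mean_rate(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        s = np.clip((u - self.zero_below) / (1.0 - self.zero_below), 0.0, 1.0)
        lam = self.lambda_lo * (self.lambda_max / self.lambda_lo) ** s
        return np.where(u < self.zero_below, 0.0, lam)

    def draw_rates(self, bins: np.ndarray, M: int, rng: np.random.Generator):
        lam = self.mean_rate((np.asarray(bins) + 0.5) / M)
        out = np.zeros_like(lam, dtype=float)
        pos = lam > 0
        if np.any(pos):
            out[pos] = rng.gamma(shape=self.kappa, scale=lam[pos] / self.kappa)
        return out


DEFAULT_RATE_MAP = RateMap()


@dataclass
class ScenarioConfig:
    """Generator parameters for one simulated dataset."""

    alpha_b_ranges: Sequence[tuple[float, float]]
    class_sizes: Sequence[int] = (400, 400)
    J: int = 25
    beta_b_range: tuple[float, float] = (2.0, 6.5)
    M_range: tuple[int, int] = (5, 15)
    t_range: tuple[float, float] = (2.0 / 3.0, 5.0 / 4.0)
    rate_map: RateMap = field(default_factory=lambda: DEFAULT_RATE_MAP)
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.alpha_b_ranges) != len(self.class_sizes):
            raise ValueError("one alpha_b range per class is required")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        d["rate_map"] = RateMap(**d["rate_map"])
        d["alpha_b_ranges"] = [tuple(r) for r in d["alpha_b_ranges"]]
        for key in ("class_sizes", "beta_b_range", "M_range", "t_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


#: class-specific alpha_b ranges of the two-class benchmark scenarios
TWO_CLASS_ALPHA_RANGES = {
    1: [(1.5, 1.8), (1.8, 2.1)],  # weak signal, low sparsity
    2: [(1.5, 1.8), (2.7, 3.0)],  # strong signal, low sparsity
    3: [(0.2, 0.4), (0.4, 0.6)],  # weak signal, high sparsity
    4: [(0.2, 0.4), (0.8, 1.0)],  # strong signal, high sparsity
}

#: three-class scenarios: strongly differentiated classes at decreasing
#: density (scenario 1 low sparsity ... scenario 3 high sparsity)
THREE_CLASS_ALPHA_RANGES = {
    1: [(1.5, 1.8), (2.1, 2.4), (2.7, 3.0)],
    2: [(0.8, 1.0), (1.4, 1.6), (2.0, 2.2)],
    3: [(0.2, 0.4), (0.8, 1.0), (1.4, 1.6)],
}

#: target per-class summary statistics (mean zero proportion, mean count)
#: of the two-class scenarios, used by the rate-map calibration
TWO_CLASS_SUMMARY_TARGETS = {
    (1, 0): (0.32, 7.91),
    (1, 1): (0.26, 9.63),
    (2, 0): (0.33, 7.74),
    (2, 1): (0.14, 15.12),
    (3, 0): (0.84, 1.05),
    (3, 1): (0.74, 1.92),
    (4, 0): (0.84, 0.98),
    (4, 1): (0.56, 3.61),
}


def two_class_scenario(scenario: int, **overrides) -> ScenarioConfig:
    if scenario not in TWO_CLASS_ALPHA_RANGES:
        raise ValueError(f"two-class scenario must be 1-4, got {scenario}")
    overrides.setdefault("class_sizes", (400, 400))
    return ScenarioConfig(
        alpha_b_ranges=TWO_CLASS_ALPHA_RANGES[scenario], **overrides
    )


def three_class_scenario(scenario: int, **overrides) -> ScenarioConfig:
    if scenario not in THREE_CLASS_ALPHA_RANGES:
        raise ValueError(f"three-class scenario must be 1-3, got {scenario}")
    overrides.setdefault("class_sizes", (400, 400, 400))
    return ScenarioConfig(
        alpha_b_ranges=THREE_CLASS_ALPHA_RANGES[scenario], **overrides
    )


@dataclass
class SimulatedDataset:
    """Generated table plus the generating truth per OTU and sample."""

    table: OTUTable
    truth: dict

    def class_summary(self) -> dict:
        """Per-class (mean over OTUs of zero proportion, grand mean count)."""
        out = {}
        for cl in np.unique(self.table.labels):
            block = self.table.counts[self.table.labels == cl]
            out[str(cl)] = {
                "mean_zero_proportion": float((block == 0).mean(axis=0).mean()),
                "mean_count": float(block.mean()),
            }
        return out


def simulate_otu_class(
    n: int,
    alpha_b: float,
    beta_b: float,
    M: int,
    rate_map: RateMap,
    t: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts for one OTU in one class.

    Draw Beta(alpha_b, beta_b) per sample, bin into M uniform intervals to
    pick a rate component, draw the rate from the component's Gamma, and
    observe Poisson(rate * t_i).
    """
    if n < 1 or alpha_b <= 0 or beta_b <= 0:
        raise ValueError("need n >= 1 and positive Beta parameters")
    u = rng.beta(alpha_b, beta_b, size=n)
    bins = np.minimum((u * M).astype(int), M - 1)
    rates = rate_map.draw_rates(bins, M, rng)
    return rng.poisson(rates * np.asarray(t, dtype=float))


def simulate_dataset(config: ScenarioConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """One replicate dataset under a scenario configuration.

    Per OTU, the component count M and dispersion beta_b are drawn once and
    shared across classes; each class draws its alpha_b from its own range.
    Resolutions are drawn once per sample and shared across OTUs; the
    table's per-sample totals encode the drawn resolution at a nominal
    depth so that recomputed resolutions agree with the generative ones up
    to a common factor.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    sizes = list(config.class_sizes)
    I = sum(sizes)
    J = config.J
    labels = np.concatenate(
        [np.full(s, f"class{k + 1}") for k, s in enumerate(sizes)]
    )
    t = rng.uniform(config.t_range[0], config.t_range[1], size=I)
    counts = np.zeros((I, J), dtype=np.int64)
    class_slices = []
    start = 0
    for s in sizes:
        class_slices.append(slice(start, start + s))
        start += s
    truth_otus = []
    for j in range(J):
        M = int(rng.integers(config.M_range[0], config.M_range[1] + 1))
        beta_b = rng.uniform(*config.beta_b_range)
        alphas = [rng.uniform(*r) for r in config.alpha_b_ranges]
        for k, sl in enumerate(class_slices):
            counts[sl, j] = simulate_otu_class(
                sizes[k], alphas[k], beta_b, M, config.rate_map, t[sl], rng
            )
        truth_otus.append({"M": M, "beta_b": beta_b, "alpha_b": alphas})
    totals = np.round(DEPTH_SCALE * t).astype(np.int64)
    table = OTUTable(
        counts=counts,
        sample_ids=[f"S{i + 1}" for i in range(I)],
        otu_ids=[f"OTU{j + 1}" for j in range(J)],
        totals=totals,
        labels=labels,
    )
    truth = {
        "seed": seed,
        "t": t.tolist(),
        "otus": truth_otus,
        "rate_map": asdict(config.rate_map),
    }
    return SimulatedDataset(table=table, truth=truth)


def permute_null(dataset: SimulatedDataset, rng: np.random.Generator) -> SimulatedDataset:
    """Uniformly permute class labels; counts untouched."""
    table = dataset.table
    if table.labels is None:
        raise ValueError("null permutation needs a labelled dataset")
    perm = rng.permutation(table.n_samples)
    new_table = OTUTable(
        counts=table.counts,
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        totals=table.totals,
        labels=table.labels[perm],
    )
    return SimulatedDataset(table=new_table, truth=dict(dataset.truth, permuted=True))


# ---------------------------------------------------------------------------
# rate-map calibration


def scenario_summary(
    rate_map: RateMap,
    replicates: int = 20,
    seed: int = 0,
    scenarios: Sequence[int] = (1, 2, 3, 4),
) -> dict:
    """Mean zero proportion and mean count per (scenario, class) over replicates."""
    acc: dict[tuple[int, int], list[tuple[float, float]]] = {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(replicates * len(scenarios)) % (2**31)
    i = 0
    for sc in scenarios:
        cfg = two_class_scenario(sc, rate_map=rate_map)
        for _ in range(replicates):
            ds = simulate_dataset(cfg, seed=int(seeds[i]))
            i += 1
            for k, cl in enumerate(np.unique(ds.table.labels)):
                block = ds.table.counts[ds.table.labels == cl]
                zp = float((block == 0).mean(axis=0).mean())
                mc = float(block.mean())
                acc.setdefault((sc, k), []).append((zp, mc))
    return {
        key: (
            float(np.mean([v[0] for v in vals])),
            float(np.mean([v[1] for v in vals])),
        )
        for key, vals in acc.items()
    }


def calibrate_rate_map(
    targets: dict = None,
    replicates: int = 4,
    seed: int = 0,
    x0: RateMap = None,
    maxiter: int = 80,
) -> RateMap:
    """Fit the rate map so scenario summaries match their targets.

    Minimizes summed squared errors in zero proportion plus squared
    relative errors in mean count across all scenario/class cells of the
    two-class benchmark, by Nelder-Mead over (zero_below, log lambda_lo,
    log lambda_max) with the within-component dispersion ``kappa`` held at
    its default.  Deterministic given ``seed`` (common random numbers
    across evaluations).
    """
    if targets is None:
        targets = TWO_CLASS_SUMMARY_TARGETS
    if x0 is None:
        x0 = DEFAULT_RATE_MAP
    start = np.array(
        [x0.zero_below, np.log(x0.lambda_lo), np.log(x0.lambda_max)]
    )

    def loss(params):
        rm = RateMap(
            zero_below=float(np.clip(params[0], 0.0, 0.5)),
            lambda_lo=float(np.exp(params[1])),
            lambda_max=float(np.exp(params[2])),
            kappa=x0.kappa,
        )
        got = scenario_summary(rm, replicates=replicates, seed=seed)
        err = 0.0
        for key, (zp_t, mc_t) in targets.items():
            zp, mc = got[key]
            err += (zp - zp_t) ** 2 + ((mc - mc_t) / mc_t) ** 2
        return err

    res = minimize(loss, start, method="Nelder-Mead",
                   options={"xatol": 5e-3, "fatol": 1e-4, "maxiter": maxiter})
    return RateMap(
        zero_below=float(np.clip(res.x[0], 0.0, 0.5)),
        lambda_lo=float(np.exp(res.x[1])),
        lambda_max=float(np.exp(res.x[2])),
        kappa=x0.kappa,
    )
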