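"""Spike-in two-class microarray simulator with controlled contamination.

The generator composes four additive terms per gene i and sample j,

    d_ij = z_ij + s_ij + n_ij + t_ij

where

* ``z_ij`` are replicate base levels: a per-gene base ``zbar_i = lb + ub*z_i``
  with ``z_i`` drawn from a beta(2, 4) or normal(10, 1.5) distribution, then
  ``z_ij ~ unif((1-a_i) zbar_i, (1+a_i) zbar_i)`` with
  ``a_i = lambda1 * exp(-lambda1 * zbar_i)`` so that weakly expressed genes
  get proportionally more replicate noise (low signal-to-noise at low
  expression);
* ``s_ij`` spikes in the differential expression: zero everywhere except
  the treatment columns of the truly DE genes, where
  ``s_ij ~ N(+-mu_de, sigma_de^2)`` with a per-gene effect size
  ``mu_de = mu_de_min + Exp(rate=lambda2)``;
* ``n_ij ~ N(0, sigma_n^2)`` is additive measurement noise on every cell;
* ``t_ij ~ N(0, sigma_deo^2)`` is the technical-outlier contamination,
  present only in high-noise scenarios, only for DE genes, and only in the
  LAST ``n_deo = floor(0.2 * n2)`` treatment columns.

Four scenarios: beta_low / beta_high / normal_low / normal_high, where
"high" adds the contamination term.  Each of the four steps consumes its
own RNG substream spawned from the seed, so a high-noise dataset equals the
matching low-noise dataset plus the t-term, cell for cell.

Columns 0..n1-1 are control, n1..n1+n2-1 treatment.  The first
``round(prop_down * n)`` genes are down-regulated and the last
``round(prop_up * n)`` up-regulated (in the treatment group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import TruthLabels, TwoGroupExpression

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "generate_base_levels",
    "generate_replicates",
    "apply_de_shifts",
    "apply_noise_and_outliers",
    "generate_dataset",
]

SCENARIOS = ("beta_low", "beta_high", "normal_low", "normal_high")


@dataclass(frozen=True)
class ScenarioConfig:
    """All generator parameters for one simulation scenario.

    Defaults are the study conditions: 10,000 genes, 2% DE (1% up + 1%
    down), beta(2,4) or normal(10,1.5) base levels with transform constants
    (lb, ub) = (4, 14) or (0, 1), lambda1=0.13, lambda2=2 (rate; mean
    effect 0.5 above mu_de_min=0.5), sigma_de=0.5, sigma_n=0.4 and, in the
    contaminated scenarios, sigma_deo=1 with floor(0.2*n2) outlying
    treatment columns.
    """

    scenario: str = "beta_low"
    n_genes: int = 10_000
    n1: int = 10
    n2: int = 10
    prop_up: float = 0.01
    prop_down: float = 0.01
    shape1: float = 2.0
    shape2: float = 4.0
    norm_mean: float = 10.0
    norm_sd: float = 1.5
    lb: float | None = None
    ub: float | None = None
    lambda1: float = 0.13
    lambda2: float = 2.0
    mu_de_min: float = 0.5
    sigma_de: float = 0.5
    sigma_n: float = 0.4
    sigma_deo: float | None = None
    mu_de_per_sample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.prop_up + self.prop_down >= 1:
            raise ValueError("DE fractions must sum to less than 1")
        defaults = {
            "lb": 4.0 if self.is_beta else 0.0,
            "ub": 14.0 if self.is_beta else 1.0,
            "sigma_deo": 1.0 if self.contaminated else 0.0,
        }
        for name, value in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
        if min(self.sigma_de, self.sigma_n, self.sigma_deo) < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.n_deo >= self.n2:
            raise ValueError("outlying samples must be fewer than n2")

    @property
    def is_beta(self) -> bool:
        return self.scenario.startswith("beta")

    @property
    def contaminated(self) -> bool:
        return self.scenario.endswith("high")

    @property
    def n_deo(self) -> int:
        """Number of outlying treatment columns, floor(0.2 * n2)."""
        return math.floor(0.2 * self.n2) if self.contaminated else 0

    @property
    def n_up(self) -> int:
        return round(self.prop_up * self.n_genes)

    @property
    def n_down(self) -> int:
        return round(self.prop_down * self.n_genes)

    def truth(self) -> TruthLabels:
        """Ground-truth labels implied by the configuration."""
        n_cols = self.n1 + self.n2
        return TruthLabels(
            up_genes=np.arange(self.n_genes - self.n_up, self.n_genes),
            down_genes=np.arange(self.n_down),
            outlier_columns=np.arange(n_cols - self.n_deo, n_cols),
        )


def generate_base_levels(
    config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene base expression zbar_i = lb + ub * z_i.

    ``z_i`` is beta(shape1, shape2) or normal(norm_mean, norm_sd); in the
    normal scenarios (lb, ub) = (0, 1), i.e. no transformation.
    """
    if config.is_beta:
        z = rng.beta(config.shape1, config.shape2, size=config.n_genes)
    else:
        z = rng.normal(config.norm_mean, config.norm_sd, size=config.n_genes)
    return config.lb + config.ub * z


def generate_replicates(
    zbar: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replicate levels z_ij ~ unif((1-a_i) zbar_i, (1+a_i) zbar_i).

    The relative half-width ``a_i = lambda1 * exp(-lambda1 * zbar_i)``
    shrinks as the base level grows.
    """
    zbar = np.asarray(zbar, dtype=float)
    alpha = config.lambda1 * np.exp(-config.lambda1 * zbar)
    half = (alpha * zbar)[:, None]
    n_cols = config.n1 + config.n2
    u = rng.uniform(-1.0, 1.0, size=(zbar.size, n_cols))
    return zbar[:, None] + half * u


def apply_de_shifts(
    matrix: np.ndarray,
    truth: TruthLabels,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add the spike-in term s_ij to the treatment columns of DE genes.

    One effect size ``mu_de = mu_de_min + Exp(rate=lambda2)`` is drawn per
    gene (per-sample draws available via ``mu_de_per_sample``); the
    per-sample shift is N(mu_de, sigma_de^2) with sign + for up-regulated
    and - for down-regulated genes.  Control columns and non-DE genes are
    untouched.
    """
    out = np.array(matrix, dtype=float, copy=True)
    for genes, sign in ((truth.up_genes, 1.0), (truth.down_genes, -1.0)):
        if genes.size == 0:
            continue
        if config.mu_de_per_sample:
            mu = config.mu_de_min + rng.exponential(
                1.0 / config.lambda2, size=(genes.size, config.n2)
            )
        else:
            mu = config.mu_de_min + rng.exponential(
                1.0 / config.lambda2, size=genes.size
            )
            mu = mu[:, None]
        shift = rng.normal(mu, config.sigma_de, size=(genes.size, config.n2))
        out[np.ix_(genes, range(config.n1, config.n1 + config.n2))] += sign * shift
    return out


def apply_noise_and_outliers(
    matrix: np.ndarray,
    truth: TruthLabels,
    config: ScenarioConfig,
    noise_rng: np.random.Generator,
    outlier_rng: np.random.Generator,
) -> np.ndarray:
    """Add measurement noise everywhere, plus contamination where due.

    ``n_ij ~ N(0, sigma_n^2)`` on every cell.  In contaminated scenarios
    the DE genes additionally receive ``t_ij ~ N(0, sigma_deo^2)`` in the
    last ``n_deo`` (treatment) columns.  The outlier term uses its own RNG
    stream so that zeroing ``sigma_deo`` reproduces the uncontaminated
    matrix bit for bit.
    """
    out = np.array(matrix, dtype=float, copy=True)
    out += noise_rng.normal(0.0, config.sigma_n, size=out.shape)
    de = truth.true_genes
    if config.n_deo > 0 and de.size:
        t = outlier_rng.normal(
            0.0, config.sigma_deo, size=(de.size, config.n_deo)
        )
        out[np.ix_(de, truth.outlier_columns)] += t
    return out


def generate_dataset(
    config: ScenarioConfig,
) -> tuple[TwoGroupExpression, TruthLabels]:
    """Compose the four generation steps into a labelled dataset.

    Deterministic under ``config.seed``; each step draws from its own
    spawned substream, so configurations differing only in the
    contamination term share the underlying data exactly.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    base_rng, repl_rng, de_rng, noise_rng, outlier_rng = map(
        np.random.default_rng, streams
    )

    truth = config.truth()
    zbar = generate_base_levels(config, base_rng)
    z = generate_replicates(zbar, config, repl_rng)
    z = apply_de_shifts(z, truth, config, de_rng)
    d = apply_noise_and_outliers(z, truth, config, noise_rng, outlier_rng)

    width = len(str(config.n_genes))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(config.n_genes)])
    group = np.array(["control"] * config.n1 + ["treatment"] * config.n2)
    return TwoGroupExpression(values=d, gene_ids=gene_ids, group=group), truth
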