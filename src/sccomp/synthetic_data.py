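"""Synthetic spectral-count datasets with known ground truth.

The generator emulates the statistical structure the comparability method
assumes so every stage of the toolkit can be exercised without real
deposited data:

* per-replicate sequencing-depth variation — a multiplicative
  ``depth_factor`` on every expected count (the nuisance the internal
  standards are designed to cancel);
* constitutively expressed internal standards — fold 1 between samples
  and a smaller biological noise than the bulk proteome;
* lognormal biological variability between replicates, on top of Poisson
  counting noise;
* a single reporter protein (a GFP stand-in, id ``"gfp"``) with a known
  true fold change between the two samples.

Counts are Poisson draws around lognormal-perturbed means.  This is the
simplest generative model reproducing overdispersion plus depth effects;
it starts at protein-level counts (no spectra, peptides or retention
times are simulated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tabular_io import DEFAULT_INTERNAL_STANDARDS, CountMatrix

REPORTER_ID = "gfp"


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    Defaults mirror a small bacterial whole-cell experiment: ~300 proteins
    per run at a mean count of ~8 spectra, nine abundant internal
    standards (~60 spectra each), an induced reporter at ~50 spectra in
    the low-expression sample, triplicates, and lognormal biological
    noise of sigma 0.2 (bulk) / 0.1 (standards) — spreads that place the
    between-replicate SRA standard deviations in the few-tenths-fold
    range typical of biological replicates.
    """

    n_proteins: int = 300
    n_standards: int = 9
    n_replicates_per_sample: int = 3
    reporter_fold: float = 3.0
    depth_factors: Sequence[float] | None = None  # len = 2 * n_replicates
    biological_cv: float = 0.2     # lognormal sigma, bulk proteins + reporter
    standard_cv: float = 0.1       # lognormal sigma, internal standards
    protein_mean_count: float = 8.0
    standard_mean_count: float = 60.0
    reporter_base_count: float = 50.0
    abundance_log_sigma: float = 1.0  # spread of base abundances across proteins
    sample_names: tuple[str, str] = ("high", "low")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_standards > self.n_proteins - 1:
            raise ValueError("n_standards must leave room for bulk proteins")
        if self.reporter_fold <= 0:
            raise ValueError("reporter_fold must be positive")
        if self.depth_factors is not None:
            self.depth_factors = tuple(float(d) for d in self.depth_factors)
            if len(self.depth_factors) != 2 * self.n_replicates_per_sample:
                raise ValueError(
                    "depth_factors must have one entry per replicate "
                    f"(expected {2 * self.n_replicates_per_sample})")
            if any(d <= 0 for d in self.depth_factors):
                raise ValueError("depth factors must be positive")
        if self.biological_cv < 0 or self.standard_cv < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one generated dataset."""

    reporter_id: str
    reporter_fold: float
    standard_ids: list[str]
    depth_factors: dict[str, float]        # "sample:replicate" -> factor
    base_abundances: dict[str, float]      # expected counts, low sample, depth 1


@dataclass
class SyntheticDataset:
    matrix: CountMatrix
    truth: SyntheticTruth
    config: SimulationConfig


def _standard_ids(n: int) -> list[str]:
    if n <= len(DEFAULT_INTERNAL_STANDARDS):
        return list(DEFAULT_INTERNAL_STANDARDS[:n])
    extra = [f"IN{j:02d}" for j in range(len(DEFAULT_INTERNAL_STANDARDS), n)]
    return list(DEFAULT_INTERNAL_STANDARDS) + extra


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one two-sample dataset; bit-identical for a given config."""
    rng = np.random.default_rng(config.seed)
    n_bulk = config.n_proteins - config.n_standards - 1
    standard_ids = _standard_ids(config.n_standards)
    bulk_ids = [f"P{i:04d}" for i in range(n_bulk)]
    protein_ids = [REPORTER_ID] + standard_ids + bulk_ids

    # base abundances: expected counts in the low sample at depth 1
    mu = np.log(config.protein_mean_count) - config.abundance_log_sigma**2 / 2
    bulk_base = np.exp(rng.normal(mu, config.abundance_log_sigma, size=n_bulk))
    std_base = config.standard_mean_count * np.exp(
        rng.uniform(-0.3, 0.3, size=config.n_standards))
    base = np.concatenate(([config.reporter_base_count], std_base, bulk_base))

    # noise sigma per protein: reporter and bulk use biological_cv
    sigma = np.full(config.n_proteins, config.biological_cv)
    sigma[1:1 + config.n_standards] = config.standard_cv

    n_rep = config.n_replicates_per_sample
    depths = (config.depth_factors if config.depth_factors is not None
              else (1.0,) * (2 * n_rep))
    rep_names = [chr(ord("A") + i) for i in range(n_rep)]
    labels = [(s, r) for s in config.sample_names for r in rep_names]

    # sample-level fold: only the reporter changes between samples
    fold = np.ones(config.n_proteins)
    counts = np.zeros((config.n_proteins, 2 * n_rep), dtype=np.int64)
    for col, ((sample, _), depth) in enumerate(zip(labels, depths)):
        fold_col = fold.copy()
        if sample == config.sample_names[0]:
            fold_col[0] = config.reporter_fold
        noise = np.exp(rng.normal(0.0, sigma))
        lam = base * fold_col * noise * depth
        counts[:, col] = rng.poisson(lam)

    lengths = rng.integers(100, 1001, size=config.n_proteins)
    matrix = CountMatrix(protein_ids, labels, counts, lengths)
    truth = SyntheticTruth(
        reporter_id=REPORTER_ID,
        reporter_fold=config.reporter_fold,
        standard_ids=standard_ids,
        depth_factors={f"{s}:{r}": d for (s, r), d in zip(labels, depths)},
        base_abundances=dict(zip(protein_ids, base)),
    )
    return SyntheticDataset(matrix=matrix, truth=truth, config=config)


#: Depth factors echoing a real two-growth-phase experiment: one sample
#: with fairly even run depths, the other with a run nearly 1.7x deeper
#: than its shallowest mate, so pairwise R_TS spans ~1.0-1.7.
BENCHMARK_DEPTHS = (1.00, 1.18, 1.70, 1.32, 1.04, 1.72)


def simulate_benchmark_like(seed: int = 2015) -> SyntheticDataset:
    """A fixed-seed dataset shaped like a small bacterial experiment.

    Two samples x triplicates, ~300 proteins, per-replicate totals in the
    2400–4600 range and pairwise R_TS spanning roughly 1.0–1.7.
    """
    config = SimulationConfig(
        n_proteins=300,
        depth_factors=BENCHMARK_DEPTHS,
        protein_mean_count=6.8,
        seed=seed,
    )
    return simulate(config)
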