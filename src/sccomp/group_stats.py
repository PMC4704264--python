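"""Pooling of per-pair fold estimates and comparison to external truth.

Per-pair adjusted SRA estimates are pooled only over pairs that passed the
comparability screen; failing pairs are recorded with the reason rather
than silently dropped.  All averaging happens on the SRA scale (where
opposite fold changes cancel), and the pooled value is rendered back as a
fold magnitude at the end.  Agreement with an external measurement (e.g.
fluorescence) is tested with Welch's unequal-variance two-tailed t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .comparability import ComparabilityReport, assess_pair
from .sra_core import (AdjustedSRAResult, adjusted_sra, profile_from_matrix,
                       sra_between_datasets)
from .tabular_io import CountMatrix, RunConfig


@dataclass
class TTestResult:
    """Welch's t-test: statistic, Welch–Satterthwaite df, two-tailed p."""

    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def to_record(self) -> dict:
        return {
            "t_stat": self.t_stat, "df": self.df, "p_value": self.p_value,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "n_a": self.n_a, "n_b": self.n_b,
        }


def welch_t_test(xs: Sequence[float], ys: Sequence[float]) -> TTestResult:
    """Two-sample, two-tailed t-test with unequal variances (heteroscedastic)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("non-finite values in input")
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return TTestResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(xs.mean()), mean_b=float(ys.mean()),
        sd_a=float(xs.std(ddof=1)), sd_b=float(ys.std(ddof=1)),
        n_a=len(xs), n_b=len(ys),
    )


def welch_t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TTestResult:
    """Welch's test from group summaries (mean, SD, n) instead of raw values.

    Useful when the external measurement is only reported as mean ± SD.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t_stat=t, df=df, p_value=p,
                       mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
                       n_a=n_a, n_b=n_b)


@dataclass
class PooledEstimate:
    """Fold estimate pooled over the replicate pairs that passed screening."""

    values: list[float]                 # signed folds of included pairs
    pooled_mean: float                  # signed fold of the pooled SRA mean
    pooled_sd: float                    # SD of per-pair SRA values
    pooled_sra_mean: float
    included_pairs: list[tuple[str, str]]
    excluded_pairs: list[tuple[tuple[str, str], str]]  # (pair, reason)
    empty: bool = False

    def to_record(self) -> dict:
        return {
            "pooled_fold": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
            "pooled_sra_mean": self.pooled_sra_mean,
            "n_included": len(self.included_pairs),
            "n_excluded": len(self.excluded_pairs),
            "empty": self.empty,
        }


def _signed_fold(sra_value: float) -> float:
    if sra_value == 0:
        return 1.0
    return math.copysign(abs(sra_value) + 1.0, sra_value)


def pool_fold_estimates(
    results: Sequence[tuple[AdjustedSRAResult, ComparabilityReport | None]],
) -> PooledEstimate:
    """Pool per-pair adjusted-SRA estimates over comparable pairs.

    Each item pairs an adjusted-SRA result with the comparability report
    for the same replicate pair (``None`` means no screening, include
    unconditionally).  Pairs whose report says not comparable are listed
    in ``excluded_pairs`` with the failing gate as the reason.  Averaging
    is on the SRA scale; the pooled mean is rendered as a signed fold.
    """
    if not results:
        raise ValueError("no results to pool")
    included_sra: list[float] = []
    included_pairs: list[tuple[str, str]] = []
    excluded: list[tuple[tuple[str, str], str]] = []
    for result, report in results:
        if report is not None and not report.comparable:
            reasons = []
            if report.r_ts > report.rts_threshold:
                reasons.append(f"r_ts {report.r_ts:.2f} > {report.rts_threshold}")
            if not (report.sd_sra_in <= report.sd_threshold):
                reasons.append(f"sd_sra_in {report.sd_sra_in:.2f} > {report.sd_threshold}")
            excluded.append((result.pair, "; ".join(reasons) or "not comparable"))
            continue
        included_sra.append(result.mean_sra)
        included_pairs.append(result.pair)
    if not included_sra:
        return PooledEstimate(
            values=[], pooled_mean=float("nan"), pooled_sd=float("nan"),
            pooled_sra_mean=float("nan"),
            included_pairs=[], excluded_pairs=excluded, empty=True)
    arr = np.asarray(included_sra)
    mean_sra = float(arr.mean())
    return PooledEstimate(
        values=[_signed_fold(v) for v in included_sra],
        pooled_mean=_signed_fold(mean_sra),
        pooled_sd=float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        pooled_sra_mean=mean_sra,
        included_pairs=included_pairs,
        excluded_pairs=excluded,
    )


def quantify_between_samples(
    matrix: CountMatrix,
    sample_a: str,
    sample_b: str,
    protein_id: str,
    config: RunConfig | None = None,
    screen: bool = True,
) -> tuple[list[tuple[AdjustedSRAResult, ComparabilityReport | None]], PooledEstimate]:
    """Adjusted-SRA quantification over every cross-sample replicate pair.

    For each (replicate of ``sample_a``) x (replicate of ``sample_b``)
    pair the internal-standard-adjusted SRA of ``protein_id`` is computed;
    with ``screen=True`` each pair is also put through the comparability
    assessment and non-comparable pairs are excluded from the pool.
    Returns the per-pair results together with the pooled estimate.
    """
    config = config or RunConfig()
    results: list[tuple[AdjustedSRAResult, ComparabilityReport | None]] = []
    for rep_a in matrix.replicates_of(sample_a):
        profile_a = profile_from_matrix(matrix, rep_a)
        for rep_b in matrix.replicates_of(sample_b):
            profile_b = profile_from_matrix(matrix, rep_b)
            result = adjusted_sra(profile_a, profile_b, protein_id,
                                  config.internal_standard_ids)
            report = assess_pair(matrix, rep_a, rep_b, config) if screen else None
            results.append((result, report))
    return results, pool_fold_estimates(results)


def raw_fold_estimate(
    matrix: CountMatrix, sample_a: str, sample_b: str, protein_id: str,
) -> float:
    """Unadjusted fold of a protein from raw spectral counts.

    Mean (on the SRA scale, over all cross-sample replicate pairs) of the
    SRA of raw SpC, rendered as a signed fold.  No internal standards, no
    depth correction — the baseline the adjusted estimator improves on.
    """
    sras: list[float] = []
    for rep_a in matrix.replicates_of(sample_a):
        profile_a = profile_from_matrix(matrix, rep_a)
        for rep_b in matrix.replicates_of(sample_b):
            profile_b = profile_from_matrix(matrix, rep_b)
            value = sra_between_datasets(profile_a, profile_b, protein_id, basis="spc")
            if value is not None:
                sras.append(value.value)
    if not sras:
        raise ValueError(f"protein {protein_id!r} undetected in every pair")
    return _signed_fold(float(np.mean(sras)))
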