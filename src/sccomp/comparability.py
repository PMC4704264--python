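"""Dataset comparability: R_TS, SRA variability summaries, and verdicts.

Two LC-MS/MS runs can only be compared quantitatively if they are of
similar quality.  Two complementary screens are used:

* **R_TS** — the relative number of total spectra, ``max(SpC_total_A,
  SpC_total_B) / min(...)``, always >= 1.  A presumptive gate: runs whose
  identification depth differs grossly will not quantify reliably.
* **SD_SRA over internal standards** — constitutively expressed proteins
  act as pseudo-replicates shared by any two conditions, so the standard
  deviation of their per-protein SRA values between two datasets measures
  dataset quality without being confounded by genuine biology.

Between replicates of a single sample the SRA spread over *all* proteins
(SD_SRA[rep, k]) measures reproducibility; between different samples only
the internal-standard subset (SD_SRA[comp, INj]) is meaningful.  The
default gates — R_TS <= 1.35 and SD over standards <= 0.46-fold — can be
re-derived for any instrument or organism from the linear correlation
between R_TS and the internal-standard SD across replicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .tabular_io import CountMatrix, RunConfig
from .sra_core import AbundanceProfile, Basis, profile_from_matrix, sra_between_datasets


def r_ts(spc_total_a: int, spc_total_b: int) -> float:
    """Relative number of total spectra of two runs: max/min, >= 1."""
    if spc_total_a <= 0 or spc_total_b <= 0:
        raise ValueError("SpC_total must be positive")
    return max(spc_total_a, spc_total_b) / min(spc_total_a, spc_total_b)


@dataclass
class VariabilitySummary:
    """SRA spread between two replicates, over all proteins and standards."""

    pair: tuple[str, str]
    kind: Literal["rep", "comp"]
    ave_sra_all: float
    sd_sra_all: float
    sd_sra_in: float          # nan when no shared standards
    n_proteins_used: int
    n_standards_used: int
    r_ts: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "pair": f"{self.pair[0]}|{self.pair[1]}",
            "kind": self.kind,
            "r_ts": float("nan") if self.r_ts is None else self.r_ts,
            "ave_sra_all": self.ave_sra_all,
            "sd_sra_all": self.sd_sra_all,
            "sd_sra_in": self.sd_sra_in,
            "n_proteins_used": self.n_proteins_used,
            "n_standards_used": self.n_standards_used,
            "notes": ";".join(self.notes) or "-",
        }


def variability_summary(
    a: AbundanceProfile,
    b: AbundanceProfile,
    standards: Iterable[str],
    kind: Literal["rep", "comp"] = "rep",
    basis: Basis = "spc",
) -> VariabilitySummary:
    """Mean and SD of per-protein SRA between two profiles.

    Only proteins detected (count > 0) in both profiles enter; the SD is
    the sample standard deviation (n-1).  ``sd_sra_in`` restricts to the
    internal-standard subset and is NaN (flagged in notes) when fewer than
    two standards are shared.
    """
    standards = set(standards)
    shared = [p for p in a.protein_ids if a.detected(p) and b.detected(p)]
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 proteins detected in both {a.replicate_label} and "
            f"{b.replicate_label}, got {len(shared)}")
    values = np.array([
        sra_between_datasets(a, b, p, basis=basis).value for p in shared])
    std_values = np.array([
        v for p, v in zip(shared, values) if p in standards])

    notes = []
    n_excluded = sum(1 for p in a.protein_ids
                     if (a.detected(p) != b.detected(p)))
    if n_excluded:
        notes.append(f"{n_excluded} proteins detected in only one profile excluded")
    if len(std_values) < 2:
        notes.append("sd_sra_in undefined: fewer than 2 shared internal standards")
        sd_in = float("nan")
    else:
        sd_in = float(std_values.std(ddof=1))
    return VariabilitySummary(
        pair=(a.replicate_label, b.replicate_label),
        kind=kind,
        ave_sra_all=float(values.mean()),
        sd_sra_all=float(values.std(ddof=1)),
        sd_sra_in=sd_in,
        n_proteins_used=len(shared),
        n_standards_used=len(std_values),
        notes=notes,
    )


@dataclass
class ThresholdDerivation:
    """R_TS cutoff derived from the R_TS ~ internal-standard-SD regression."""

    points: list[tuple[float, float]]      # (r_ts, sd_sra_in)
    slope: float
    intercept: float
    r_squared: float
    sd_threshold: float
    derived_rts_threshold: float
    sd_all_threshold: float | None = None  # 2 x min(sd_sra_all), when supplied

    def to_record(self) -> dict:
        return {
            "n_points": len(self.points),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "sd_threshold": self.sd_threshold,
            "derived_rts_threshold": self.derived_rts_threshold,
            "sd_all_threshold": (float("nan") if self.sd_all_threshold is None
                                 else self.sd_all_threshold),
        }


def derive_thresholds(
    summaries: Sequence[VariabilitySummary] | Sequence[tuple[float, float]],
    sd_threshold: float = 0.46,
) -> ThresholdDerivation:
    """Fit sd_sra_in against r_ts and invert the line at ``sd_threshold``.

    Accepts variability summaries carrying ``r_ts`` or bare ``(r_ts,
    sd_sra_in)`` pairs.  Also reports twice the minimum whole-proteome SD
    (the replicate-derived gate for SD_SRA over all proteins) when
    summaries are supplied.
    """
    points: list[tuple[float, float]] = []
    sd_all_values: list[float] = []
    for item in summaries:
        if isinstance(item, VariabilitySummary):
            if item.r_ts is None:
                raise ValueError(f"summary for pair {item.pair} lacks r_ts")
            points.append((item.r_ts, item.sd_sra_in))
            sd_all_values.append(item.sd_sra_all)
        else:
            x, y = item
            points.append((float(x), float(y)))
    if len(points) < 3:
        raise ValueError("need >= 3 points for the threshold regression")
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    if np.allclose(xs, xs[0]):
        raise ValueError("degenerate regression: all r_ts values equal")
    fit = stats.linregress(xs, ys)
    if fit.slope == 0:
        raise ValueError("degenerate regression: zero slope, cannot invert")
    return ThresholdDerivation(
        points=points,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        sd_threshold=sd_threshold,
        derived_rts_threshold=float((sd_threshold - fit.intercept) / fit.slope),
        sd_all_threshold=2.0 * min(sd_all_values) if sd_all_values else None,
    )


@dataclass
class ComparabilityReport:
    """Two-gate verdict for one pair of replicates."""

    pair: tuple[str, str]
    r_ts: float
    sd_sra_in: float
    rts_threshold: float
    sd_threshold: float
    comparable: bool
    notes: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "pair": f"{self.pair[0]}|{self.pair[1]}",
            "r_ts": self.r_ts,
            "sd_sra_in": self.sd_sra_in,
            "rts_threshold": self.rts_threshold,
            "sd_threshold": self.sd_threshold,
            "comparable": self.comparable,
            "notes": ";".join(self.notes) or "-",
        }


def assess_pair(
    counts: CountMatrix,
    rep_a: str | tuple[str, str],
    rep_b: str | tuple[str, str],
    config: RunConfig | None = None,
) -> ComparabilityReport:
    """Assess whether two replicate datasets are quantitatively comparable.

    The verdict is the conjunction of the R_TS gate (presumptive, from raw
    identification depth) and the internal-standard SD gate; both use full
    precision, rounding is presentation-only.  Comparing a replicate with
    itself trivially passes.  When no internal-standard SD can be computed
    the SD gate fails closed (not comparable) with a note.
    """
    config = config or RunConfig()
    profile_a = profile_from_matrix(counts, rep_a)
    profile_b = profile_from_matrix(counts, rep_b)
    value = r_ts(counts.spc_total(rep_a), counts.spc_total(rep_b))
    kind = "rep" if profile_a.replicate_label.split(":")[0] == \
        profile_b.replicate_label.split(":")[0] else "comp"
    summary = variability_summary(
        profile_a, profile_b, config.internal_standard_ids, kind=kind)
    notes = list(summary.notes)
    sd_in = summary.sd_sra_in
    if np.isnan(sd_in):
        sd_gate = False
        notes.append("sd gate failed: internal-standard SD undefined")
    else:
        sd_gate = sd_in <= config.sd_in_threshold
    comparable = (value <= config.rts_threshold) and sd_gate
    return ComparabilityReport(
        pair=(profile_a.replicate_label, profile_b.replicate_label),
        r_ts=value,
        sd_sra_in=sd_in,
        rts_threshold=config.rts_threshold,
        sd_threshold=config.sd_in_threshold,
        comparable=comparable,
        notes=notes,
    )
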