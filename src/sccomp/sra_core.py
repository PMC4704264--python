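"""The scalar relative amount (SRA) transform and its internal-standard
adjustment.

Ratios cannot be averaged directly: a two-fold increase (ratio 2.0) and a
two-fold decrease (ratio 0.5) should average to "no change", yet their
arithmetic mean is 1.25.  The SRA transform maps a ratio of two positive
abundances onto a signed linear scale where opposite fold changes cancel::

    SRA[a|b] = a/b - 1   if a >= b
             = 1 - b/a   if a <  b

so +0.5 and -0.5 are a 1.5-fold increase and decrease, and opposite
two-fold changes (+1, -1) average to exactly zero.  The fold magnitude is
always ``|SRA| + 1``; the sign carries direction only.

Abundances may be raw spectral counts (SpC) or normalized spectral
abundance factors (NSAF).  For the internal-standard-adjusted SRA the two
choices coincide: each standard j turns the comparison of protein k
between samples A and B into a ratio of within-sample ratios
``(x_Ak / x_Aj) / (x_Bk / x_Bj)`` in which every per-sample normalizer
(total spectra, and the per-protein length if both measures use it)
cancels algebraically — this cancellation is exactly the depth correction
the internal standards provide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .tabular_io import CountMatrix

logger = logging.getLogger(__name__)

Basis = Literal["nsaf", "spc"]


@dataclass
class AbundanceProfile:
    """Per-protein abundances of one replicate: raw counts plus NSAF."""

    replicate_label: str
    protein_ids: list[str]
    spc: np.ndarray
    nsaf: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.spc = np.asarray(self.spc, dtype=np.int64)
        self.nsaf = np.asarray(self.nsaf, dtype=float)
        if not (len(self.protein_ids) == len(self.spc) == len(self.nsaf)):
            raise ValueError("profile arrays must align with protein ids")
        self._index = {p: i for i, p in enumerate(self.protein_ids)}

    def get(self, protein_id: str, basis: Basis = "spc") -> float:
        i = self._index[protein_id]
        return float(self.spc[i]) if basis == "spc" else float(self.nsaf[i])

    def detected(self, protein_id: str) -> bool:
        i = self._index.get(protein_id)
        return i is not None and self.spc[i] > 0


def nsaf(
    spc: Sequence[int] | np.ndarray,
    lengths: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Normalized spectral abundance factors for one replicate.

    ``nsaf_k = (spc_k / L_k) / sum_j (spc_j / L_j)``.  When no lengths are
    given the length-free variant (L == 1, i.e. plain spectral fractions)
    is used.  Zero-count proteins get NSAF 0; the nonzero entries sum to 1.
    """
    spc = np.asarray(spc, dtype=float)
    if np.any(spc < 0):
        raise ValueError("spectral counts must be non-negative")
    if not np.any(spc > 0):
        raise ValueError("cannot normalize an all-zero count profile")
    if lengths is None:
        saf = spc
    else:
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths <= 0):
            raise ValueError("protein lengths must be positive")
        saf = spc / lengths
    return saf / saf.sum()


def profile_from_matrix(
    matrix: CountMatrix, label: str | tuple[str, str]
) -> AbundanceProfile:
    """Build the abundance profile of one replicate column of a count matrix."""
    counts = matrix.column(label)
    label_str = label if isinstance(label, str) else f"{label[0]}:{label[1]}"
    return AbundanceProfile(
        replicate_label=label_str,
        protein_ids=list(matrix.protein_ids),
        spc=counts,
        nsaf=nsaf(counts, matrix.lengths),
    )


@dataclass(frozen=True)
class SRAValue:
    """A signed scalar relative amount; 0 means no change."""

    value: float

    @property
    def fold_magnitude(self) -> float:
        return abs(self.value) + 1.0

    @property
    def fold_text(self) -> str:
        if self.value == 0:
            return "1.00-fold (no change)"
        direction = "increase" if self.value > 0 else "decrease"
        return f"{self.fold_magnitude:.2f}-fold {direction}"

    def __float__(self) -> float:
        return self.value


def sra(alpha: float, beta: float) -> SRAValue:
    """Scalar relative amount of ``alpha`` versus ``beta`` (both > 0)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("SRA is defined for positive abundances only")
    if alpha >= beta:
        return SRAValue(alpha / beta - 1.0)
    return SRAValue(1.0 - beta / alpha)


def sra_between_datasets(
    a: AbundanceProfile,
    b: AbundanceProfile,
    protein_id: str,
    basis: Basis = "nsaf",
) -> SRAValue | None:
    """SRA of one protein between two replicates (same or different sample).

    Returns ``None`` when the protein has a zero count in either profile:
    undetected proteins are excluded from SRA arithmetic, never imputed.
    """
    if not (a.detected(protein_id) and b.detected(protein_id)):
        return None
    return sra(a.get(protein_id, basis), b.get(protein_id, basis))


@dataclass
class AdjustedSRAResult:
    """Internal-standard-adjusted SRA of one protein between two datasets.

    Each usable standard j yields one SRA of the ratio-of-ratios
    ``(k_A / IN_Aj) | (k_B / IN_Bj)``; the result is their mean with the
    spread over the N standards as the uncertainty.
    """

    protein_id: str
    pair: tuple[str, str]
    per_standard_sra: list[float]
    mean_sra: float
    sd_sra: float
    n_standards: int
    dropped_standards: list[str] = field(default_factory=list)

    @property
    def fold_magnitude(self) -> float:
        return abs(self.mean_sra) + 1.0

    @property
    def signed_fold(self) -> float:
        """Fold magnitude carrying the SRA's direction sign."""
        return math.copysign(self.fold_magnitude, self.mean_sra) if self.mean_sra else 1.0

    def to_record(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "pair": f"{self.pair[0]}|{self.pair[1]}",
            "mean_sra": self.mean_sra,
            "sd_sra": self.sd_sra,
            "fold": self.fold_magnitude,
            "direction": "increase" if self.mean_sra > 0 else
                         ("decrease" if self.mean_sra < 0 else "none"),
            "n_standards": self.n_standards,
            "dropped_standards": ";".join(self.dropped_standards) or "-",
        }


def adjusted_sra(
    a: AbundanceProfile,
    b: AbundanceProfile,
    protein_id: str,
    standards: Iterable[str],
    basis: Basis = "spc",
    pseudocount: float = 0.0,
) -> AdjustedSRAResult:
    """Internal-standard-adjusted SRA of ``protein_id`` between profiles.

    Standards with a zero count in either profile are dropped with a
    warning and N reduced; at least one usable standard is required.  The
    ``basis`` choice (raw counts vs NSAF) does not change the result —
    the normalizers cancel in the ratio of ratios — so ``spc`` is the
    default.  ``pseudocount`` (> 0 rescues zero-count entries) exists for
    exploration only and is off by default.
    """
    standards = list(standards)
    if not standards:
        raise ValueError("no internal standards supplied")

    def value(profile: AbundanceProfile, pid: str) -> float:
        if pid not in profile._index:
            return pseudocount
        v = profile.get(pid, basis)
        if v == 0:
            return pseudocount
        return v

    k_a = value(a, protein_id)
    k_b = value(b, protein_id)
    if k_a <= 0 or k_b <= 0:
        raise ValueError(
            f"protein {protein_id!r} has no counts in "
            f"{a.replicate_label if k_a <= 0 else b.replicate_label}; "
            "adjusted SRA is undefined")

    per_standard: list[float] = []
    dropped: list[str] = []
    for std in standards:
        in_a = value(a, std)
        in_b = value(b, std)
        if in_a <= 0 or in_b <= 0:
            dropped.append(std)
            continue
        per_standard.append(sra(k_a / in_a, k_b / in_b).value)
    if dropped:
        logger.warning(
            "dropped %d/%d internal standards with zero counts in %s|%s: %s",
            len(dropped), len(standards), a.replicate_label, b.replicate_label,
            ", ".join(dropped))
    if not per_standard:
        raise ValueError(
            f"no usable internal standards between {a.replicate_label} "
            f"and {b.replicate_label}")

    arr = np.asarray(per_standard)
    return AdjustedSRAResult(
        protein_id=protein_id,
        pair=(a.replicate_label, b.replicate_label),
        per_standard_sra=per_standard,
        mean_sra=float(arr.mean()),
        sd_sra=float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        n_standards=len(per_standard),
        dropped_standards=dropped,
    )
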