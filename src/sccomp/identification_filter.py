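"""Protein presence scoring across replicates and target-decoy FDR.

Presence scoring addresses the usual ragged-identification problem: one
biological replicate identifies a protein, another does not.  Each
(protein, replicate) identification gets a confidence score in {0..3} from
the number of unique peptides and the X!Tandem ``-log(e)``; a protein is
called present in a sample when the scores summed over its n replicates
reach n.  With triplicates this means one high-confidence identification
(score 3) or a low-confidence identification (score 1) in every replicate
suffices.

False discovery rate over a target/decoy search is estimated as
``R / (F + R)`` with R decoy and F target matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tabular_io import IdentificationTable, parse_replicate_label


@dataclass
class PresenceCall:
    """Per-sample presence verdict for one protein."""

    protein_id: str
    per_replicate_scores: list[int]
    id_score: int
    n_replicates: int
    present: bool

    def to_record(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "scores": ",".join(str(s) for s in self.per_replicate_scores),
            "id_score": self.id_score,
            "n_replicates": self.n_replicates,
            "present": self.present,
        }


@dataclass
class FDRResult:
    """Target/decoy tally with the resulting FDR estimate."""

    n_target: int
    n_decoy: int
    fdr: float
    score_cutoff: float | None = None
    threshold_met: bool = True

    def to_record(self) -> dict:
        return {
            "n_target": self.n_target,
            "n_decoy": self.n_decoy,
            "fdr": self.fdr,
            "score_cutoff": float("nan") if self.score_cutoff is None else self.score_cutoff,
            "threshold_met": self.threshold_met,
        }


def score_replicate(pep_uniq: int, neg_log_e: float) -> int:
    """Score one replicate's identification evidence on the 0–3 scale.

    3: >=2 unique peptides AND -log(e) >= 10 (high confidence);
    2: >=2 unique peptides OR -log(e) >= 10;
    1: exactly one unique peptide with 2 <= -log(e) < 10;
    0: anything weaker.  Rows are evaluated strictly in this order.
    """
    if pep_uniq < 0:
        raise ValueError("pep_uniq must be >= 0")
    if pep_uniq >= 2 and neg_log_e >= 10:
        return 3
    if pep_uniq >= 2 or neg_log_e >= 10:
        return 2
    if pep_uniq == 1 and 2 <= neg_log_e < 10:
        return 1
    return 0


def call_presence(table: IdentificationTable, sample: str) -> list[PresenceCall]:
    """Call presence for every protein seen in any replicate of ``sample``.

    A protein not observed in a replicate contributes a score of 0 there.
    The protein is present iff the summed score reaches the number of
    replicates in the sample.
    """
    df = table.rows
    rep_sample = df["replicate"].map(lambda r: parse_replicate_label(r)[0])
    sub = df[rep_sample == sample]
    if sub.empty:
        raise KeyError(f"sample {sample!r} has no rows in the identification table")
    replicates = sorted(sub["replicate"].unique())
    n = len(replicates)
    scores: dict[str, dict[str, int]] = {}
    for row in sub.itertuples(index=False):
        scores.setdefault(row.protein_id, {})[row.replicate] = score_replicate(
            int(row.pep_uniq), float(row.neg_log_e))
    calls = []
    for protein_id in dict.fromkeys(sub["protein_id"]):  # first-seen order
        per_rep = [scores[protein_id].get(rep, 0) for rep in replicates]
        id_score = int(sum(per_rep))
        calls.append(PresenceCall(
            protein_id=protein_id,
            per_replicate_scores=per_rep,
            id_score=id_score,
            n_replicates=n,
            present=id_score >= n,
        ))
    return calls


def compute_fdr(n_target: int, n_decoy: int) -> FDRResult:
    """FDR = R/(F+R) for F target and R decoy matches."""
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    if n_target + n_decoy == 0:
        raise ValueError("FDR undefined with no matches")
    return FDRResult(n_target=n_target, n_decoy=n_decoy,
                     fdr=n_decoy / (n_target + n_decoy))


def fdr_threshold(
    psms: Sequence[tuple[float, bool]], level: float = 0.01
) -> FDRResult:
    """Pick the most permissive score cutoff holding FDR at ``level``.

    ``psms`` is a list of ``(score, is_decoy)`` pairs.  The threshold is
    closed: every match with score >= cutoff is accepted, ties included.
    Returns the smallest cutoff whose accepted set has R/(F+R) <= level.
    If no cutoff achieves the level, the strictest candidate cutoff is
    returned with its achieved FDR and ``threshold_met=False``.
    """
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    if len(psms) == 0:
        raise ValueError("no PSMs supplied")
    scores = np.asarray([s for s, _ in psms], dtype=float)
    decoys = np.asarray([bool(d) for _, d in psms])
    if not (~decoys).any():
        raise ValueError("need at least one target PSM")

    order = np.argsort(scores)[::-1]  # descending
    s_sorted = scores[order]
    d_sorted = decoys[order]
    cum_decoy = np.cumsum(d_sorted)
    cum_total = np.arange(1, len(psms) + 1)

    # Candidate cutoffs are the distinct scores; a closed cutoff at score s
    # accepts the prefix of all PSMs with score >= s.
    # last index of each distinct score in the descending sort:
    is_last = np.empty(len(psms), dtype=bool)
    is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
    is_last[-1] = True
    idx = np.flatnonzero(is_last)

    best = None  # (cutoff, n_target, n_decoy, fdr)
    for i in idx:
        r = int(cum_decoy[i])
        total = int(cum_total[i])
        f = total - r
        fdr = r / total
        if fdr <= level:
            best = (float(s_sorted[i]), f, r, fdr)  # keep lowest qualifying cutoff
    if best is not None:
        cutoff, f, r, fdr = best
        return FDRResult(n_target=f, n_decoy=r, fdr=fdr,
                         score_cutoff=cutoff, threshold_met=True)
    # strictest cutoff: highest distinct score
    i = idx[0]
    r = int(cum_decoy[i])
    total = int(cum_total[i])
    return FDRResult(n_target=total - r, n_decoy=r, fdr=r / total,
                     score_cutoff=float(s_sorted[i]), threshold_met=False)


def drop_decoys(table: IdentificationTable) -> IdentificationTable:
    """Remove decoy rows after thresholding; decoys never reach count matrices."""
    return IdentificationTable(table.rows[~table.rows["is_decoy"]].reset_index(drop=True))
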