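"""Tabular input/output for spectral-count data.

All exchange formats are plain TSV (UTF-8, ``#``-prefixed comment lines
allowed).  The toolkit consumes search-engine *summaries* — count matrices
and per-replicate identification tables — never raw mass-spectrometry
formats.  Replicate columns are addressed by compound ``sample:replicate``
labels (e.g. ``High-1:A``) so that multi-sample, multi-replicate designs
stay expressible in a single flat file.

No science lives in this module; it validates, round-trips and warns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The nine glycolytic enzymes of Lactococcus lactis used as the default
#: internal-standard panel (constitutively expressed across growth phases).
DEFAULT_INTERNAL_STANDARDS: tuple[str, ...] = (
    "pgiA", "pfkA", "pbaA", "tpiA", "gapA", "pgk", "pmg", "eno", "pyk",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def parse_replicate_label(label: str) -> tuple[str, str]:
    """Split a ``sample:replicate`` compound label into its two parts."""
    sample, sep, replicate = label.partition(":")
    if not sep or not sample or not replicate:
        raise FormatError(
            f"replicate column {label!r} is not of the form 'sample:replicate'"
        )
    return sample, replicate


@dataclass
class CountMatrix:
    """Spectral counts per protein per replicate.

    Parameters
    ----------
    protein_ids
        Opaque string identifiers, unique, in file order.
    replicate_labels
        ``(sample, replicate)`` pairs, unique, in file column order.
    counts
        Non-negative integer matrix of shape ``(n_proteins, n_replicates)``.
    lengths
        Optional per-protein sequence length in amino acids (> 0), used by
        the length-normalized abundance measure.
    """

    protein_ids: list[str]
    replicate_labels: list[tuple[str, str]]
    counts: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.protein_ids), len(self.replicate_labels)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.replicate_labels)} replicates"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("spectral counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for protein {self.protein_ids[r]!r} in "
                f"replicate {self.label_strings[c]!r}"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = {p for p in self.protein_ids if self.protein_ids.count(p) > 1}
            raise ValidationError(f"duplicate protein ids: {sorted(dupes)}")
        if len(set(self.replicate_labels)) != len(self.replicate_labels):
            raise ValidationError("duplicate replicate labels")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths)
            if len(self.lengths) != len(self.protein_ids):
                raise ValidationError("lengths do not match protein count")
            if np.any(self.lengths <= 0):
                raise ValidationError("protein lengths must be positive")

    @property
    def label_strings(self) -> list[str]:
        """Replicate labels rendered back as ``sample:replicate`` strings."""
        return [f"{s}:{r}" for s, r in self.replicate_labels]

    @property
    def samples(self) -> list[str]:
        """Distinct sample names in first-appearance order."""
        seen: dict[str, None] = {}
        for s, _ in self.replicate_labels:
            seen.setdefault(s)
        return list(seen)

    def column_index(self, label: str | tuple[str, str]) -> int:
        if isinstance(label, str):
            label = parse_replicate_label(label)
        try:
            return self.replicate_labels.index(label)
        except ValueError:
            raise KeyError(f"replicate {label[0]}:{label[1]} not in matrix") from None

    def replicates_of(self, sample: str) -> list[tuple[str, str]]:
        labels = [lab for lab in self.replicate_labels if lab[0] == sample]
        if not labels:
            raise KeyError(f"sample {sample!r} not in matrix")
        return labels

    def column(self, label: str | tuple[str, str]) -> np.ndarray:
        return self.counts[:, self.column_index(label)]

    def spc_total(self, label: str | tuple[str, str]) -> int:
        """Total number of identification spectra in one replicate."""
        return int(self.column(label).sum())

    def spc_totals(self) -> dict[str, int]:
        return {lab: int(t) for lab, t in zip(self.label_strings, self.counts.sum(axis=0))}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=pd.Index(self.protein_ids, name="protein_id"),
                          columns=self.label_strings)
        if self.lengths is not None:
            df.insert(0, "length", self.lengths)
        return df


@dataclass
class IdentificationTable:
    """Per-replicate identification evidence.

    One row per (protein, replicate): the number of unique peptides backing
    the identification, the X!Tandem ``-log(e)`` confidence score, the
    spectral count, and an optional decoy flag.
    """

    rows: pd.DataFrame  # protein_id, replicate, pep_uniq, neg_log_e, spc, is_decoy

    def __post_init__(self) -> None:
        df = self.rows
        required = ["protein_id", "replicate", "pep_uniq", "neg_log_e", "spc"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"identification table missing columns: {missing}")
        if "is_decoy" not in df.columns:
            df = df.assign(is_decoy=False)
        if df.duplicated(["protein_id", "replicate"]).any():
            dup = df[df.duplicated(["protein_id", "replicate"], keep=False)]
            pairs = sorted(set(zip(dup["protein_id"], dup["replicate"])))
            raise ValidationError(f"duplicate (protein, replicate) rows: {pairs[:5]}")
        if (df["pep_uniq"] < 0).any():
            bad = df.loc[df["pep_uniq"] < 0].iloc[0]
            raise ValidationError(
                f"pep_uniq < 0 for protein {bad['protein_id']!r} replicate {bad['replicate']!r}"
            )
        if (df["spc"] < 0).any():
            bad = df.loc[df["spc"] < 0].iloc[0]
            raise ValidationError(
                f"spc < 0 for protein {bad['protein_id']!r} replicate {bad['replicate']!r}"
            )
        self.rows = df.reset_index(drop=True)

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for rep in self.rows["replicate"]:
            seen.setdefault(parse_replicate_label(rep)[0])
        return list(seen)


@dataclass
class RunConfig:
    """Thresholds and the internal-standard panel for one analysis run."""

    internal_standard_ids: list[str] = field(
        default_factory=lambda: list(DEFAULT_INTERNAL_STANDARDS))
    sd_in_threshold: float = 0.46   # fold-deviation gate on internal standards
    rts_threshold: float = 1.35     # gate on the relative number of total spectra
    fdr_level: float = 0.01
    presence_score_threshold_rule: str = "equal to replicate count"

    def __post_init__(self) -> None:
        if self.sd_in_threshold <= 0 or self.rts_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if not (0 < self.fdr_level <= 1):
            raise ValidationError("fdr_level must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "internal_standard_ids": list(self.internal_standard_ids),
            "sd_in_threshold": self.sd_in_threshold,
            "rts_threshold": self.rts_threshold,
            "fdr_level": self.fdr_level,
            "presence_score_threshold_rule": self.presence_score_threshold_rule,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       skip_blank_lines=True)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a protein x replicate spectral-count TSV.

    Layout: first column ``protein_id``, optional column ``length``, then
    one column per replicate named ``sample:replicate``.  Empty cells are
    treated as zero counts (a warning is logged): identification tables
    routinely omit proteins that were simply not detected in a run.
    """
    df = _read_tsv(path)
    if df.columns[0] != "protein_id":
        raise FormatError(
            f"{path}: first column must be 'protein_id', got {df.columns[0]!r}")
    protein_ids = df["protein_id"].tolist()
    lengths = None
    rep_cols = [c for c in df.columns[1:]]
    if rep_cols and rep_cols[0] == "length":
        lengths = pd.to_numeric(df["length"], errors="coerce").to_numpy()
        if np.isnan(lengths).any():
            raise ValidationError(f"{path}: non-numeric protein length")
        rep_cols = rep_cols[1:]
    if not rep_cols:
        raise FormatError(f"{path}: no replicate columns found")
    replicate_labels = [parse_replicate_label(c) for c in rep_cols]

    raw = df[rep_cols]
    n_missing = int(raw.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d empty count cells treated as 0", path, n_missing)
    counts = np.zeros((len(protein_ids), len(rep_cols)), dtype=np.int64)
    for j, col in enumerate(rep_cols):
        for i, cell in enumerate(raw[col]):
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric count {cell!r} for protein "
                    f"{protein_ids[i]!r}, column {col!r}") from None
            if value != int(value):
                raise ValidationError(
                    f"{path}: non-integer count {cell!r} for protein "
                    f"{protein_ids[i]!r}, column {col!r}")
            counts[i, j] = int(value)
    return CountMatrix(protein_ids, replicate_labels, counts, lengths)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_identification_table(path: str | Path) -> IdentificationTable:
    """Read a per-replicate identification-evidence TSV.

    Columns: ``protein_id, replicate, pep_uniq, neg_log_e, spc[, decoy]``.
    The decoy column defaults to false when absent.
    """
    df = _read_tsv(path)
    required = ["protein_id", "replicate", "pep_uniq", "neg_log_e", "spc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    out = pd.DataFrame({
        "protein_id": df["protein_id"],
        "replicate": df["replicate"],
        "pep_uniq": pd.to_numeric(df["pep_uniq"]).astype(int),
        "neg_log_e": pd.to_numeric(df["neg_log_e"]).astype(float),
        "spc": pd.to_numeric(df["spc"]).astype(int),
    })
    if "decoy" in df.columns:
        out["is_decoy"] = df["decoy"].str.strip().str.lower().isin(
            {"1", "true", "yes", "y", "t"})
    return IdentificationTable(out)


#: Fixed decimal precision for all real-valued report fields.
REPORT_DECIMALS = 4


def _format_real(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{REPORT_DECIMALS}f}"


def write_report(report, path: str | Path) -> None:
    """Write a result object (or list of them) as a deterministic TSV.

    Accepts anything exposing ``to_record()`` -> dict, or a list of such
    objects sharing one schema.  Reals are printed with 4 decimals; column
    order follows the record's key order, so repeated runs are
    byte-identical.
    """
    items = report if isinstance(report, (list, tuple)) else [report]
    records = [item.to_record() for item in items]
    if not records:
        raise ValueError("write_report needs a populated report")
    columns = list(records[0])

    def _write(fh) -> None:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            cells = []
            for col in columns:
                v = rec[col]
                if isinstance(v, bool):
                    cells.append(str(v).lower())
                elif isinstance(v, float):
                    cells.append(_format_real(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")

    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            _write(fh)


def read_report(path: str | Path) -> pd.DataFrame:
    """Re-parse a report TSV written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    for col in df.columns:
        if df[col].dtype == object:
            lowered = df[col].astype(str).str.lower()
            if lowered.isin({"true", "false"}).all():
                df[col] = lowered == "true"
    return df
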