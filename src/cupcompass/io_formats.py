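"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are kept 0-based half-open internally; GTF input
(1-based inclusive) is converted at the boundary.  Readers validate
strictly and raise :class:`FormatError` rather than silently coercing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "FormatError",
    "ExpressionProfile",
    "MethylomeProfile",
    "Segment",
    "VariantSummary",
    "TherapyLine",
    "SurvivalRecord",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_segments",
    "write_segments",
    "read_intervals",
    "read_clinical",
    "write_clinical",
    "profiles_to_frame",
    "LINE_ROLES",
    "PLATFORMS_METH",
    "PLATFORMS_SEQ",
]

LINE_ROLES = frozenset(
    {"pre_mtb_last", "recommended_first", "recommended_later", "post_mtb_other"}
)
PLATFORMS_METH = frozenset({"850k", "450k", "27k"})
PLATFORMS_SEQ = frozenset({"WGS", "WES_v5_UTR", "WES_v5"})
EVENT_TYPES = frozenset({"progression", "death", "censored"})


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """Per-sample gene expression vector in FPKM units."""

    sample_id: str
    values: pd.Series  # gene_id -> FPKM, nonnegative
    entity: Optional[str] = None
    is_cup: bool = False
    biopsy_site: Optional[str] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError(f"duplicate gene ids in profile {self.sample_id}")
        if (self.values < 0).any():
            raise FormatError(f"negative FPKM in profile {self.sample_id}")


@dataclass
class MethylomeProfile:
    """Per-sample CpG beta-value vector; NaN marks missing probes."""

    sample_id: str
    values: pd.Series  # probe_id -> beta in [0, 1] or NaN
    entity: Optional[str] = None
    platform: str = "850k"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS_METH:
            raise FormatError(f"unknown methylation platform {self.platform!r}")
        present = self.values.dropna()
        if ((present < 0) | (present > 1)).any():
            raise FormatError(f"beta outside [0,1] in profile {self.sample_id}")


@dataclass
class Segment:
    """Genomic copy-number segment (0-based half-open coordinates)."""

    chromosome: str
    start: int
    end: int
    coverage_ratio: float
    baf: float
    n_het_snps: int
    cn_major: Optional[int] = None
    cn_minor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"segment end <= start ({self.chromosome}:{self.start}-{self.end})"
            )
        if not (0.0 <= self.baf <= 0.5):
            raise FormatError(f"BAF {self.baf} outside [0, 0.5]")
        if self.coverage_ratio <= 0:
            raise FormatError(f"nonpositive coverage ratio {self.coverage_ratio}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class VariantSummary:
    """Per-sample variant counts used for TMB and hypermutation calls."""

    sample_id: str
    n_nonsilent_snv: int
    n_coding_indel: int
    platform: str = "WGS"

    def __post_init__(self) -> None:
        if self.n_nonsilent_snv < 0 or self.n_coding_indel < 0:
            raise FormatError("variant counts must be nonnegative")
        if self.platform not in PLATFORMS_SEQ:
            raise FormatError(f"unknown sequencing platform {self.platform!r}")

    @property
    def total(self) -> int:
        return self.n_nonsilent_snv + self.n_coding_indel


@dataclass
class TherapyLine:
    """One dated systemic-therapy line of a patient."""

    patient_id: str
    line_role: str
    start_date: _dt.date
    event_date: Optional[_dt.date] = None
    event_type: str = "censored"

    def __post_init__(self) -> None:
        if self.line_role not in LINE_ROLES:
            raise FormatError(f"unknown line role {self.line_role!r}")
        if self.event_type not in EVENT_TYPES:
            raise FormatError(f"unknown event type {self.event_type!r}")
        if self.event_date is not None and self.event_date < self.start_date:
            raise FormatError(
                f"event before start for {self.patient_id}/{self.line_role}"
            )


@dataclass
class SurvivalRecord:
    """Time-to-event observation (months) for survival analysis."""

    patient_id: str
    time_months: float
    event: bool  # True = death/progression observed, False = censored

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise FormatError(f"nonpositive survival time for {self.patient_id}")


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path: str, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {kind} matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"non-numeric values in columns {non_numeric[:5]} of {path}")
    return df.astype(float)


def read_expression_matrix(
    path: str, label_table: Optional[pd.DataFrame] = None
) -> list[ExpressionProfile]:
    """Read a genes x samples FPKM TSV into profiles sharing one gene universe.

    ``label_table`` may carry columns ``entity``, ``is_cup`` and
    ``biopsy_site`` indexed by sample id.
    """
    df = _read_matrix(path, "expression")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        line_no = int(np.where(df.index == row)[0][0]) + 2  # +header +1-based
        raise FormatError(f"missing FPKM value at line {line_no} ({row}) in {path}")
    if (df.values < 0).any():
        row = df.index[(df < 0).any(axis=1)][0]
        line_no = int(np.where(df.index == row)[0][0]) + 2
        raise FormatError(f"negative FPKM at line {line_no} ({row}) in {path}")
    profiles = []
    for sample in df.columns:
        meta = {}
        if label_table is not None and sample in label_table.index:
            rec = label_table.loc[sample]
            meta["entity"] = rec.get("entity") if pd.notna(rec.get("entity")) else None
            meta["is_cup"] = bool(rec.get("is_cup", False))
            site = rec.get("biopsy_site")
            meta["biopsy_site"] = site if pd.notna(site) else None
        profiles.append(ExpressionProfile(sample, df[sample].copy(), **meta))
    return profiles


def write_expression_matrix(profiles: Sequence[ExpressionProfile], path: str) -> None:
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_beta_matrix(path: str) -> list[MethylomeProfile]:
    """Read a probes x samples beta-value TSV; empty cells / 'NA' are missing."""
    df = _read_matrix(path, "beta")
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        row = df.index[bad.any(axis=1)][0]
        line_no = int(np.where(df.index == row)[0][0]) + 2
        raise FormatError(f"beta outside [0,1] at line {line_no} ({row}) in {path}")
    return [MethylomeProfile(s, df[s].copy()) for s in df.columns]


def write_beta_matrix(profiles: Sequence[MethylomeProfile], path: str) -> None:
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def profiles_to_frame(
    profiles: Sequence[ExpressionProfile] | Sequence[MethylomeProfile],
) -> pd.DataFrame:
    """Stack per-sample profiles into a features x samples DataFrame."""
    if not profiles:
        return pd.DataFrame()
    return pd.DataFrame({p.sample_id: p.values for p in profiles})


# ---------------------------------------------------------------------------
# segments and intervals
# ---------------------------------------------------------------------------

_SEG_COLS = [
    "chromosome",
    "start",
    "end",
    "coverage_ratio",
    "baf",
    "n_het_snps",
    "cn_major",
    "cn_minor",
]


def read_segments(path: str) -> list[Segment]:
    """Read a SEG-like TSV of allele-specific copy-number segments."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"chromosome": str})
    missing = set(_SEG_COLS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"segment table {path} lacks columns {sorted(missing)}")
    segs = []
    for i, row in df.iterrows():
        try:
            segs.append(
                Segment(
                    chromosome=str(row["chromosome"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    coverage_ratio=float(row["coverage_ratio"]),
                    baf=float(row["baf"]),
                    n_het_snps=int(row["n_het_snps"]),
                    cn_major=None if pd.isna(row.get("cn_major")) else int(row["cn_major"]),
                    cn_minor=None if pd.isna(row.get("cn_minor")) else int(row["cn_minor"]),
                )
            )
        except FormatError as exc:
            raise FormatError(f"line {i + 2} of {path}: {exc}") from exc
    return segs


def write_segments(segments: Sequence[Segment], path: str) -> None:
    rows = [
        {
            "chromosome": s.chromosome,
            "start": s.start,
            "end": s.end,
            "coverage_ratio": s.coverage_ratio,
            "baf": s.baf,
            "n_het_snps": s.n_het_snps,
            "cn_major": s.cn_major,
            "cn_minor": s.cn_minor,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_intervals(path: str, feature_filter: Optional[str] = None) -> pr.PyRanges:
    """Read genomic intervals from BED (0-based half-open) or GTF (1-based).

    GTF coordinates are converted to the internal 0-based half-open
    convention; ``feature_filter`` (e.g. ``"CDS"``) selects GTF feature
    rows.  A GTF with no matching features yields an empty range set.
    """
    if path.endswith((".gtf", ".gtf.gz")):
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "Chromosome",
                "source",
                "Feature",
                "Start",
                "End",
                "score",
                "strand",
                "frame",
                "attribute",
            ],
            dtype={"Chromosome": str},
        )
        if feature_filter is not None:
            df = df[df["Feature"] == feature_filter]
        if df.empty:
            return pr.PyRanges()
        if (df["End"] < df["Start"]).any():
            raise FormatError(f"GTF interval with end < start in {path}")
        out = df[["Chromosome", "Start", "End"]].copy()
        out["Start"] = out["Start"] - 1  # GTF is 1-based inclusive
        return pr.PyRanges(out)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["Chromosome", "Start", "End"],
        dtype={"Chromosome": str},
    )
    if (df["End"] <= df["Start"]).any():
        raise FormatError(f"BED interval with end <= start in {path}")
    return pr.PyRanges(df)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CLIN_COLS = ["patient_id", "line_role", "start_date", "event_date", "event_type"]


def _parse_date(value, where: str) -> Optional[_dt.date]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise FormatError(f"unparseable ISO-8601 date {value!r} at {where}") from exc


def read_clinical(path: str) -> list[TherapyLine]:
    """Read a therapy-line CSV with ISO-8601 dates into TherapyLine records."""
    df = pd.read_csv(path, dtype=str)
    missing = set(_CLIN_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table {path} lacks columns {sorted(missing)}")
    lines = []
    for i, row in df.iterrows():
        where = f"line {i + 2} of {path}"
        start = _parse_date(row["start_date"], where)
        if start is None:
            raise FormatError(f"missing start_date at {where}")
        try:
            lines.append(
                TherapyLine(
                    patient_id=str(row["patient_id"]),
                    line_role=str(row["line_role"]),
                    start_date=start,
                    event_date=_parse_date(row["event_date"], where),
                    event_type=str(row["event_type"]),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{where}: {exc}") from exc
    return lines


def write_clinical(lines: Sequence[TherapyLine], path: str) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "line_role": t.line_role,
            "start_date": t.start_date.isoformat(),
            "event_date": "" if t.event_date is None else t.event_date.isoformat(),
            "event_type": t.event_type,
        }
        for t in lines
    ]
    pd.DataFrame(rows, columns=_CLIN_COLS).to_csv(path, index=False)
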