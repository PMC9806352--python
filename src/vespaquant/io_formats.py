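"""Readers and writers for every table the pipeline exchanges.

Dialects are deliberately rigid: comma-separated CSV for search-engine
exports and composition tables, tab-separated TSV for lane profiles, band
tables, annotation maps and RSEM-style transcript quantifications.  All
files are UTF-8 with a mandatory header row and "." as the decimal mark;
thousands separators are rejected by construction (plain float parsing).
Unknown extra columns are preserved on read and ignored by computation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralHit",
    "AnnotationRecord",
    "TranscriptRecord",
    "LaneProfile",
    "TableDialect",
    "read_spectral_hits",
    "write_spectral_hits",
    "read_annotation_map",
    "write_annotation_map",
    "read_transcript_quant",
    "write_transcript_quant",
    "read_lane_profile",
    "write_lane_profile",
    "read_band_definitions",
    "write_band_definitions",
    "read_band_areas",
    "write_band_areas",
    "read_composition",
    "write_composition",
]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralHit:
    """One protein identification in one gel band.

    ``score`` is the search engine's -10*log10(p) protein confidence score
    (higher is better), ``auc`` the area under the spectral-intensity curve
    for the protein's peptides in this band — the label-free abundance proxy.
    """

    band_id: str
    accession: str
    score: float
    unique_peptides: int
    auc: float
    description: str = ""
    is_contaminant: bool = False
    extra: tuple = ()  # preserved unknown columns as (name, value) pairs

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValidationError(f"negative auc for {self.accession!r}: {self.auc}")
        if self.score < 0:
            raise ValidationError(f"negative score for {self.accession!r}: {self.score}")
        if self.unique_peptides < 0 or int(self.unique_peptides) != self.unique_peptides:
            raise ValidationError(
                f"unique_peptides must be a non-negative integer, got "
                f"{self.unique_peptides!r} for {self.accession!r}"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    """Maps a protein or transcript accession to its toxin-family label."""

    accession: str
    family: str
    is_toxin: bool

    def __post_init__(self) -> None:
        if self.is_toxin and not self.family:
            raise ValidationError(
                f"toxin accession {self.accession!r} has an empty family label"
            )


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript with RSEM-style quantification fields.

    ``tpm`` may be ``None`` when the source table lacks a TPM column; it is
    then filled by :func:`vespaquant.transcript_quant.compute_tpm`.
    """

    transcript_id: str
    length: float
    effective_length: float
    expected_count: float
    tpm: float | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.transcript_id!r}: length must be > 0")
        if self.effective_length <= 0:
            raise ValidationError(
                f"{self.transcript_id!r}: effective_length must be > 0"
            )
        if self.effective_length > self.length:
            raise ValidationError(
                f"{self.transcript_id!r}: effective_length "
                f"({self.effective_length}) exceeds length ({self.length})"
            )
        if self.expected_count < 0:
            raise ValidationError(f"{self.transcript_id!r}: negative expected_count")
        if self.tpm is not None and self.tpm < 0:
            raise ValidationError(f"{self.transcript_id!r}: negative TPM")


@dataclass(frozen=True, eq=False)
class LaneProfile:
    """A densitometric scan of one gel lane.

    ``positions`` are migration coordinates (arbitrary units, strictly
    increasing); ``intensities`` are the non-negative stain intensities
    sampled at those coordinates.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.positions.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("lane profile arrays must be one-dimensional")
        if len(self.positions) != len(self.intensities):
            raise ValidationError(
                f"positions ({len(self.positions)}) and intensities "
                f"({len(self.intensities)}) differ in length"
            )
        if len(self.positions) < 2:
            raise ValidationError("lane profile needs at least two samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LaneProfile):
            return NotImplemented
        return np.array_equal(self.positions, other.positions) and np.array_equal(
            self.intensities, other.intensities
        )


@dataclass(frozen=True)
class TableDialect:
    """Column naming and delimiter for a spectral-hit export.

    ``column_map`` maps the canonical names (band_id, accession, score,
    unique_peptides, auc, description) to the names used in the file.
    """

    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)

    def resolve(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


DEFAULT_DIALECT = TableDialect()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_read_handle(source: str | Path | IO[str]):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _as_write_handle(destination: str | Path | IO[str]):
    if isinstance(destination, (str, Path)):
        try:
            return open(destination, "w", encoding="utf-8", newline=""), True
        except OSError as exc:
            raise FormatError(f"cannot write {destination}: {exc}") from exc
    return destination, False


def _read_table(source, *, sep: str, required: Iterable[str], what: str) -> pd.DataFrame:
    handle, close = _as_read_handle(source)
    try:
        try:
            df = pd.read_csv(handle, sep=sep, dtype=str, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{what}: empty input") from exc
    finally:
        if close:
            handle.close()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {', '.join(missing)}")
    return df

def _to_float(value: str, *, what: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{what}: unparseable number {value!r} in row {row}") from exc


def _to_bool(value: str, *, what: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "t", "y"}:
        return True
    if text in {"0", "false", "no", "f", "n"}:
        return False
    raise FormatError(f"{what}: unparseable boolean {value!r} in row {row}")


# ---------------------------------------------------------------------------
# spectral hits (search-engine export)
# ---------------------------------------------------------------------------

def read_spectral_hits(
    source: str | Path | IO[str],
    dialect: TableDialect = DEFAULT_DIALECT,
) -> list[SpectralHit]:
    """Read a per-band protein identification table.

    Duplicate (band_id, accession) rows — which search exports commonly emit
    when a protein group is split across members — are merged by summing
    their AUC; the highest score and unique-peptide count are retained.
    The number of merged rows is logged at INFO level.
    """
    cols = {c: dialect.resolve(c) for c in
            ("band_id", "accession", "score", "unique_peptides", "auc", "description")}
    df = _read_table(
        source,
        sep=dialect.delimiter,
        required=[cols[c] for c in ("band_id", "accession", "score", "unique_peptides", "auc")],
        what="spectral hits",
    )
    known = set(cols.values())
    extra_cols = [c for c in df.columns if c not in known]

    merged: dict[tuple[str, str], SpectralHit] = {}
    n_merged = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        rec = dict(zip(df.columns, row))
        band = str(rec[cols["band_id"]])
        acc = str(rec[cols["accession"]])
        score = _to_float(rec[cols["score"]], what="spectral hits", row=i)
        auc = _to_float(rec[cols["auc"]], what="spectral hits", row=i)
        uniq_f = _to_float(rec[cols["unique_peptides"]], what="spectral hits", row=i)
        if score < 0 or auc < 0:
            raise ValidationError(
                f"spectral hits: negative score/auc in row {i} ({acc!r})"
            )
        if uniq_f < 0 or uniq_f != int(uniq_f):
            raise ValidationError(
                f"spectral hits: unique_peptides must be a non-negative integer "
                f"in row {i} ({acc!r})"
            )
        desc = str(rec.get(cols["description"], "") or "")
        if desc == "nan":
            desc = ""
        extra = tuple((c, rec[c]) for c in extra_cols)
        hit = SpectralHit(band, acc, score, int(uniq_f), auc, desc, extra=extra)
        key = (band, acc)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                auc=prev.auc + hit.auc,
                score=max(prev.score, hit.score),
                unique_peptides=max(prev.unique_peptides, hit.unique_peptides),
            )
            n_merged += 1
        else:
            merged[key] = hit
    if n_merged:
        logger.info("merged %d duplicate (band, accession) rows by summing AUC", n_merged)
    return list(merged.values())


def write_spectral_hits(hits: Iterable[SpectralHit], destination) -> None:
    df = pd.DataFrame(
        [
            {
                "band_id": h.band_id,
                "accession": h.accession,
                "score": h.score,
                "unique_peptides": h.unique_peptides,
                "auc": h.auc,
                "description": h.description,
            }
            for h in hits
        ],
        columns=["band_id", "accession", "score", "unique_peptides", "auc", "description"],
    )
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, index=False)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# annotation map
# ---------------------------------------------------------------------------

def read_annotation_map(source) -> dict[str, AnnotationRecord]:
    """Read a TSV of accession → (family, is_toxin).

    Exact duplicates are deduplicated silently; the same accession mapped to
    two different families is a conflict and raises ``ValidationError``.
    """
    df = _read_table(source, sep="\t", required=["accession", "family", "is_toxin"],
                     what="annotation map")
    records: dict[str, AnnotationRecord] = {}
    conflicts: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        acc = str(rec["accession"])
        new = AnnotationRecord(
            accession=acc,
            family=str(rec["family"]),
            is_toxin=_to_bool(rec["is_toxin"], what="annotation map", row=i),
        )
        old = records.get(acc)
        if old is not None and (old.family != new.family or old.is_toxin != new.is_toxin):
            conflicts.append(acc)
        records[acc] = new
    if conflicts:
        raise ValidationError(
            "annotation map: conflicting records for accession(s) "
            + ", ".join(sorted(set(conflicts)))
        )
    return records


def write_annotation_map(annotations: Mapping[str, AnnotationRecord], destination) -> None:
    df = pd.DataFrame(
        [
            {"accession": a.accession, "family": a.family, "is_toxin": a.is_toxin}
            for a in annotations.values()
        ],
        columns=["accession", "family", "is_toxin"],
    )
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# transcript quantification (RSEM-style)
# ---------------------------------------------------------------------------

def read_transcript_quant(source) -> list[TranscriptRecord]:
    """Read an RSEM-style ``.results`` table.

    Required columns: transcript_id, length, effective_length,
    expected_count.  The TPM column is optional; when absent, records carry
    ``tpm=None`` and must be completed by ``compute_tpm``.  An optional
    ``family`` column is attached verbatim.
    """
    df = _read_table(
        source, sep="\t",
        required=["transcript_id", "length", "effective_length", "expected_count"],
        what="transcript quantification",
    )
    has_tpm = "TPM" in df.columns
    has_family = "family" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        what = "transcript quantification"
        tpm = _to_float(rec["TPM"], what=what, row=i) if has_tpm else None
        family = str(rec["family"]) if has_family and not pd.isna(rec["family"]) else None
        records.append(
            TranscriptRecord(
                transcript_id=str(rec["transcript_id"]),
                length=_to_float(rec["length"], what=what, row=i),
                effective_length=_to_float(rec["effective_length"], what=what, row=i),
                expected_count=_to_float(rec["expected_count"], what=what, row=i),
                tpm=tpm,
                family=family,
            )
        )
    return records


def write_transcript_quant(records: Iterable[TranscriptRecord], destination) -> None:
    rows = []
    any_family = False
    for r in records:
        row = {
            "transcript_id": r.transcript_id,
            "length": r.length,
            "effective_length": r.effective_length,
            "expected_count": r.expected_count,
            "TPM": r.tpm,
        }
        if r.family is not None:
            any_family = True
        row["family"] = r.family
        rows.append(row)
    columns = ["transcript_id", "length", "effective_length", "expected_count", "TPM"]
    if any_family:
        columns.append("family")
    df = pd.DataFrame(rows, columns=columns)
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# lane profiles, band definitions, band areas
# ---------------------------------------------------------------------------

def read_lane_profile(source) -> LaneProfile:
    df = _read_table(source, sep="\t", required=["position", "intensity"],
                     what="lane profile")
    positions = df["position"].astype(float).to_numpy()
    intensities = df["intensity"].astype(float).to_numpy()
    return LaneProfile(positions, intensities)


def write_lane_profile(profile: LaneProfile, destination) -> None:
    df = pd.DataFrame({"position": profile.positions, "intensity": profile.intensities})
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def read_band_definitions(source) -> list:
    from .densitometry import BandDefinition  # local import to avoid a cycle

    df = _read_table(source, sep="\t", required=["band_id", "start", "end"],
                     what="band definitions")
    return [
        BandDefinition(str(r["band_id"]), float(r["start"]), float(r["end"]))
        for r in (dict(zip(df.columns, t)) for t in df.itertuples(index=False))
    ]


def write_band_definitions(bands, destination) -> None:
    df = pd.DataFrame(
        [{"band_id": b.band_id, "start": b.start, "end": b.end} for b in bands],
        columns=["band_id", "start", "end"],
    )
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def read_band_areas(source) -> dict[str, float]:
    df = _read_table(source, sep="\t", required=["band_id", "area"], what="band areas")
    areas: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        areas[str(rec["band_id"])] = _to_float(rec["area"], what="band areas", row=i)
    return areas


def write_band_areas(areas: Mapping[str, float], destination) -> None:
    df = pd.DataFrame(
        [{"band_id": k, "area": v} for k, v in areas.items()],
        columns=["band_id", "area"],
    )
    handle, close = _as_write_handle(destination)
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

def write_composition(table, destination, header_comment: str | None = None) -> None:
    """Serialise a composition table as CSV.

    Columns: the label (named after the table level), ``percent`` rounded to
    two decimals for display, and ``percent_exact`` at full precision so that
    ``read_composition(write_composition(T)) == T``.
    """
    handle, close = _as_write_handle(destination)
    try:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        handle.write(f"# level={table.level}\n")
        handle.write(f"{table.level},percent,percent_exact\n")
        for label, percent in table.entries.items():
            handle.write(f"{label},{percent:.2f},{percent!r}\n")
    finally:
        if close:
            handle.close()


def read_composition(source):
    from .abundance import CompositionTable  # local import to avoid a cycle

    handle, close = _as_read_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    level = None
    for line in text.splitlines():
        if line.startswith("# level="):
            level = line.split("=", 1)[1].strip()
    df = pd.read_csv(io.StringIO(text), comment="#", dtype=str)
    if level is None:
        # fall back to the label column name
        level = df.columns[0]
    if "percent_exact" not in df.columns:
        raise FormatError("composition table: missing required column percent_exact")
    entries = {
        str(rec[df.columns[0]]): float(rec["percent_exact"])
        for rec in (dict(zip(df.columns, t)) for t in df.itertuples(index=False))
    }
    return CompositionTable(level=level, entries=entries)
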