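"""Transcript abundance: TPM computation, validation, family aggregation.

TPM (transcripts per million) length-normalises read counts:

    tpm_i = 1e6 * (count_i / efflen_i) / sum_j (count_j / efflen_j)

so a sample's TPMs always sum to one million.  For comparison with the
venom proteome, transcript TPM is aggregated to toxin families over
toxin-annotated transcripts only — the same denominator convention as the
proteomic composition ("all toxin hits"), which makes the two percentage
scales directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .abundance import CompositionTable
from .errors import DegenerateDataError, ValidationError
from .io_formats import AnnotationRecord, TranscriptRecord

__all__ = [
    "compute_tpm",
    "validate_tpm",
    "TpmReport",
    "family_transcript_abundance",
]

TPM_TOTAL = 1_000_000.0


def compute_tpm(records: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    """Fill the ``tpm`` field from expected counts and effective lengths.

    Invariant to uniform scaling of the counts; the returned TPMs sum to
    one million up to floating-point rounding.
    """
    records = list(records)
    if not records:
        raise DegenerateDataError("no transcript records")
    rates = [r.expected_count / r.effective_length for r in records]
    total = math.fsum(rates)
    if total <= 0:
        raise DegenerateDataError("all expected counts are zero")
    return [
        replace(r, tpm=TPM_TOTAL * rate / total) for r, rate in zip(records, rates)
    ]


@dataclass(frozen=True)
class TpmReport:
    """Outcome of checking that a table's TPMs sum to one million."""

    total: float
    ok: bool
    tolerance: float
    n_records: int


def validate_tpm(
    records: Iterable[TranscriptRecord], tolerance: float = 1e-6
) -> TpmReport:
    """Check sum(TPM) ∈ 1e6 * (1 ± tolerance)."""
    records = list(records)
    missing = [r.transcript_id for r in records if r.tpm is None]
    if missing:
        raise ValidationError(
            "records without TPM: " + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    total = math.fsum(r.tpm for r in records)
    ok = abs(total - TPM_TOTAL) <= tolerance * TPM_TOTAL
    return TpmReport(total=total, ok=ok, tolerance=tolerance, n_records=len(records))


def family_transcript_abundance(
    records: Iterable[TranscriptRecord],
    annotations: Mapping[str, AnnotationRecord],
) -> CompositionTable:
    """Family-level transcriptome composition over toxin transcripts.

    percent(family) = 100 * sum TPM of the family's toxin transcripts
    divided by the total TPM of all toxin-annotated transcripts.
    Transcripts that are unannotated or annotated non-toxin are excluded
    from numerator and denominator alike.
    """
    totals: dict[str, list[float]] = {}
    n_hits: dict[str, int] = {}
    for r in records:
        ann = annotations.get(r.transcript_id)
        if ann is None or not ann.is_toxin:
            continue
        if r.tpm is None:
            raise ValidationError(f"{r.transcript_id!r}: TPM not computed")
        totals.setdefault(ann.family, []).append(r.tpm)
        n_hits[ann.family] = n_hits.get(ann.family, 0) + 1
    grand = math.fsum(v for vals in totals.values() for v in vals)
    if not totals or grand <= 0:
        raise DegenerateDataError("no toxin-annotated transcripts with positive TPM")
    entries = {fam: 100.0 * math.fsum(vals) / grand for fam, vals in totals.items()}
    prov = {fam: {"bands": 0, "hits": n} for fam, n in n_hits.items()}
    return CompositionTable(level="family", entries=entries, provenance=prov)
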