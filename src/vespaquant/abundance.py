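"""Band-proportion-weighted relative spectral abundance.

The composition statistic: for toxin X identified across gel bands
B1..BN with densitometric proportions p_n,

    percent(X) = 100 * sum_n [ AUC(X in B_n) / total toxin AUC in B_n ] * p_n

i.e. each band's toxin AUCs are normalised within the band, then weighted
by the band's share of the lane and summed.  Because every band's fractions
sum to one, the composition sums to 100% exactly whenever every analysed
band contributes at least one toxin hit.  Bands with positive proportion
but no toxin identification are handled by policy: either the remaining
proportions are renormalised (default, keeps the total at 100%) or an
error is raised for auditing.

Family-level aggregation sums member percentages under an annotation map;
the translation index divides a family's proteome percentage by its
venom-gland transcriptome percentage, so values above one indicate
preferential translation of that family's transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .densitometry import BandProportionTable
from .errors import DataPolicyError, DegenerateDataError, ValidationError
from .io_formats import AnnotationRecord, SpectralHit

__all__ = [
    "CompositionTable",
    "TranslationIndexEntry",
    "TranslationIndexTable",
    "band_relative_auc",
    "relative_abundance",
    "aggregate_families",
    "translation_index",
]


@dataclass(frozen=True)
class CompositionTable:
    """Relative abundance percentages at protein or family level.

    ``entries`` maps a label (accession or family) to its percent of the
    composition; ``provenance`` optionally records how many bands and hits
    contributed to each label.  Percentages are kept at full precision;
    rounding to two decimals happens only at display/serialisation time,
    with no post-rounding renormalisation.
    """

    level: str
    entries: dict[str, float]
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("protein", "family"):
            raise ValidationError(f"unknown composition level {self.level!r}")
        for label, pct in self.entries.items():
            if pct < 0:
                raise ValidationError(f"{label!r}: negative percent {pct}")

    @property
    def total(self) -> float:
        return math.fsum(self.entries.values())

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.entries.items()}


def band_relative_auc(hits: Iterable[SpectralHit]) -> dict[str, float]:
    """Within-band AUC fractions: auc(X) / total toxin AUC in the band.

    All hits must share one band and must already be contaminant-free.
    """
    hits = list(hits)
    if not hits:
        raise DegenerateDataError("no hits in band")
    bands = {h.band_id for h in hits}
    if len(bands) != 1:
        raise ValidationError(f"hits span multiple bands: {sorted(bands)}")
    if any(h.is_contaminant for h in hits):
        raise ValidationError("contaminant hit passed to band_relative_auc")
    total = math.fsum(h.auc for h in hits)
    if total <= 0:
        raise DegenerateDataError(
            f"band {next(iter(bands))!r}: total toxin AUC is zero"
        )
    return {h.accession: h.auc / total for h in hits}


def relative_abundance(
    hits: Iterable[SpectralHit],
    proportions: BandProportionTable,
    zero_band_policy: str = "renormalise",
) -> CompositionTable:
    """Protein-level composition from filtered toxin hits and band weights.

    ``hits`` must be the quality-filtered, contaminant-free, toxin-only
    identifications; every band they reference must appear in
    ``proportions``.  Under the default ``renormalise`` policy, analysed
    bands without any toxin hit have their proportion redistributed over
    the toxin-bearing bands so the output still sums to 100%; under
    ``error`` such a band aborts the computation.
    """
    if zero_band_policy not in ("renormalise", "error"):
        raise ValidationError(f"unknown zero_band_policy {zero_band_policy!r}")
    by_band: dict[str, list[SpectralHit]] = {}
    for h in hits:
        by_band.setdefault(h.band_id, []).append(h)
    if not by_band:
        raise DegenerateDataError("no toxin hits to quantify")
    missing = sorted(set(by_band) - set(proportions.entries))
    if missing:
        raise ValidationError(
            "band(s) present in hits but absent from the proportion table: "
            + ", ".join(missing)
        )

    empty = [
        b for b, e in proportions.entries.items()
        if e.proportion > 0 and b not in by_band
    ]
    if empty and zero_band_policy == "error":
        raise DataPolicyError(
            "band(s) with positive proportion but no toxin hits: "
            + ", ".join(sorted(empty))
        )
    weight_total = math.fsum(
        e.proportion for b, e in proportions.entries.items() if b in by_band
    )
    if weight_total <= 0:
        raise DegenerateDataError("toxin-bearing bands carry zero total proportion")

    percents: dict[str, float] = {}
    prov: dict[str, dict[str, int]] = {}
    for band_id in sorted(by_band):
        weight = proportions.entries[band_id].proportion / weight_total
        fractions = band_relative_auc(by_band[band_id])
        for acc, frac in fractions.items():
            percents[acc] = percents.get(acc, 0.0) + 100.0 * frac * weight
            p = prov.setdefault(acc, {"bands": 0, "hits": 0})
            p["bands"] += 1
            p["hits"] += 1
    return CompositionTable(level="protein", entries=percents, provenance=prov)


def aggregate_families(
    table: CompositionTable, annotations: Mapping[str, AnnotationRecord]
) -> CompositionTable:
    """Sum protein percentages into toxin-family percentages.

    Every protein label must be annotated; the family total equals the
    protein total (aggregation only reorders the summation).
    """
    unannotated = sorted(acc for acc in table.entries if acc not in annotations)
    if unannotated:
        raise ValidationError(
            "unannotated accession(s): " + ", ".join(unannotated)
        )
    members: dict[str, list[float]] = {}
    prov: dict[str, dict[str, int]] = {}
    for acc, pct in table.entries.items():
        family = annotations[acc].family
        members.setdefault(family, []).append(pct)
        p = prov.setdefault(family, {"bands": 0, "hits": 0})
        src = table.provenance.get(acc, {})
        p["bands"] += src.get("bands", 0)
        p["hits"] += src.get("hits", 0)
    entries = {fam: math.fsum(vals) for fam, vals in members.items()}
    return CompositionTable(level="family", entries=entries, provenance=prov)


@dataclass(frozen=True)
class TranslationIndexEntry:
    proteome_percent: float
    transcriptome_percent: float
    index: float
    defined: bool


@dataclass(frozen=True)
class TranslationIndexTable:
    """Per-family proteome/transcriptome percentage ratio.

    ``defined`` is False exactly when the family is absent from (or zero
    in) the transcriptome side, in which case ``index`` is NaN.
    """

    entries: dict[str, TranslationIndexEntry]


def translation_index(
    proteome: CompositionTable, transcriptome: CompositionTable
) -> TranslationIndexTable:
    """Fold-difference between translated and transcribed family shares."""
    if proteome.level != "family" or transcriptome.level != "family":
        raise ValidationError("translation_index requires family-level tables")
    families = sorted(set(proteome.entries) | set(transcriptome.entries))
    entries = {}
    for fam in families:
        p = proteome.entries.get(fam, 0.0)
        t = transcriptome.entries.get(fam, 0.0)
        if t > 0:
            entries[fam] = TranslationIndexEntry(p, t, p / t, defined=True)
        else:
            entries[fam] = TranslationIndexEntry(p, t, float("nan"), defined=False)
    return TranslationIndexTable(entries)
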