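"""Identification quality filters and contaminant exclusion.

Protein identifications from the database search are retained only when
they reach a -10*log10(p) score of at least 50 and at least one unique
peptide, and are not contaminants (cRAP-style entries matched by accession
or prefix).  The FDR of the search itself is a search-engine setting, not a
column of the export; a standard target-decoy estimator is provided so that
the FDR regime can be verified on simulated data carrying planted decoys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import SpectralHit

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "apply_quality_filters",
    "flag_contaminants",
    "estimate_decoy_fdr",
    "FdrEstimate",
]

#: Accession prefixes conventionally marking contaminant and decoy entries.
DEFAULT_CONTAMINANT_PREFIXES = ("CRAP_", "CON_", "DECOY_")


@dataclass(frozen=True)
class FilterConfig:
    """Quality thresholds applied to spectral hits before quantification.

    All thresholds are inclusive: a hit with score exactly ``min_score`` or
    exactly ``min_unique_peptides`` unique peptides is retained.
    """

    min_score: float = 50.0
    min_unique_peptides: int = 1
    max_fdr: float = 0.001
    contaminant_prefixes: Sequence[str] = field(default=DEFAULT_CONTAMINANT_PREFIXES)

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if not 0 <= self.max_fdr <= 1:
            raise ValueError("max_fdr must lie in [0, 1]")
        if self.min_unique_peptides < 0:
            raise ValueError("min_unique_peptides must be >= 0")


def flag_contaminants(
    hits: Iterable[SpectralHit],
    contaminant_accessions: Iterable[str] = (),
    prefixes: Sequence[str] = (),
) -> list[SpectralHit]:
    """Return hits with ``is_contaminant`` set where the accession matches.

    A hit is flagged when its accession is in ``contaminant_accessions``
    exactly or starts with any of ``prefixes``.  All other fields are
    unchanged; hits already flagged stay flagged.
    """
    exact = set(contaminant_accessions)
    out = []
    for h in hits:
        flagged = h.is_contaminant or h.accession in exact or any(
            h.accession.startswith(p) for p in prefixes
        )
        out.append(replace(h, is_contaminant=flagged) if flagged != h.is_contaminant else h)
    return out


def apply_quality_filters(
    hits: Iterable[SpectralHit], config: FilterConfig = FilterConfig()
) -> list[SpectralHit]:
    """Apply score, unique-peptide and contaminant filters.

    Contaminants are recognised either from an already-set ``is_contaminant``
    flag or from the config's accession prefixes.  Removal counts per
    criterion are logged.  Filtering is idempotent and order-independent.
    """
    kept = []
    n_score = n_unique = n_contam = 0
    for h in hits:
        if h.is_contaminant or any(
            h.accession.startswith(p) for p in config.contaminant_prefixes
        ):
            n_contam += 1
            continue
        if h.score < config.min_score:
            n_score += 1
            continue
        if h.unique_peptides < config.min_unique_peptides:
            n_unique += 1
            continue
        kept.append(h)
    logger.info(
        "quality filters: kept %d, removed %d contaminant, %d low-score, %d low-unique",
        len(kept), n_contam, n_score, n_unique,
    )
    return kept


@dataclass(frozen=True)
class FdrEstimate:
    """Target-decoy FDR estimate at a score threshold.

    ``defined`` is False when no target passes the threshold, in which case
    ``fdr`` is NaN rather than a ratio over zero.
    """

    fdr: float
    n_targets: int
    n_decoys: int
    defined: bool


def estimate_decoy_fdr(
    hits: Iterable[SpectralHit],
    decoy_prefix: str = "DECOY_",
    score_threshold: float = 50.0,
) -> FdrEstimate:
    """Standard target-decoy estimate: #decoys / #targets above threshold."""
    n_targets = n_decoys = 0
    for h in hits:
        if h.score < score_threshold:
            continue
        if h.accession.startswith(decoy_prefix):
            n_decoys += 1
        else:
            n_targets += 1
    if n_targets == 0:
        if n_decoys == 0:
            return FdrEstimate(0.0, 0, 0, defined=True)
        return FdrEstimate(float("nan"), 0, n_decoys, defined=False)
    return FdrEstimate(n_decoys / n_targets, n_targets, n_decoys, defined=True)
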