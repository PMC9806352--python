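"""Seed-deterministic synthetic venom-profiling datasets with known truth.

The generator emulates the full input set of the pipeline — a per-band
spectral-hit export, a lane densitometry profile with band definitions and
analytic band areas, an RSEM-style transcript quantification and a
toxin-family annotation map — from a planted ground truth:

* each toxin family holds a share of a true proteome composition pi
  (a simplex over families), split among its member proteins;
* each protein migrates to a lane position linear in log10 of its
  molecular weight (descending, as on an SDS-PAGE gel) and contributes a
  Gaussian peak whose area is its true mass share; bands are drawn around
  clusters of neighbouring peaks;
* a protein's spectral AUC in its band is its within-band mass share times
  the band area, perturbed by multiplicative log-normal noise;
* identification scores are drawn from a high distribution for true hits
  and a low (null) one for planted decoys, so the standard quality filters
  are exercised realistically; contaminants carry a ``CRAP_`` accession
  prefix and decoys ``DECOY_``;
* transcript TPM for family f is proportional to pi_f divided by the
  family's translation efficiency tau_f (the proteome/transcriptome fold),
  with per-transcript log-normal dispersion, renormalised to one million.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the one truth seed, with a fixed draw order (families, then proteins,
then bands, then transcripts), so regenerating with the same truth yields
a byte-identical dataset.

Note that because family percentages are compositional (they are forced to
sum to 100% on both sides), the realised translation index of family f is
tau_f * sum_g(pi_g / tau_g), not tau_f itself; the two coincide as the
perturbed families' total share approaches zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .densitometry import BandDefinition
from .errors import ValidationError, VespaQuantError
from .io_formats import (
    AnnotationRecord,
    LaneProfile,
    SpectralHit,
    TranscriptRecord,
    read_annotation_map,
    read_band_areas,
    read_band_definitions,
    read_lane_profile,
    read_spectral_hits,
    read_transcript_quant,
    write_annotation_map,
    write_band_areas,
    write_band_definitions,
    write_lane_profile,
    write_spectral_hits,
    write_transcript_quant,
)

__all__ = [
    "HORNET_PROTEOME_PERCENTS",
    "HORNET_TRANSLATION_EFFICIENCY",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_truth",
    "simulate",
    "write_dataset",
    "load_dataset",
]


#: Family-level venom proteome of a south-Asian hornet (percent of toxin
#: proteome), used as the default planted composition.
HORNET_PROTEOME_PERCENTS: dict[str, float] = {
    "CAP": 26.09,
    "PLA1": 21.86,
    "trypsin": 18.95,
    "hyaluronidase": 15.20,
    "DPP": 6.87,
    "LAAO": 6.79,
    "serine_protease": 1.91,
    "aminopeptidase": 0.93,
    "carboxypeptidase": 0.58,
    "PLA2_inhibitor": 0.45,
    "PLA2": 0.17,
    "chitinase": 0.11,
    "chymotrypsin": 0.08,
    "peroxiredoxin": 0.02,
}

#: Default proteome/transcriptome fold (translation efficiency tau) per
#: family: strongly over-translated CAP and DPP, mildly over-translated
#: hyaluronidase, near-parity phospholipase A1, parity elsewhere —
#: the qualitative venom-gland pattern of vespid wasps.
HORNET_TRANSLATION_EFFICIENCY: dict[str, float] = {
    "CAP": 9.0,
    "DPP": 3.0,
    "hyaluronidase": 2.0,
    "PLA1": 0.85,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth and noise model for one synthetic dataset.

    ``families`` maps family label to its true proteome share (fractions
    summing to one); ``translation_efficiency`` the per-family
    proteome/transcriptome fold (families absent from the map get 1.0).
    ``noise_sd_log`` is the standard deviation of the multiplicative
    log-normal noise applied to spectral AUCs and transcript TPMs.
    """

    families: dict[str, float]
    proteins_per_family: int = 2
    transcripts_per_family: int = 4
    translation_efficiency: dict[str, float] = field(default_factory=dict)
    noise_sd_log: float = 0.2
    n_contaminants: int = 4
    n_decoys: int = 30
    mw_range: tuple[float, float] = (10.0, 100.0)
    nontoxin_tpm_fraction: float = 0.35
    n_nontoxin_transcripts: int = 10
    seed: int = 0
    # lane geometry (configuration, not science)
    lane_length: float = 100.0
    lane_margin: float = 8.0
    peak_sd: float = 1.0
    lane_samples: int = 2001
    lane_scale: float = 1_000_000.0
    # score model: true hits vs decoys
    true_score_mean: float = 85.0
    true_score_sd: float = 8.0
    decoy_score_mean: float = 25.0
    decoy_score_sd: float = 10.0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValidationError("truth must define at least one family")
        for fam, share in self.families.items():
            if share < 0:
                raise ValidationError(f"family {fam!r}: negative share {share}")
        total = math.fsum(self.families.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"family shares must sum to 1 (got {total!r}); "
                "use default_truth() or normalise first"
            )
        for fam, tau in self.translation_efficiency.items():
            if tau <= 0:
                raise ValidationError(
                    f"translation efficiency for {fam!r} must be > 0, got {tau}"
                )
        if self.noise_sd_log < 0:
            raise ValidationError("noise_sd_log must be >= 0")
        if self.proteins_per_family < 1 or self.transcripts_per_family < 1:
            raise ValidationError("need at least one protein and transcript per family")
        lo, hi = self.mw_range
        if not 0 < lo < hi:
            raise ValidationError(f"invalid mw_range {self.mw_range}")
        if not 0 <= self.nontoxin_tpm_fraction < 1:
            raise ValidationError("nontoxin_tpm_fraction must lie in [0, 1)")

    def tau(self, family: str) -> float:
        return self.translation_efficiency.get(family, 1.0)


def default_truth(n_families: int = 14, **overrides) -> SyntheticTruth:
    """Hornet-venom-like truth over the ``n_families`` most abundant families.

    Shares are taken from :data:`HORNET_PROTEOME_PERCENTS`, truncated to the
    top ``n_families`` and renormalised to one.  Keyword overrides are passed
    through to :class:`SyntheticTruth`.
    """
    items = list(HORNET_PROTEOME_PERCENTS.items())[:n_families]
    if len(items) < n_families:
        raise ValidationError(
            f"at most {len(HORNET_PROTEOME_PERCENTS)} default families available"
        )
    total = math.fsum(v for _, v in items)
    families = {k: v / total for k, v in items}
    overrides.setdefault(
        "translation_efficiency",
        {k: v for k, v in HORNET_TRANSLATION_EFFICIENCY.items() if k in families},
    )
    return SyntheticTruth(families=families, **overrides)


@dataclass(frozen=True)
class _ProteinTruth:
    accession: str
    family: str
    mass_share: float
    mw_kda: float
    position: float
    band_id: str


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic input set plus the truth that generated it.

    ``band_areas`` are the analytic (noise-free) band areas implied by the
    planted mass shares; ``lane`` is the sampled densitometry profile of
    the same signal.  ``planted`` records bookkeeping counts, notably
    ``n_pass_default_filters`` — the number of hits that satisfy the
    default quality thresholds, computed at generation time.
    """

    hits: list[SpectralHit]
    lane: LaneProfile
    bands: list[BandDefinition]
    band_areas: dict[str, float]
    quant: list[TranscriptRecord]
    annotations: dict[str, AnnotationRecord]
    truth: SyntheticTruth
    proteins: list[_ProteinTruth]
    planted: dict[str, int]


def _assign_bands(
    positions: list[float], truth: SyntheticTruth
) -> tuple[list[BandDefinition], list[int]]:
    """Cluster sorted peak positions into disjoint bands.

    Peaks closer than four peak widths share a band; band edges extend 3.5
    widths beyond the outermost peaks, meeting halfway inside narrow gaps.
    Returns bands in migration order and, per input peak, its band index.
    """
    order = np.argsort(positions, kind="stable")
    ext = 3.5 * truth.peak_sd
    gap = 4.0 * truth.peak_sd
    clusters: list[list[int]] = []
    for idx in order:
        if clusters and positions[idx] - positions[clusters[-1][-1]] <= gap:
            clusters[-1].append(int(idx))
        else:
            clusters.append([int(idx)])
    bands: list[BandDefinition] = []
    assignment = [0] * len(positions)
    starts, ends = [], []
    for ci, members in enumerate(clusters):
        lo = positions[members[0]] - ext
        hi = positions[members[-1]] + ext
        starts.append(lo)
        ends.append(hi)
    # resolve overlaps between extended neighbours at the gap midpoint
    for ci in range(len(clusters) - 1):
        if ends[ci] > starts[ci + 1]:
            mid = 0.5 * (
                positions[clusters[ci][-1]] + positions[clusters[ci + 1][0]]
            )
            ends[ci] = mid
            starts[ci + 1] = mid
    for ci, members in enumerate(clusters):
        band_id = f"B{ci + 1:02d}"
        start = max(0.0, starts[ci])
        end = min(truth.lane_length, ends[ci])
        bands.append(BandDefinition(band_id, start, end))
        for m in members:
            assignment[m] = ci
    return bands, assignment


def simulate(truth: SyntheticTruth) -> SyntheticDataset:
    """Generate a full dataset from the planted truth (deterministic)."""
    rng = np.random.default_rng(truth.seed)
    families = list(truth.families)
    k = truth.proteins_per_family
    log_lo, log_hi = (math.log10(v) for v in truth.mw_range)

    # --- proteins: mass shares within family, molecular weights ---
    accessions: list[str] = []
    fam_of: list[str] = []
    shares: list[float] = []
    mws: list[float] = []
    for fam in families:
        split = rng.dirichlet(np.full(k, 2.0))
        log_mw = rng.uniform(log_lo, log_hi, size=k)
        for j in range(k):
            accessions.append(f"{fam}_p{j + 1}")
            fam_of.append(fam)
            shares.append(truth.families[fam] * float(split[j]))
            mws.append(10.0 ** float(log_mw[j]))

    # --- migration positions: linear in log10(MW), descending ---
    usable = truth.lane_length - 2 * truth.lane_margin
    positions = [
        truth.lane_margin + usable * (log_hi - math.log10(mw)) / (log_hi - log_lo)
        for mw in mws
    ]

    bands, band_index = _assign_bands(positions, truth)
    proteins = [
        _ProteinTruth(
            accession=accessions[i],
            family=fam_of[i],
            mass_share=shares[i],
            mw_kda=mws[i],
            position=positions[i],
            band_id=bands[band_index[i]].band_id,
        )
        for i in range(len(accessions))
    ]

    # --- analytic band areas and the sampled lane profile ---
    band_share = {b.band_id: 0.0 for b in bands}
    for p in proteins:
        band_share[p.band_id] += p.mass_share
    band_areas = {bid: truth.lane_scale * s for bid, s in band_share.items()}

    x = np.linspace(0.0, truth.lane_length, truth.lane_samples)
    intensity = np.zeros_like(x)
    norm = 1.0 / (truth.peak_sd * math.sqrt(2.0 * math.pi))
    for p in proteins:
        intensity += (
            p.mass_share
            * truth.lane_scale
            * norm
            * np.exp(-0.5 * ((x - p.position) / truth.peak_sd) ** 2)
        )
    lane = LaneProfile(x, intensity)

    # --- spectral hits: true proteins, then contaminants, then decoys ---
    hits: list[SpectralHit] = []
    for bi, band in enumerate(bands):
        members = [p for p in proteins if p.band_id == band.band_id]
        members.sort(key=lambda p: p.position)
        total_share = band_share[band.band_id]
        for p in members:
            noise = math.exp(float(rng.normal(0.0, truth.noise_sd_log)))
            auc = (p.mass_share / total_share) * band_areas[band.band_id] * noise
            score = max(0.0, float(rng.normal(truth.true_score_mean, truth.true_score_sd)))
            unique = 1 + int(rng.poisson(4.0))
            hits.append(
                SpectralHit(
                    band_id=band.band_id,
                    accession=p.accession,
                    score=score,
                    unique_peptides=unique,
                    auc=auc,
                    description=f"{p.family} toxin, {p.mw_kda:.1f} kDa",
                )
            )
    for i in range(truth.n_contaminants):
        band = bands[int(rng.integers(len(bands)))]
        auc = band_areas[band.band_id] * 0.05 * math.exp(float(rng.normal(0.0, 0.5)))
        score = max(0.0, float(rng.normal(75.0, 10.0)))
        unique = 1 + int(rng.poisson(2.0))
        hits.append(
            SpectralHit(
                band_id=band.band_id,
                accession=f"CRAP_C{i + 1}",
                score=score,
                unique_peptides=unique,
                auc=auc,
                description="adventitious contaminant",
            )
        )
    for i in range(truth.n_decoys):
        band = bands[int(rng.integers(len(bands)))]
        auc = band_areas[band.band_id] * 0.01 * math.exp(float(rng.normal(0.0, 0.5)))
        score = max(0.0, float(rng.normal(truth.decoy_score_mean, truth.decoy_score_sd)))
        hits.append(
            SpectralHit(
                band_id=band.band_id,
                accession=f"DECOY_D{i + 1}",
                score=score,
                unique_peptides=1,
                auc=auc,
                description="reversed-sequence decoy",
            )
        )

    # bookkeeping: which hits satisfy the default quality regime, counted
    # directly from the planted values (independent of spectral_filter)
    n_pass = sum(
        1
        for h in hits
        if not h.accession.startswith(("CRAP_", "DECOY_"))
        and h.score >= 50.0
        and h.unique_peptides >= 1
    )

    # --- transcripts: family TPM ~ pi/tau with per-transcript dispersion ---
    kt = truth.transcripts_per_family
    t_ids: list[str] = []
    t_family: list[str | None] = []
    t_raw: list[float] = []
    t_len: list[int] = []
    for fam in families:
        raw_f = truth.families[fam] / truth.tau(fam)
        split = rng.dirichlet(np.full(kt, 2.0))
        noise = np.exp(rng.normal(0.0, truth.noise_sd_log, size=kt))
        lengths = rng.integers(300, 3001, size=kt)
        for j in range(kt):
            t_ids.append(f"{fam}_t{j + 1}")
            t_family.append(fam)
            t_raw.append(raw_f * float(split[j]) * float(noise[j]))
            t_len.append(int(lengths[j]))
    toxin_raw_total = math.fsum(t_raw)
    nf = truth.nontoxin_tpm_fraction
    if nf > 0 and truth.n_nontoxin_transcripts > 0:
        nt_total = toxin_raw_total * nf / (1.0 - nf)
        split = rng.dirichlet(np.full(truth.n_nontoxin_transcripts, 2.0))
        lengths = rng.integers(300, 3001, size=truth.n_nontoxin_transcripts)
        for j in range(truth.n_nontoxin_transcripts):
            t_ids.append(f"NT_t{j + 1}")
            t_family.append("housekeeping")
            t_raw.append(nt_total * float(split[j]))
            t_len.append(int(lengths[j]))
    raw_total = math.fsum(t_raw)
    tpms = [1_000_000.0 * r / raw_total for r in t_raw]
    efflens = [L - 150 for L in t_len]
    weights = [tpm * el for tpm, el in zip(tpms, efflens)]
    w_total = math.fsum(weights)
    total_reads = 2.0e7
    counts = [round(total_reads * w / w_total, 2) for w in weights]
    quant = [
        TranscriptRecord(
            transcript_id=t_ids[i],
            length=float(t_len[i]),
            effective_length=float(efflens[i]),
            expected_count=counts[i],
            tpm=tpms[i],
            family=t_family[i],
        )
        for i in range(len(t_ids))
    ]

    # --- annotation map over every accession the dataset mentions ---
    annotations: dict[str, AnnotationRecord] = {}
    for p in proteins:
        annotations[p.accession] = AnnotationRecord(p.accession, p.family, True)
    for i in range(truth.n_contaminants):
        acc = f"CRAP_C{i + 1}"
        annotations[acc] = AnnotationRecord(acc, "contaminant", False)
    for i in range(truth.n_decoys):
        acc = f"DECOY_D{i + 1}"
        annotations[acc] = AnnotationRecord(acc, "decoy", False)
    for tid, fam in zip(t_ids, t_family):
        annotations[tid] = AnnotationRecord(tid, fam, fam != "housekeeping")

    planted = {
        "n_hits": len(hits),
        "n_true_hits": len(proteins),
        "n_contaminants": truth.n_contaminants,
        "n_decoys": truth.n_decoys,
        "n_pass_default_filters": n_pass,
        "n_bands": len(bands),
    }
    return SyntheticDataset(
        hits=hits,
        lane=lane,
        bands=bands,
        band_areas=band_areas,
        quant=quant,
        annotations=annotations,
        truth=truth,
        proteins=proteins,
        planted=planted,
    )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_FILES = {
    "hits": "hits.csv",
    "lane": "lane_profile.tsv",
    "bands": "bands.tsv",
    "band_areas": "band_areas.tsv",
    "quant": "quant.tsv",
    "annotations": "annotations.tsv",
    "truth": "truth.json",
}


def write_dataset(ds: SyntheticDataset, directory: str | Path, force: bool = False) -> None:
    """Write every table in its pipeline dialect plus ``truth.json``.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise VespaQuantError(
            f"refusing to write into non-empty directory {directory} (use force)"
        )
    directory.mkdir(parents=True, exist_ok=True)
    write_spectral_hits(ds.hits, directory / _FILES["hits"])
    write_lane_profile(ds.lane, directory / _FILES["lane"])
    write_band_definitions(ds.bands, directory / _FILES["bands"])
    write_band_areas(ds.band_areas, directory / _FILES["band_areas"])
    write_transcript_quant(ds.quant, directory / _FILES["quant"])
    write_annotation_map(ds.annotations, directory / _FILES["annotations"])
    payload = {
        "truth": dataclasses.asdict(ds.truth),
        "planted": ds.planted,
        "proteins": [dataclasses.asdict(p) for p in ds.proteins],
    }
    (directory / _FILES["truth"]).write_text(
        json.dumps(payload, indent=1), encoding="utf-8"
    )


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset` back into memory."""
    directory = Path(directory)
    payload = json.loads((directory / _FILES["truth"]).read_text(encoding="utf-8"))
    truth_kwargs = dict(payload["truth"])
    truth_kwargs["mw_range"] = tuple(truth_kwargs["mw_range"])
    truth = SyntheticTruth(**truth_kwargs)
    return SyntheticDataset(
        hits=read_spectral_hits(directory / _FILES["hits"]),
        lane=read_lane_profile(directory / _FILES["lane"]),
        bands=read_band_definitions(directory / _FILES["bands"]),
        band_areas=read_band_areas(directory / _FILES["band_areas"]),
        quant=read_transcript_quant(directory / _FILES["quant"]),
        annotations=read_annotation_map(directory / _FILES["annotations"]),
        truth=truth,
        proteins=[_ProteinTruth(**p) for p in payload["proteins"]],
        planted=dict(payload["planted"]),
    )
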