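"""End-to-end runs: quantify, compare, assay.

These functions are the library form of the CLI subcommands: they read the
input tables, drive the filtering/densitometry/abundance modules, and
write composition CSVs plus a machine-readable JSON summary.  Every output
file begins with a comment header embedding the tool version and a hash of
the effective configuration, so identical inputs and configuration yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import (
    TranslationIndexTable,
    aggregate_families,
    relative_abundance,
    translation_index,
)
from .assay_math import (
    AssayMeasurement,
    ClottingResult,
    StandardCurve,
    clotting_delay,
    relative_haemolysis,
    specific_activity_from_curve,
    turbidity_reduction_units,
)
from .densitometry import integrate_bands, proportions_from_areas, subtract_baseline
from .errors import FormatError, ValidationError
from .io_formats import (
    read_annotation_map,
    read_band_areas,
    read_band_definitions,
    read_composition,
    read_lane_profile,
    read_spectral_hits,
    read_transcript_quant,
    write_composition,
)
from .spectral_filter import FilterConfig, apply_quality_filters, flag_contaminants
from .transcript_quant import compute_tpm, family_transcript_abundance, validate_tpm

logger = logging.getLogger(__name__)

__all__ = ["QuantifyConfig", "run_quantify", "run_compare", "run_assay"]


def _config_hash(obj) -> str:
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def _header(config_obj) -> str:
    return f"vespaquant {__version__} config_hash={_config_hash(config_obj)}"


@dataclass(frozen=True)
class QuantifyConfig:
    """Effective configuration of one quantification run."""

    hits: str
    annotations: str
    profile: str | None = None
    bands: str | None = None
    band_areas: str | None = None
    out_dir: str = "."
    zero_band_policy: str = "renormalise"
    filters: FilterConfig = field(default_factory=FilterConfig)
    skip_baseline: bool = False

    def __post_init__(self) -> None:
        has_profile = self.profile is not None and self.bands is not None
        has_areas = self.band_areas is not None
        if has_profile == has_areas:
            raise ValidationError(
                "provide either a lane profile with band definitions or a "
                "band-area table, not both"
            )


def run_quantify(config: QuantifyConfig) -> dict:
    """Quantify a venom proteome from a spectral-hit export.

    Writes ``composition_protein.csv``, ``composition_family.csv``,
    ``chart_family.csv`` (label, rounded percent — doughnut-chart data)
    and ``summary.json`` into the output directory; returns the summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    header = _header(cfg_dict)

    raw_hits = read_spectral_hits(config.hits)
    annotations = read_annotation_map(config.annotations)

    flagged = flag_contaminants(raw_hits, prefixes=config.filters.contaminant_prefixes)
    passed = apply_quality_filters(flagged, config.filters)
    toxin_hits = []
    n_nontoxin = 0
    unannotated: list[str] = []
    for h in passed:
        ann = annotations.get(h.accession)
        if ann is None:
            unannotated.append(h.accession)
        elif ann.is_toxin:
            toxin_hits.append(h)
        else:
            n_nontoxin += 1
    if unannotated:
        raise ValidationError(
            "unannotated accession(s) in filtered hits: "
            + ", ".join(sorted(unannotated))
        )

    if config.band_areas is not None:
        proportions = proportions_from_areas(read_band_areas(config.band_areas))
    else:
        profile = read_lane_profile(config.profile)
        bands = read_band_definitions(config.bands)
        if not config.skip_baseline:
            profile = subtract_baseline(profile, bands)
        proportions = integrate_bands(profile, bands)

    protein_table = relative_abundance(
        toxin_hits, proportions, zero_band_policy=config.zero_band_policy
    )
    family_table = aggregate_families(protein_table, annotations)

    write_composition(protein_table, out / "composition_protein.csv", header)
    write_composition(family_table, out / "composition_family.csv", header)
    with open(out / "chart_family.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\nlabel,percent\n")
        for label, pct in sorted(
            family_table.entries.items(), key=lambda kv: -kv[1]
        ):
            fh.write(f"{label},{pct:.2f}\n")

    summary = {
        "tool": "vespaquant",
        "version": __version__,
        "config_hash": _config_hash(cfg_dict),
        "config": cfg_dict,
        "n_hits_raw": len(raw_hits),
        "n_hits_filtered": len(passed),
        "n_hits_toxin": len(toxin_hits),
        "n_hits_nontoxin": n_nontoxin,
        "n_hits_removed": len(raw_hits) - len(passed),
        "bands_analysed": sorted(proportions.entries),
        "zero_band_policy": config.zero_band_policy,
        "total_percent_protein": protein_table.total,
        "total_percent_family": family_table.total,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
    )
    return summary


def run_compare(
    proteome_csv: str,
    quant_tsv: str,
    annotations_tsv: str,
    out_path: str,
) -> TranslationIndexTable:
    """Compare a proteome composition with the venom-gland transcriptome.

    Reads a family-level composition CSV (as written by ``run_quantify``),
    computes or validates TPM on the transcript table, aggregates it to
    toxin families, and writes per-family proteome %, transcriptome %,
    translation index and a defined flag.
    """
    proteome = read_composition(proteome_csv)
    if proteome.level != "family":
        raise ValidationError(
            f"compare requires a family-level composition, got {proteome.level!r}"
        )
    records = read_transcript_quant(quant_tsv)
    if any(r.tpm is None for r in records):
        records = compute_tpm(records)
    else:
        report = validate_tpm(records, tolerance=1e-3)
        if not report.ok:
            logger.warning(
                "input TPM sums to %.1f, not 1e6; recomputing from counts",
                report.total,
            )
            records = compute_tpm(records)
    annotations = read_annotation_map(annotations_tsv)
    transcriptome = family_transcript_abundance(records, annotations)

    shared = set(proteome.entries) & set(transcriptome.entries)
    if not shared:
        logger.warning("proteome and transcriptome share no family labels")

    table = translation_index(proteome, transcriptome)
    cfg = {"proteome": proteome_csv, "quant": quant_tsv, "annotations": annotations_tsv}
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_header(cfg)}\n")
        fh.write("family,proteome_percent,transcriptome_percent,index,defined\n")
        for fam, e in table.entries.items():
            idx = repr(e.index) if e.defined else "NA"
            fh.write(
                f"{fam},{e.proteome_percent!r},{e.transcriptome_percent!r},"
                f"{idx},{e.defined}\n"
            )
    return table


_ASSAY_TYPES = ("hyaluronidase", "phospholipase", "haemolysis", "coagulation")


def _require_roles(df: pd.DataFrame, roles: list[str], assay: str) -> None:
    present = set(df["role"])
    missing = [r for r in roles if r not in present]
    if missing:
        raise FormatError(f"{assay} assay: missing required role(s) {', '.join(missing)}")


def run_assay(assay_type: str, input_csv: str, out_path: str) -> pd.DataFrame:
    """Compute per-sample assay results and fold differences between samples.

    The input CSV is long-format with columns ``sample_id, role, value``
    plus ``venom_mass_mg`` and ``time_min`` where applicable; standards for
    the phospholipase curve carry an ``amount_nmol`` column.  The result
    column depends on the assay: TRU/mg/min, nmol/mg/min, percent
    haemolysis, or clotting delay and fold.  Each sample also reports its
    fold difference against the first sample (the reference venom).
    """
    if assay_type not in _ASSAY_TYPES:
        raise ValidationError(f"unknown assay type {assay_type!r}")
    df = pd.read_csv(input_csv, comment="#")
    for col in ("sample_id", "role", "value"):
        if col not in df.columns:
            raise FormatError(f"assay table: missing required column {col}")

    rows: list[dict] = []
    if assay_type == "hyaluronidase":
        _require_roles(df, ["control", "sample"], assay_type)
        a_control = float(df.loc[df["role"] == "control", "value"].iloc[0])
        for _, r in df[df["role"] == "sample"].iterrows():
            m = AssayMeasurement(
                a_sample=float(r["value"]),
                a_control=a_control,
                venom_mass_mg=float(r.get("venom_mass_mg", 1.0)),
                incubation_time_min=float(r.get("time_min", 1.0)),
            )
            rows.append(
                {"sample_id": r["sample_id"],
                 "activity_tru_per_mg_min": turbidity_reduction_units(m)}
            )
        value_col = "activity_tru_per_mg_min"
    elif assay_type == "phospholipase":
        _require_roles(df, ["standard", "sample"], assay_type)
        standards = df[df["role"] == "standard"]
        if "amount_nmol" not in standards.columns:
            raise FormatError("phospholipase assay: standards need an amount_nmol column")
        curve = StandardCurve.fit(
            list(zip(standards["amount_nmol"].astype(float),
                     standards["value"].astype(float)))
        )
        for _, r in df[df["role"] == "sample"].iterrows():
            m = AssayMeasurement(
                a_sample=float(r["value"]),
                venom_mass_mg=float(r.get("venom_mass_mg", 1.0)),
                incubation_time_min=float(r.get("time_min", 1.0)),
            )
            rows.append(
                {"sample_id": r["sample_id"],
                 "activity_nmol_per_mg_min": specific_activity_from_curve(curve, m)}
            )
        value_col = "activity_nmol_per_mg_min"
    elif assay_type == "haemolysis":
        _require_roles(df, ["positive", "sample"], assay_type)
        a_positive = float(df.loc[df["role"] == "positive", "value"].iloc[0])
        blanks = df.loc[df["role"] == "blank", "value"]
        a_blank = float(blanks.iloc[0]) if len(blanks) else 0.0
        for _, r in df[df["role"].isin(["sample", "positive"])].iterrows():
            m = AssayMeasurement(
                a_sample=float(r["value"]),
                a_blank=a_blank,
                a_positive=a_positive,
            )
            rows.append(
                {"sample_id": r["sample_id"],
                 "haemolysis_percent": relative_haemolysis(m)}
            )
        value_col = "haemolysis_percent"
    else:  # coagulation
        _require_roles(df, ["control", "sample"], assay_type)
        control_time = float(df.loc[df["role"] == "control", "value"].iloc[0])
        for _, r in df[df["role"] == "sample"].iterrows():
            censored = bool(r.get("censored", False))
            res = ClottingResult(
                control_time_s=control_time,
                venom_time_s=float(r["value"]),
                censored=censored,
                censoring_limit_s=float(r.get("censoring_limit_s", 1800.0))
                if censored
                else 1800.0,
            )
            d = clotting_delay(res)
            rows.append(
                {"sample_id": r["sample_id"], "delay_s": d.delay_s,
                 "fold_vs_control": d.fold, "censored_lower_bound": d.censored}
            )
        value_col = "fold_vs_control"

    result = pd.DataFrame(rows)
    ref = result[value_col].iloc[0]
    if ref != 0 and not math.isnan(ref):
        result[f"fold_vs_{result['sample_id'].iloc[0]}"] = result[value_col] / ref
    cfg = {"assay": assay_type, "input": input_csv}
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_header(cfg)}\n")
        result.to_csv(fh, index=False)
    return result
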