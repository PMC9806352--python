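"""The band-weighted relative-abundance statistic and its aggregations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vespaquant.abundance import (
    CompositionTable,
    aggregate_families,
    band_relative_auc,
    relative_abundance,
    translation_index,
)
from vespaquant.densitometry import proportions_from_areas
from vespaquant.errors import DataPolicyError, DegenerateDataError, ValidationError
from vespaquant.io_formats import AnnotationRecord, SpectralHit


def _hit(band, acc, auc):
    return SpectralHit(band, acc, score=80.0, unique_peptides=2, auc=auc)


def _props(weights):
    return proportions_from_areas(weights)


def oracle_percent(band_aucs, band_percents):
    """Literal double-loop evaluation of the band-weighted abundance sum.

    percent(X) = sum over bands of [AUC(X in band) / total AUC in band]
    times the band's densitometric percent.  Deliberately naive: plain
    Python loops over proteins and bands, no grouping or renormalisation
    beyond restricting to bands that contain hits.
    """
    proteins = sorted({acc for aucs in band_aucs.values() for acc in aucs})
    total_w = sum(band_percents[b] for b in band_aucs)
    out = {}
    for acc in proteins:
        s = 0.0
        for band, aucs in band_aucs.items():
            if acc in aucs:
                s += (aucs[acc] / sum(aucs.values())) * (
                    100.0 * band_percents[band] / total_w
                )
        out[acc] = s
    return out


class TestBandRelativeAuc:
    @pytest.mark.parametrize(
        "aucs,expected",
        [
            ({"X": 3.0, "Y": 1.0}, {"X": 0.75, "Y": 0.25}),
            ({"X": 7.0}, {"X": 1.0}),
            ({"X": 2.0, "Y": 2.0, "Z": 4.0}, {"X": 0.25, "Y": 0.25, "Z": 0.5}),
        ],
    )
    def test_within_band_fractions(self, aucs, expected):
        fractions = band_relative_auc([_hit("B1", a, v) for a, v in aucs.items()])
        assert fractions == pytest.approx(expected, abs=1e-12)
        assert math.fsum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_multiple_bands_rejected(self):
        with pytest.raises(ValidationError):
            band_relative_auc([_hit("B1", "X", 1.0), _hit("B2", "X", 1.0)])

    def test_zero_total_auc_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            band_relative_auc([_hit("B1", "X", 0.0)])


class TestRelativeAbundance:
    def test_single_band_single_protein_is_100(self):
        table = relative_abundance([_hit("B1", "X", 42.0)], _props({"B1": 1.0}))
        assert table.entries == {"X": 100.0}

    def test_hand_evaluated_two_band_example(self):
        # B1 (weight 0.6): X and Y split evenly; B2 (weight 0.4): X alone
        hits = [_hit("B1", "X", 2.0), _hit("B1", "Y", 2.0), _hit("B2", "X", 5.0)]
        table = relative_abundance(hits, _props({"B1": 0.6, "B2": 0.4}))
        assert table.entries["X"] == pytest.approx(70.0, abs=1e-12)
        assert table.entries["Y"] == pytest.approx(30.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_micro_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_bands = int(rng.integers(1, 5))
            n_prot = int(rng.integers(1, 7))
            bands = [f"B{i}" for i in range(n_bands)]
            prots = [f"P{i}" for i in range(n_prot)]
            band_aucs = {}
            for b in bands:
                members = [p for p in prots if rng.random() < 0.7]
                if not members:
                    members = [prots[int(rng.integers(n_prot))]]
                band_aucs[b] = {p: float(rng.uniform(0.1, 50)) for p in members}
            weights = {b: float(rng.uniform(0.1, 10)) for b in bands}
            total = sum(weights.values())
            percents = {b: 100 * w / total for b, w in weights.items()}
            hits = [
                _hit(b, p, auc)
                for b, aucs in band_aucs.items()
                for p, auc in aucs.items()
            ]
            table = relative_abundance(hits, _props(weights))
            expected = oracle_percent(band_aucs, percents)
            for acc, pct in expected.items():
                assert abs(table.entries[acc] - pct) < 1e-10

    def test_zero_toxin_band_renormalise_keeps_total_100(self):
        table = relative_abundance(
            [_hit("B1", "X", 1.0)],
            _props({"B1": 0.5, "B2": 0.5}),
            zero_band_policy="renormalise",
        )
        assert table.entries["X"] == pytest.approx(100.0, abs=1e-9)

    def test_zero_toxin_band_error_policy_names_band(self):
        with pytest.raises(DataPolicyError, match="B2"):
            relative_abundance(
                [_hit("B1", "X", 1.0)],
                _props({"B1": 0.5, "B2": 0.5}),
                zero_band_policy="error",
            )

    def test_band_missing_from_proportions_rejected(self):
        with pytest.raises(ValidationError, match="B9"):
            relative_abundance([_hit("B9", "X", 1.0)], _props({"B1": 1.0}))

    def test_contaminant_hit_rejected(self):
        bad = SpectralHit("B1", "CRAP_X", 80.0, 2, 1.0, is_contaminant=True)
        with pytest.raises(ValidationError):
            relative_abundance([bad], _props({"B1": 1.0}))

    def test_within_band_scale_invariance(self):
        hits = [_hit("B1", "X", 2.0), _hit("B1", "Y", 6.0), _hit("B2", "X", 1.0)]
        scaled = [
            _hit(h.band_id, h.accession, h.auc * (7.0 if h.band_id == "B1" else 1.0))
            for h in hits
        ]
        props = _props({"B1": 0.3, "B2": 0.7})
        a = relative_abundance(hits, props)
        b = relative_abundance(scaled, props)
        assert a.entries == pytest.approx(b.entries, rel=1e-12)

    def test_increasing_one_auc_is_monotone(self):
        props = _props({"B1": 0.5, "B2": 0.5})
        base = relative_abundance(
            [_hit("B1", "X", 2.0), _hit("B1", "Y", 3.0), _hit("B2", "Y", 1.0)], props
        )
        bumped = relative_abundance(
            [_hit("B1", "X", 4.0), _hit("B1", "Y", 3.0), _hit("B2", "Y", 1.0)], props
        )
        assert bumped.entries["X"] > base.entries["X"]
        assert bumped.entries["Y"] < base.entries["Y"]


class TestAggregateFamilies:
    ANN = {
        "PLA1": AnnotationRecord("PLA1", "Phospholipases", True),
        "PLA2": AnnotationRecord("PLA2", "Phospholipases", True),
        "CAP": AnnotationRecord("CAP", "CAP", True),
    }

    def test_phospholipase_family_sums_members(self):
        table = CompositionTable(
            level="protein",
            entries={"PLA1": 21.86, "PLA2": 0.17, "CAP": 77.97},
        )
        fam = aggregate_families(table, self.ANN)
        assert fam.entries["Phospholipases"] == pytest.approx(22.03, abs=1e-12)

    def test_identity_mapping_preserves_table(self):
        table = CompositionTable(level="protein", entries={"CAP": 100.0})
        fam = aggregate_families(table, self.ANN)
        assert fam.entries == {"CAP": 100.0}

    def test_total_conserved(self):
        ann = {f"P{i}": AnnotationRecord(f"P{i}", "F", True) for i in range(3)}
        table = CompositionTable(
            level="protein", entries={"P0": 10.0, "P1": 20.0, "P2": 70.0}
        )
        fam = aggregate_families(table, ann)
        assert fam.entries["F"] == pytest.approx(100.0, abs=1e-12)
        assert fam.total == pytest.approx(table.total, abs=1e-12)

    def test_unannotated_accession_listed(self):
        table = CompositionTable(level="protein", entries={"NOPE": 100.0})
        with pytest.raises(ValidationError, match="NOPE"):
            aggregate_families(table, self.ANN)


class TestTranslationIndex:
    def test_headline_fold_increase(self):
        prot = CompositionTable(level="family", entries={"CAP": 26.09, "rest": 73.91})
        trans = CompositionTable(level="family", entries={"CAP": 2.88, "rest": 97.12})
        table = translation_index(prot, trans)
        assert table.entries["CAP"].index == pytest.approx(26.09 / 2.88, rel=1e-12)
        assert table.entries["CAP"].index == pytest.approx(9.06, abs=0.01)

    def test_equal_percentages_give_unity(self):
        t = CompositionTable(level="family", entries={"F": 100.0})
        assert translation_index(t, t).entries["F"].index == 1.0

    def test_family_absent_from_transcriptome_is_undefined(self):
        prot = CompositionTable(level="family", entries={"F": 100.0})
        trans = CompositionTable(level="family", entries={"G": 100.0})
        e = translation_index(prot, trans).entries["F"]
        assert not e.defined and math.isnan(e.index)
        assert e.transcriptome_percent == 0.0

    def test_requires_family_level(self):
        prot = CompositionTable(level="protein", entries={"X": 100.0})
        fam = CompositionTable(level="family", entries={"F": 100.0})
        with pytest.raises(ValidationError):
            translation_index(prot, fam)


@given(
    st.dictionaries(
        st.sampled_from(["P1", "P2", "P3", "P4"]), st.floats(0.1, 60), min_size=1
    )
)
def test_composition_conservation_single_band(aucs):
    """Any single-band composition sums to exactly 100."""
    hits = [_hit("B1", acc, v) for acc, v in aucs.items()]
    table = relative_abundance(hits, _props({"B1": 3.0}))
    assert table.total == pytest.approx(100.0, abs=1e-9)
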