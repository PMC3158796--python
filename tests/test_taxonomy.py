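"""16S identity-threshold rules, best-hit binning, and profile aggregation."""

import pytest
from hypothesis import given, strategies as st

from metacomp.aligner import Hit, HitTable
from metacomp.sequence_io import Read, ReadSet
from metacomp.taxonomy import (
    RANK_GENUS, RANK_HIGHER, RANK_UNIDENTIFIED, ReferenceRecord,
    bin_reads_best_hit, classify_rrna, taxon_profile,
)

NAMED = ReferenceRecord("ref1", "", genus="Polynucleobacter",
                        higher_taxon="Betaproteobacteria",
                        annotation="Polynucleobacter necessarius 16S")
NAMED2 = ReferenceRecord("ref2", "", genus="Acinetobacter",
                         higher_taxon="Gammaproteobacteria",
                         annotation="Acinetobacter sp. 16S")
UNCULTURED = ReferenceRecord("ref3", "", genus=None, higher_taxon="Bacteria",
                             annotation="uncultured bacterium clone X")
REFS = [NAMED, NAMED2, UNCULTURED]


def _hit(read, subject, ident, length, bits=100.0):
    return Hit(read, subject, ident, length, 0, 0, 1, length, 1, length,
               1e-30, bits)


class TestRrnaRules:
    """The five canonical rule outcomes of the identity-threshold classifier."""

    def test_genus_above_95(self):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", 96.2, 140)])
        (a,) = classify_rrna(ht, REFS)
        assert (a.taxon, a.rank) == ("Polynucleobacter", RANK_GENUS)

    def test_higher_taxon_between_90_and_95(self):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", 92.0, 200)])
        (a,) = classify_rrna(ht, REFS)
        assert (a.taxon, a.rank) == ("Betaproteobacteria", RANK_HIGHER)

    def test_below_90_is_unidentified(self):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", 89.0, 200)])
        (a,) = classify_rrna(ht, REFS)
        assert a.rank == RANK_UNIDENTIFIED
        assert a.note == "low-identity"

    def test_uncultured_only_matches_are_unidentified(self):
        ht = HitTable("q", "refs", [_hit("r1", "ref3", 99.0, 300)])
        (a,) = classify_rrna(ht, REFS)
        assert a.rank == RANK_UNIDENTIFIED
        assert a.note == "uncultured-only"

    def test_short_alignments_are_filtered(self):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", 99.0, 95)])
        (a,) = classify_rrna(ht, REFS)
        assert a.rank == RANK_UNIDENTIFIED
        assert a.note == "length-filtered"

    @pytest.mark.parametrize("ident,expected_rank", [
        (95.0, RANK_HIGHER),   # exactly 95 is not "> 95"
        (90.0, RANK_HIGHER),   # exactly 90 is not "< 90"
    ])
    def test_boundary_identities(self, ident, expected_rank):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", ident, 200)])
        (a,) = classify_rrna(ht, REFS)
        assert a.rank == expected_rank

    def test_best_named_hit_wins_over_better_uncultured(self):
        # the uncultured record scores higher, but genus assignment must use
        # the best *named* hit
        ht = HitTable("q", "refs", [
            _hit("r1", "ref3", 99.5, 400, bits=400.0),
            _hit("r1", "ref2", 97.0, 300, bits=300.0),
            _hit("r1", "ref1", 96.0, 250, bits=250.0),
        ])
        (a,) = classify_rrna(ht, REFS)
        assert (a.taxon, a.rank) == ("Acinetobacter", RANK_GENUS)

    def test_missing_reference_raises(self):
        ht = HitTable("q", "refs", [_hit("r1", "ghost", 99.0, 200)])
        with pytest.raises(KeyError):
            classify_rrna(ht, REFS)

    def test_reads_without_hits_are_unidentified(self):
        reads = ReadSet("q", [Read("r1", "ACGT" * 50), Read("r2", "ACGT" * 50)])
        ht = HitTable("q", "refs", [_hit("r1", "ref1", 96.0, 140)])
        out = classify_rrna(ht, REFS, reads=reads)
        by_id = {a.read_id: a for a in out}
        assert by_id["r2"].note == "no-hit"
        assert by_id["r1"].rank == RANK_GENUS

    @given(st.floats(min_value=0.0, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    def test_identity_bands_are_exhaustive_and_exclusive(self, ident):
        ht = HitTable("q", "refs", [_hit("r1", "ref1", ident, 200)])
        (a,) = classify_rrna(ht, REFS)
        if ident > 95:
            assert a.rank == RANK_GENUS
        elif ident >= 90:
            assert a.rank == RANK_HIGHER
        else:
            assert a.rank == RANK_UNIDENTIFIED


class TestBestHitBinning:
    TAXA = {"g1": "Actinobacteria", "g2": "Betaproteobacteria"}

    def test_rule_application_and_cutoffs(self):
        hits = [
            Hit("r1", "g1", 98.0, 120, 0, 0, 1, 120, 1, 120, 1e-20, 90.0),
            Hit("r2", "g1", 98.0, 120, 0, 0, 1, 120, 1, 120, 1e-3, 90.0),  # evalue fails
            Hit("r3", "g2", 98.0, 40, 0, 0, 1, 40, 1, 40, 1e-20, 90.0),    # too short
        ]
        out = bin_reads_best_hit(HitTable("q", "s", hits), self.TAXA)
        by_id = {a.read_id: a for a in out}
        assert by_id["r1"].taxon == "Actinobacteria"
        assert by_id["r2"].taxon == "unclassified"
        assert by_id["r3"].taxon == "unclassified"

    def test_agrees_with_brute_force_scan(self, rng):
        hits = []
        for i in range(150):
            hits.append(Hit(f"r{int(rng.integers(0, 40))}",
                            "g1" if rng.random() < 0.5 else "g2",
                            99.0, int(rng.integers(30, 200)), 0, 0, 1, 50, 1, 50,
                            float(10 ** rng.uniform(-30, 0)),
                            float(rng.uniform(20, 200))))
        ht = HitTable("q", "s", hits)
        out = {a.read_id: a.taxon for a in bin_reads_best_hit(ht, self.TAXA)}
        for rid in {h.query_id for h in hits}:
            passing = [h for h in hits if h.query_id == rid
                       and h.evalue <= 1e-5 and h.align_length >= 50]
            if not passing:
                assert out[rid] == "unclassified"
            else:
                top = max(h.bit_score for h in passing)
                best = min((h for h in passing if h.bit_score == top),
                           key=lambda h: h.subject_id)
                assert out[rid] == self.TAXA[best.subject_id]

    def test_unknown_subject_raises(self):
        ht = HitTable("q", "s", [Hit("r1", "ghost", 99.0, 100, 0, 0, 1, 100,
                                     1, 100, 1e-20, 90.0)])
        with pytest.raises(KeyError):
            bin_reads_best_hit(ht, self.TAXA)


class TestTaxonProfile:
    def _assign(self, taxon, rank, n):
        from metacomp.taxonomy import TaxonAssignment
        return [TaxonAssignment(f"{taxon}_{i}", taxon, rank, 99.0)
                for i in range(n)]

    def test_percentages_and_ordering(self):
        assignments = (self._assign("Actinobacteria", "binned", 30)
                       + self._assign("Beta", "binned", 20)
                       + self._assign("unidentified", RANK_UNIDENTIFIED, 50))
        df = taxon_profile(assignments)
        assert list(df.taxon) == ["Actinobacteria", "Beta", "unclassified"]
        assert df.loc[df.taxon == "unclassified", "percent_total"].iloc[0] == 50.0
        assert df.loc[df.taxon == "Actinobacteria", "percent_classified"].iloc[0] == \
            pytest.approx(60.0)
        classified_pct = df.percent_total.iloc[:-1].sum()
        assert classified_pct + 50.0 == pytest.approx(100.0)

    def test_total_reads_accounts_for_unaligned(self):
        df = taxon_profile(self._assign("X", "binned", 10), total_reads=40)
        assert df.loc[df.taxon == "unclassified", "count"].iloc[0] == 30
        assert df.loc[df.taxon == "X", "percent_total"].iloc[0] == 25.0

    def test_empty_assignments(self):
        df = taxon_profile([])
        assert list(df.taxon) == ["unclassified"]
        assert df["count"].iloc[0] == 0


def test_reference_record_validation():
    with pytest.raises(ValueError):
        ReferenceRecord("x", "ACGT", higher_taxon="")
    rec = ReferenceRecord("x", "ACGT", higher_taxon="Bacteria", genus="Genus",
                          annotation="Uncultured organism")
    assert not rec.is_named  # "uncultured" marker overrides the genus field
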