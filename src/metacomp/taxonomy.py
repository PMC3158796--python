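"""Rule-based taxonomic classification of metagenomic reads.

Two classifiers are provided.  ``classify_rrna`` applies the standard
identity-threshold rules used for 16S rRNA gene fragments found in shotgun
data: alignments must exceed 100 bp; >95% identity to a well-identified
(named) reference assigns the genus; 90–95% assigns only a higher taxon;
anything below 90%, or reads whose only matches are annotated
"uncultured"/"unidentified", stay unidentified.  ``bin_reads_best_hit``
is the simplified whole-dataset binning rule: each read follows its best
bit-scoring hit that passes an e-value (1e-5) and alignment-length (50 bp)
cutoff.  ``taxon_profile`` aggregates either kind of assignment into a
composition table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from metacomp.aligner import HitTable
from metacomp.sequence_io import ReadSet

RANK_GENUS = "genus"
RANK_HIGHER = "higher"
RANK_UNIDENTIFIED = "unidentified"

#: Annotation substrings that mark a reference as not well identified.
UNNAMED_MARKERS = ("uncultured", "unidentified")


@dataclass(frozen=True)
class ReferenceRecord:
    """A labeled reference marker sequence (an RDP-style database entry)."""

    id: str
    sequence: str
    higher_taxon: str
    genus: str | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.higher_taxon:
            raise ValueError(f"reference {self.id!r}: higher_taxon must be non-empty")

    @property
    def is_named(self) -> bool:
        """True for a well-identified record usable for genus assignment."""
        ann = self.annotation.lower()
        return self.genus is not None and not any(m in ann for m in UNNAMED_MARKERS)


@dataclass(frozen=True)
class TaxonAssignment:
    """Per-read taxonomic call."""

    read_id: str
    taxon: str
    rank: str
    best_identity: float
    note: str = ""


def reference_fasta_header(rec: ReferenceRecord) -> str:
    """Structured header ``id|genus|higher_taxon|annotation`` (empty genus allowed)."""
    return f"{rec.id}|{rec.genus or ''}|{rec.higher_taxon}|{rec.annotation}"


def parse_reference_header(header: str) -> ReferenceRecord:
    parts = header.split("|")
    if len(parts) != 4:
        raise ValueError(f"reference header must have 4 '|'-fields: {header!r}")
    rid, genus, higher, annotation = parts
    return ReferenceRecord(id=rid, sequence="", higher_taxon=higher,
                           genus=genus or None, annotation=annotation)


def classify_rrna(read_hits: HitTable,
                  refs: Iterable[ReferenceRecord],
                  min_align_length: int = 100,
                  genus_identity: float = 95.0,
                  unidentified_identity: float = 90.0,
                  reads: ReadSet | None = None) -> list[TaxonAssignment]:
    """Classify rRNA gene fragments by best named hit and identity bands.

    Rules, applied per read: discard alignments of length <=
    ``min_align_length``; take the best remaining hit (highest bit score)
    to a *named* record — identity > 95 assigns that record's genus,
    identity in [90, 95] assigns its higher taxon, identity < 90 is
    unidentified.  Reads whose passing hits all point to
    "uncultured"/"unidentified" records, or with no passing hits at all,
    are unidentified.  Boundary convention: identity exactly 95 or exactly
    90 falls in the higher-taxon band.

    If ``reads`` is given, reads absent from the hit table are also
    returned as unidentified (note ``no-hit``).

    Raises
    ------
    KeyError
        If a hit's subject id is missing from ``refs``.
    """
    ref_map = {r.id: r for r in refs}
    per_read: dict[str, list] = {}
    order: list[str] = []
    for h in read_hits:
        if h.subject_id not in ref_map:
            raise KeyError(f"hit subject {h.subject_id!r} missing from reference collection")
        if h.query_id not in per_read:
            per_read[h.query_id] = []
            order.append(h.query_id)
        per_read[h.query_id].append(h)
    if reads is not None:
        for rid in reads.ids():
            if rid not in per_read:
                per_read[rid] = []
                order.append(rid)

    out: list[TaxonAssignment] = []
    for rid in order:
        hits = [h for h in per_read[rid] if h.align_length > min_align_length]
        if not per_read[rid]:
            out.append(TaxonAssignment(rid, "unidentified", RANK_UNIDENTIFIED, 0.0, "no-hit"))
            continue
        if not hits:
            out.append(TaxonAssignment(rid, "unidentified", RANK_UNIDENTIFIED, 0.0,
                                       "length-filtered"))
            continue
        named = [h for h in hits if ref_map[h.subject_id].is_named]
        if not named:
            best = max(hits, key=lambda h: h.bit_score)
            out.append(TaxonAssignment(rid, "unidentified", RANK_UNIDENTIFIED,
                                       best.percent_identity, "uncultured-only"))
            continue
        # best named hit by bit score; ties broken by ascending subject id
        top_score = max(h.bit_score for h in named)
        best = min((h for h in named if h.bit_score == top_score),
                   key=lambda h: h.subject_id)
        rec = ref_map[best.subject_id]
        ident = best.percent_identity
        if ident > genus_identity:
            out.append(TaxonAssignment(rid, rec.genus, RANK_GENUS, ident, "genus"))
        elif ident >= unidentified_identity:
            out.append(TaxonAssignment(rid, rec.higher_taxon, RANK_HIGHER, ident,
                                       "higher-rank"))
        else:
            out.append(TaxonAssignment(rid, "unidentified", RANK_UNIDENTIFIED, ident,
                                       "low-identity"))
    return out


def bin_reads_best_hit(ht: HitTable,
                       genome_taxa: Mapping[str, str],
                       max_evalue: float = 1e-5,
                       min_len: int = 50,
                       reads: ReadSet | None = None) -> list[TaxonAssignment]:
    """Bin each read by its best bit-scoring hit passing e-value/length cutoffs.

    A hit qualifies when ``evalue <= max_evalue`` and
    ``align_length >= min_len``; the qualifying hit with the highest bit
    score (ties broken by ascending subject id) determines the read's
    taxon via ``genome_taxa``.  Reads with no qualifying hit are
    unclassified.

    Raises
    ------
    KeyError
        If a hit's subject id is absent from ``genome_taxa``.
    """
    for sid in ht.subject_ids():
        if sid not in genome_taxa:
            raise KeyError(f"subject {sid!r} has no taxon in genome_taxa")
    per_read: dict[str, list] = {}
    order: list[str] = []
    for h in ht:
        if h.query_id not in per_read:
            per_read[h.query_id] = []
            order.append(h.query_id)
        if h.evalue <= max_evalue and h.align_length >= min_len:
            per_read[h.query_id].append(h)
    if reads is not None:
        for rid in reads.ids():
            if rid not in per_read:
                per_read[rid] = []
                order.append(rid)
    out: list[TaxonAssignment] = []
    for rid in order:
        qualifying = per_read[rid]
        if not qualifying:
            out.append(TaxonAssignment(rid, "unclassified", RANK_UNIDENTIFIED, 0.0,
                                       "no-passing-hit"))
            continue
        top = max(h.bit_score for h in qualifying)
        best = min((h for h in qualifying if h.bit_score == top),
                   key=lambda h: h.subject_id)
        out.append(TaxonAssignment(rid, genome_taxa[best.subject_id], "binned",
                                   best.percent_identity, f"best-hit:{best.subject_id}"))
    return out


def taxon_profile(assignments: Iterable[TaxonAssignment],
                  total_reads: int | None = None) -> pd.DataFrame:
    """Aggregate assignments into a composition table.

    Returns a DataFrame with columns ``taxon, count, percent_classified,
    percent_total``, ordered by descending count with an ``unclassified``
    row last.  ``total_reads`` defaults to the number of assignments; pass
    the dataset size to account for reads that were never aligned.
    """
    assignments = list(assignments)
    counts: dict[str, int] = {}
    n_unclassified = 0
    for a in assignments:
        if a.rank == RANK_UNIDENTIFIED:
            n_unclassified += 1
        else:
            counts[a.taxon] = counts.get(a.taxon, 0) + 1
    total = total_reads if total_reads is not None else len(assignments)
    if total_reads is not None:
        n_unclassified += total_reads - len(assignments)
    n_classified = sum(counts.values())
    rows = []
    for taxon, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append({
            "taxon": taxon,
            "count": c,
            "percent_classified": 100.0 * c / n_classified if n_classified else 0.0,
            "percent_total": 100.0 * c / total if total else 0.0,
        })
    rows.append({
        "taxon": "unclassified",
        "count": n_unclassified,
        "percent_classified": float("nan"),
        "percent_total": 100.0 * n_unclassified / total if total else 0.0,
    })
    return pd.DataFrame(rows, columns=["taxon", "count", "percent_classified",
                                       "percent_total"])
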