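"""Fragment recruitment of reads against reference genomes.

Recruitment maps a read set onto one reference genome and records, for
every recruited read, its position along the genome and its percent
identity — the data behind the classic recruitment plot (position on the
horizontal axis, %identity on the vertical).  The counting criteria are a
minimum identity of 95% and a minimum alignment length of 50 bp, both
inclusive.  Genomes are ranked by how many reads they recruit, and
``overlap_fraction`` computes the dataset-overlap statistic (fraction of
query reads with a hit at >90% identity covering at least half the read).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from metacomp.aligner import Hit, HitTable
from metacomp.sequence_io import ReadSet


@dataclass
class RecruitmentResult:
    """Recruitment of one read set onto one genome."""

    genome_id: str
    points: list[tuple[int, float]]  # (subject midpoint bp, percent identity)
    n_recruited: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.n_recruited != len(self.points):
            raise ValueError("n_recruited must equal the number of points")

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("position\tpercent_identity\n")
            for pos, pid in self.points:
                fh.write(f"{pos}\t{pid!r}\n")


def _subject_span(h: Hit) -> tuple[int, int]:
    return (min(h.s_start, h.s_end), max(h.s_start, h.s_end))


def recruit(ht: HitTable, genome_length: int, min_identity: float = 95.0,
            min_len: int = 50) -> RecruitmentResult:
    """Recruit reads onto a single genome.

    Keeps hits with ``percent_identity >= min_identity`` and
    ``align_length >= min_len`` (both inclusive), one best hit per read
    (highest bit score, ties to the leftmost subject position).  Each
    recruited read contributes one point at its subject-coordinate
    midpoint ``min(s_start, s_end) + span // 2``.

    The hit table must target exactly one genome, and ``genome_length``
    must cover every subject coordinate.
    """
    subject_ids = ht.subject_ids()
    if len(subject_ids) > 1:
        raise ValueError(f"recruitment expects hits to a single genome, got {sorted(subject_ids)}")
    genome_id = next(iter(subject_ids)) if subject_ids else (ht.subject_label or "genome")
    passing = [h for h in ht.hits
               if h.percent_identity >= min_identity and h.align_length >= min_len]
    max_coord = max((max(h.s_start, h.s_end) for h in passing), default=0)
    if genome_length < max_coord:
        raise ValueError(f"genome_length {genome_length} < max subject coordinate {max_coord}")
    best: dict[str, Hit] = {}
    for h in passing:
        cur = best.get(h.query_id)
        if cur is None or (h.bit_score, -_subject_span(h)[0]) > (cur.bit_score, -_subject_span(cur)[0]):
            best[h.query_id] = h
    points = []
    for h in best.values():
        lo, hi = _subject_span(h)
        points.append((lo + (hi - lo) // 2, h.percent_identity))
    points.sort()
    return RecruitmentResult(genome_id=genome_id, points=points,
                             n_recruited=len(points), genome_length=genome_length)


def rank_genomes(results: list[RecruitmentResult]) -> pd.DataFrame:
    """Rank genomes by recruited-read count (descending; ties by genome id)."""
    if not results:
        raise ValueError("need at least one recruitment result")
    df = pd.DataFrame({"genome_id": [r.genome_id for r in results],
                       "n_recruited": [r.n_recruited for r in results]})
    return (df.sort_values(["n_recruited", "genome_id"], ascending=[False, True])
              .reset_index(drop=True))


def overlap_fraction(queries: ReadSet, ht: HitTable, min_identity: float = 90.0,
                     min_query_cov: float = 0.5) -> float:
    """Fraction of query reads with at least one qualifying hit.

    A hit qualifies when its identity is strictly above ``min_identity``
    and it covers at least ``min_query_cov`` of the read
    (``(q_end − q_start + 1) / read length``).  Every hit's query id must
    exist in ``queries``.
    """
    if len(queries) == 0:
        raise ValueError("empty query ReadSet")
    covered: set[str] = set()
    for h in ht.hits:
        if h.query_id not in queries:
            raise KeyError(f"hit query {h.query_id!r} absent from read set {queries.label!r}")
        read_len = len(queries.get(h.query_id))
        cov = (h.q_end - h.q_start + 1) / read_len
        if h.percent_identity > min_identity and cov >= min_query_cov:
            covered.add(h.query_id)
    return len(covered) / len(queries)
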