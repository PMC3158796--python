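"""Seed-and-extend nucleotide local alignment with BLAST-tabular semantics.

The aligner follows the classic BLASTN recipe: exact ``k``-mer seeding on
both strands, ungapped X-drop extension along each seed diagonal, and an
optional banded gapped refinement.  Raw scores are normalized into bit
scores with the Karlin–Altschul parameters (``bits = (λ·S − ln K)/ln 2``)
and expectation values are ``E = m·n·2^{−bits}``.  Output uses the
universal 12-column tabular ("outfmt 6") semantics, and tabular files from
any external aligner can be ingested in its place, so every downstream
stage is aligner-agnostic.

Coordinates are 1-based inclusive; a reverse-strand match is encoded by
``s_start > s_end``, the BLAST tabular convention.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from metacomp.sequence_io import Read, ReadSet

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T/N as uint8 codes 0–4."""
    return _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring and search parameters.

    Defaults: word size 11, match +1 / mismatch −2, gap open −5 / extend −2,
    ungapped X-drop 20 score units, Karlin–Altschul λ=1.28 and K=0.46
    applied to the final score as an ungapped-theory approximation.  The
    dataset-level Jaccard distance is invariant to any uniform rescaling of
    bit scores, so these defaults affect nothing structural downstream.
    """

    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    lambda_: float = 1.28
    kappa: float = 0.46
    max_evalue: float = 10.0
    all_hsps: bool = False
    gapped: bool = False
    band: int = 8
    gapped_window: int = 200

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.lambda_ <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@dataclass(frozen=True)
class Hit:
    """One local-alignment record in 12-column tabular semantics."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")

    @property
    def is_reverse(self) -> bool:
        return self.s_start > self.s_end

    @property
    def query_coverage_length(self) -> int:
        return self.q_end - self.q_start + 1

    def to_row(self) -> list:
        return [
            self.query_id,
            self.subject_id,
            self.percent_identity,
            self.align_length,
            self.mismatches,
            self.gap_opens,
            self.q_start,
            self.q_end,
            self.s_start,
            self.s_end,
            self.evalue,
            self.bit_score,
        ]


@dataclass
class HitTable:
    """Ordered collection of hits between a query and a subject dataset."""

    query_label: str = ""
    subject_label: str = ""
    hits: list[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def subject_ids(self) -> set[str]:
        return {h.subject_id for h in self.hits}

    def query_ids(self) -> set[str]:
        return {h.query_id for h in self.hits}


def bit_score(raw_score: float, lambda_: float = 1.28, kappa: float = 0.46) -> float:
    """Normalize a raw alignment score into bits: ``(λ·S − ln K) / ln 2``."""
    if lambda_ <= 0 or kappa <= 0:
        raise ValueError("lambda and K must be positive")
    return (lambda_ * raw_score - math.log(kappa)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance hits in an ``m × n`` search space: ``m·n·2^(−bits)``."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m) * float(n) * math.pow(2.0, -bits)


def _subject_records(subject) -> list[tuple[str, str]]:
    """Normalize a subject collection to [(id, sequence), ...]."""
    if isinstance(subject, ReadSet):
        return [(r.id, r.sequence) for r in subject.reads]
    records = []
    for item in subject:
        if isinstance(item, Read):
            records.append((item.id, item.sequence))
        elif isinstance(item, tuple) and len(item) == 2:
            records.append((str(item[0]), str(item[1])))
        else:  # duck-typed: SyntheticGenome or SeqRecord-like
            records.append((str(item.id), str(getattr(item, "sequence", getattr(item, "seq", "")))))
    return records


def _build_index(records: list[tuple[str, str]], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for si, (_sid, seq) in enumerate(records):
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((si, pos))
    return index


def _xdrop_extend(scores: np.ndarray, matches: np.ndarray, a: int, b: int,
                  xdrop: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of the exact seed [a, b] along one diagonal.

    Returns (lo, hi, n_matches, raw_score) in local diagonal coordinates.
    """
    raw = int(scores[a:b + 1].sum())
    hi = b
    right = scores[b + 1:]
    if right.size:
        c = np.cumsum(right)
        runmax = np.maximum.accumulate(c)
        over = (runmax - c) > xdrop
        limit = int(np.argmax(over)) if over.any() else right.size
        if limit > 0:
            jr = int(np.argmax(c[:limit]))
            if c[jr] > 0:
                hi = b + 1 + jr
                raw += int(c[jr])
    lo = a
    left = scores[:a][::-1]
    if left.size:
        c = np.cumsum(left)
        runmax = np.maximum.accumulate(c)
        over = (runmax - c) > xdrop
        limit = int(np.argmax(over)) if over.any() else left.size
        if limit > 0:
            jl = int(np.argmax(c[:limit]))
            if c[jl] > 0:
                lo = a - 1 - jl
                raw += int(c[jl])
    n_match = int(matches[lo:hi + 1].sum())
    return lo, hi, n_match, raw


def _diagonal_hsps(qarr: np.ndarray, sarr: np.ndarray, diag: int,
                   seed_positions: list[int], params: AlignmentParams):
    """Extend merged seeds on one (subject-offset) diagonal into ungapped HSPs.

    ``diag`` is subject position minus query position; seed_positions are
    query-local start coordinates of exact k-mer matches, ascending.
    """
    lq, ls = len(qarr), len(sarr)
    q0 = max(0, -diag)
    q1 = min(lq, ls - diag)
    seg_q = qarr[q0:q1]
    seg_s = sarr[q0 + diag:q1 + diag]
    m = (seg_q == seg_s) & (seg_q != 4)
    scores = np.where(m, params.match, params.mismatch).astype(np.int64)
    hsps = []
    covered_hi = -1
    for qpos in seed_positions:
        a = qpos - q0
        b = a + params.k - 1
        if b <= covered_hi:
            continue
        lo, hi, n_match, raw = _xdrop_extend(scores, m, a, b, params.xdrop)
        covered_hi = hi
        hsps.append((lo + q0, hi + q0, n_match, raw))
    return hsps


def _banded_gapped_extend(qarr: np.ndarray, sarr: np.ndarray,
                          q_lo: int, q_hi: int, diag: int,
                          params: AlignmentParams):
    """Banded affine-gap local refinement around an ungapped HSP.

    Runs a Smith–Waterman restricted to ``±band`` around the HSP diagonal
    over a window extended by ``gapped_window`` on each side; a gap of
    length L costs ``gap_open + L·gap_extend``.  Returns
    (q_lo, q_hi, s_lo, s_hi, n_matches, n_mismatches, n_gap_cols,
    n_gap_opens, raw) or None when the gapped score does not beat the
    ungapped one.
    """
    w = params.gapped_window
    band = params.band
    lq, ls = len(qarr), len(sarr)
    qa = max(0, q_lo - w)
    qb = min(lq - 1, q_hi + w)
    sa = max(0, q_lo + diag - w)
    sb = min(ls - 1, q_hi + diag + w)
    nq = qb - qa + 1
    ns = sb - sa + 1
    base_diag = diag - (sa - qa)
    NEG = -10 ** 9
    # H[i][j]: best local score ending at query qa+i-1 / subject sa+j-1.
    H = [[0] * (ns + 1) for _ in range(nq + 1)]
    E = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in query (subject insert)
    F = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in subject
    ptr: dict[tuple[int, int], tuple] = {}
    best = (0, 0, 0)
    for i in range(1, nq + 1):
        jlo = max(1, i + base_diag - band)
        jhi = min(ns, i + base_diag + band)
        for j in range(jlo, jhi + 1):
            sub = params.match if (qarr[qa + i - 1] == sarr[sa + j - 1]
                                   and qarr[qa + i - 1] != 4) else params.mismatch
            e = max(H[i][j - 1] + params.gap_open + params.gap_extend,
                    E[i][j - 1] + params.gap_extend)
            f = max(H[i - 1][j] + params.gap_open + params.gap_extend,
                    F[i - 1][j] + params.gap_extend)
            h = max(0, H[i - 1][j - 1] + sub, e, f)
            E[i][j], F[i][j], H[i][j] = e, f, h
            if h > 0:
                if h == H[i - 1][j - 1] + sub:
                    ptr[(i, j)] = ("D", sub == params.match)
                elif h == e:
                    ptr[(i, j)] = ("E", False)
                elif h == f:
                    ptr[(i, j)] = ("F", False)
            if h > best[0]:
                best = (h, i, j)
    raw, bi, bj = best
    if raw <= 0:
        return None
    n_match = n_mismatch = n_gap_cols = n_gap_opens = 0
    i, j = bi, bj
    last = None
    while (i, j) in ptr and H[i][j] > 0:
        op, is_match = ptr[(i, j)]
        if op == "D":
            n_match += int(is_match)
            n_mismatch += int(not is_match)
            i, j = i - 1, j - 1
        elif op == "E":
            n_gap_cols += 1
            if last != "E":
                n_gap_opens += 1
            j -= 1
        else:
            n_gap_cols += 1
            if last != "F":
                n_gap_opens += 1
            i -= 1
        last = op
    return (qa + i, qa + bi - 1, sa + j, sa + bj - 1,
            n_match, n_mismatch, n_gap_cols, n_gap_opens, raw)


def find_hits(query: ReadSet, subject, params: AlignmentParams | None = None) -> HitTable:
    """Align every query read against a subject collection on both strands.

    Exact k-mer seeds are grouped per (subject, diagonal), merged, and
    extended ungapped with X-drop; with ``params.gapped`` each ungapped HSP
    is refined by a banded affine-gap extension.  By default the single
    best-scoring HSP per (query, subject) pair is reported
    (``params.all_hsps`` reports every HSP).  Percent identity is
    ``100 × matches / alignment length``; hits with expectation above
    ``params.max_evalue`` are dropped.

    Parameters
    ----------
    query : ReadSet
    subject
        A ReadSet, a list of ``(id, sequence)`` pairs, or any iterable of
        objects with ``id`` and ``sequence`` attributes (e.g. synthetic
        genomes).
    """
    if params is None:
        params = AlignmentParams()
    records = _subject_records(subject)
    if not records:
        raise ValueError("subject collection is empty")
    k = params.k
    index = _build_index(records, k)
    sarrs = [encode(seq) for _, seq in records]
    search_n = sum(len(seq) for _, seq in records)
    table = HitTable(query_label=query.label,
                     subject_label=getattr(subject, "label", ""))
    for read in query.reads:
        lq = len(read.sequence)
        candidates: dict[int, list[tuple]] = {}
        for strand in (1, -1):
            qseq = read.sequence if strand == 1 else reverse_complement(read.sequence)
            qarr = encode(qseq)
            groups: dict[tuple[int, int], list[int]] = {}
            for i in range(lq - k + 1):
                entry = index.get(qseq[i:i + k])
                if entry:
                    for si, pos in entry:
                        groups.setdefault((si, pos - i), []).append(i)
            for (si, diag), seed_positions in groups.items():
                for q_lo, q_hi, n_match, raw in _diagonal_hsps(
                        qarr, sarrs[si], diag, seed_positions, params):
                    length = q_hi - q_lo + 1
                    gap_cols = gap_opens = 0
                    s_lo, s_hi = q_lo + diag, q_hi + diag
                    n_mismatch = length - n_match
                    if params.gapped:
                        refined = _banded_gapped_extend(
                            qarr, sarrs[si], q_lo, q_hi, diag, params)
                        if refined is not None and refined[8] > raw:
                            (q_lo, q_hi, s_lo, s_hi, n_match, n_mismatch,
                             gap_cols, gap_opens, raw) = refined
                            length = n_match + n_mismatch + gap_cols
                    candidates.setdefault(si, []).append(
                        (raw, strand, q_lo, q_hi, s_lo, s_hi,
                         n_match, n_mismatch, gap_cols, gap_opens, length))
        read_hits: list[Hit] = []
        for si, hsps in candidates.items():
            if not params.all_hsps:
                # best raw score; prefer plus strand, then leftmost start
                hsps = [max(hsps, key=lambda t: (t[0], t[1], -t[2]))]
            for (raw, strand, q_lo, q_hi, s_lo, s_hi, n_match, n_mismatch,
                 gap_cols, gap_opens, length) in hsps:
                bits = bit_score(raw, params.lambda_, params.kappa)
                ev = evalue(bits, lq, search_n)
                if ev > params.max_evalue:
                    continue
                if strand == 1:
                    qs, qe = q_lo + 1, q_hi + 1
                    ss, se = s_lo + 1, s_hi + 1
                else:
                    qs, qe = lq - q_hi, lq - q_lo
                    ss, se = s_hi + 1, s_lo + 1
                read_hits.append(Hit(
                    query_id=read.id,
                    subject_id=records[si][0],
                    percent_identity=round(100.0 * n_match / length, 3),
                    align_length=length,
                    mismatches=n_mismatch,
                    gap_opens=gap_opens,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    evalue=ev,
                    bit_score=bits,
                ))
        read_hits.sort(key=lambda h: (-h.bit_score, h.subject_id, h.q_start))
        table.hits.extend(read_hits)
    return table


class TabularParseError(ValueError):
    """Raised on malformed 12-column tabular hit files."""


def read_tabular_hits(path: str | os.PathLike, query_label: str = "",
                      subject_label: str = "") -> HitTable:
    """Read a 12-column tab-separated hit file (BLAST outfmt-6 order).

    Lines starting with ``#`` and blank lines are skipped; any other line
    with a column count other than 12 raises :class:`TabularParseError`
    naming the line number.
    """
    table = HitTable(query_label=query_label, subject_label=subject_label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TabularParseError(
                    f"{os.fspath(path)}: line {lineno}: expected 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                table.hits.append(Hit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                ))
            except ValueError as exc:
                raise TabularParseError(
                    f"{os.fspath(path)}: line {lineno}: {exc}"
                ) from exc
    return table


def write_tabular_hits(ht: HitTable, path: str | os.PathLike) -> None:
    """Write hits as 12-column TSV; round-trips losslessly."""
    with open(path, "w") as fh:
        for h in ht.hits:
            fh.write("\t".join(
                repr(float(v)) if isinstance(v, float) else str(v) for v in h.to_row()
            ) + "\n")
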