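"""Synthetic communities with planted ground truth.

Generators for reference genomes at controlled GC content, multi-genome
read communities (pyrosequencing-like reads, mean length 325 bp), paired
communities sharing a controllable fraction of their genomes, RDP-style
marker-gene reference collections with named and "uncultured" entries, and
functional-profile count tables with planted fold changes.  Everything is
bit-reproducible for a fixed seed, and every read's origin is recorded so
downstream recovery can be scored exactly.

Reads carry substitution errors only (no homopolymer indels), which keeps
percent-identity accounting exact for threshold-rule testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metacomp.sequence_io import Read, ReadSet
from metacomp.taxonomy import ReferenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default read-length model: the pyrosequencing-era mean of 325 bases with
#: a 75 bp spread, truncated below at the 60 bp analysis cutoff.
READ_LEN_MEAN = 325.0
READ_LEN_SD = 75.0
READ_LEN_MIN = 60


@dataclass(frozen=True)
class SyntheticGenome:
    """A simulated reference genome with a target GC fraction."""

    id: str
    sequence: str
    gc_target: float
    taxon_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_realized(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class CommunityTruth:
    """Ground truth for a simulated community.

    ``per_read_source`` maps read id -> (genome id, 0-based start on the
    forward strand, strand '+'/'-').
    """

    genome_ids: list[str]
    abundances: np.ndarray
    per_read_source: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    shared_fraction: float | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.genome_ids):
            raise ValueError("abundances must match genome_ids in length")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    def source_genome(self, read_id: str) -> str:
        return self.per_read_source[read_id][0]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def simulate_genome(length: int, gc_target: float, seed: int,
                    genome_id: str = "genome", taxon_label: str = "") -> SyntheticGenome:
    """Simulate an i.i.d. genome with ``P(G) = P(C) = gc_target / 2``.

    Deterministic for a fixed seed; the realized GC fraction concentrates
    around ``gc_target`` (binomial fluctuations are O(1/sqrt(length))).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_target) / 2.0
    gc = gc_target / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return SyntheticGenome(id=genome_id, sequence=_decode(codes.astype(np.uint8)),
                           gc_target=gc_target, taxon_label=taxon_label)


_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on codes


def _mutate_codes(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions at ``error_rate``; each error picks one of
    the three alternative bases uniformly."""
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.size) < error_rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
    return codes


def simulate_community(genomes: list[SyntheticGenome],
                       abundances,
                       n_reads: int,
                       len_mean: float = READ_LEN_MEAN,
                       len_sd: float = READ_LEN_SD,
                       error_rate: float = 0.0,
                       seed: int = 0,
                       label: str = "community") -> tuple[ReadSet, CommunityTruth]:
    """Draw reads from a genome mixture with substitution errors.

    Source genomes are drawn by abundance, read lengths from a normal
    (``len_mean``, ``len_sd``) truncated to [60, genome length] by
    resampling, strands uniformly.  The returned truth records every
    read's (genome, start, strand).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    abundances = np.asarray(abundances, dtype=float)
    if len(abundances) != len(genomes):
        raise ValueError("abundances must match genomes in length")
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    genome_codes = [np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8) for g in genomes]
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    genome_codes = [lut[c] for c in genome_codes]
    sources = rng.choice(len(genomes), size=n_reads, p=abundances)
    reads: list[Read] = []
    truth = CommunityTruth(genome_ids=[g.id for g in genomes], abundances=abundances)
    for i in range(n_reads):
        gi = int(sources[i])
        glen = len(genomes[gi])
        length = 0
        while not (READ_LEN_MIN <= length <= glen):
            length = int(round(rng.normal(len_mean, len_sd)))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        codes = genome_codes[gi][start:start + length]
        if strand == "-":
            codes = _COMP[codes][::-1]
        codes = _mutate_codes(codes, error_rate, rng)
        rid = f"{label}_r{i:06d}"
        reads.append(Read(id=rid, sequence=_decode(codes)))
        truth.per_read_source[rid] = (genomes[gi].id, start, strand)
    return ReadSet(label=label, reads=reads), truth


def simulate_paired_communities(shared_fraction: float,
                                n_genomes: int,
                                gc_modes: tuple[float, float] = (0.45, 0.65),
                                n_reads: int = 1000,
                                seed: int = 0,
                                genome_length: int = 20_000,
                                error_rate: float = 0.0,
                                labels: tuple[str, str] = ("A", "B"),
                                ) -> tuple[ReadSet, ReadSet, CommunityTruth, CommunityTruth]:
    """Two communities of ``n_genomes`` each, sharing a genome fraction.

    ``round(shared_fraction * n_genomes)`` genomes come from a common pool;
    the remainder are private to each community.  GC targets alternate
    between the two ``gc_modes`` within every community, so each read set
    has a bimodal GC profile (the two-peak freshwater signature).
    Abundances are uniform.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    n_shared = int(round(shared_fraction * n_genomes))
    n_private = n_genomes - n_shared
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_shared + 2 * n_private + 2)]
    gc_cycle = lambda i: gc_modes[i % 2]

    shared = [simulate_genome(genome_length, gc_cycle(i), child_seeds[i],
                              genome_id=f"shared_g{i}")
              for i in range(n_shared)]
    off = n_shared
    priv_a = [simulate_genome(genome_length, gc_cycle(n_shared + i), child_seeds[off + i],
                              genome_id=f"{labels[0]}_g{i}")
              for i in range(n_private)]
    off += n_private
    priv_b = [simulate_genome(genome_length, gc_cycle(n_shared + i), child_seeds[off + i],
                              genome_id=f"{labels[1]}_g{i}")
              for i in range(n_private)]
    genomes_a = shared + priv_a
    genomes_b = shared + priv_b
    uniform = np.full(n_genomes, 1.0 / n_genomes)
    rs_a, truth_a = simulate_community(genomes_a, uniform, n_reads,
                                       error_rate=error_rate,
                                       seed=child_seeds[-2], label=labels[0])
    rs_b, truth_b = simulate_community(genomes_b, uniform, n_reads,
                                       error_rate=error_rate,
                                       seed=child_seeds[-1], label=labels[1])
    truth_a.shared_fraction = shared_fraction
    truth_b.shared_fraction = shared_fraction
    rs_a.genomes = genomes_a  # type: ignore[attr-defined]
    rs_b.genomes = genomes_b  # type: ignore[attr-defined]
    return rs_a, rs_b, truth_a, truth_b


def _mutate_sequence(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly ``round(divergence * len)`` positions (no two at
    the same site), each to a different base."""
    n = int(round(divergence * len(sequence)))
    if n == 0:
        return sequence
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)].copy()
    pos = rng.choice(len(sequence), size=n, replace=False)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    codes[pos] = (codes[pos] + shift) % 4
    return _decode(codes)


HIGHER_TAXA = ("Actinobacteria", "Betaproteobacteria", "Alphaproteobacteria",
               "Gammaproteobacteria", "Crenarchaeota")


def build_marker_reference(n_named: int,
                           n_uncultured: int,
                           divergence: float,
                           seed: int,
                           marker_length: int = 1500) -> list[ReferenceRecord]:
    """Build an RDP-style marker reference of named and "uncultured" entries.

    All entries are mutated copies of a single random seed marker at the
    stated divergence (uniform substitutions).  Named entries carry a genus
    and a cycling higher taxon; uncultured entries carry only a higher
    taxon and the annotation ``uncultured bacterium``.
    """
    if n_named + n_uncultured < 1:
        raise ValueError("need at least one reference entry")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    base = _decode(rng.integers(0, 4, size=marker_length).astype(np.uint8))
    refs: list[ReferenceRecord] = []
    for i in range(n_named):
        genus = f"Genus{i:02d}"
        refs.append(ReferenceRecord(
            id=f"ref_named_{i:02d}",
            sequence=_mutate_sequence(base, divergence, rng),
            genus=genus,
            higher_taxon=HIGHER_TAXA[i % len(HIGHER_TAXA)],
            annotation=f"{genus} sp. strain S{i:02d} 16S ribosomal RNA gene",
        ))
    for i in range(n_uncultured):
        refs.append(ReferenceRecord(
            id=f"ref_unc_{i:02d}",
            sequence=_mutate_sequence(base, divergence, rng),
            genus=None,
            higher_taxon="Bacteria",
            annotation="uncultured bacterium clone 16S ribosomal RNA gene",
        ))
    return refs


def simulate_profile_pair(n_categories: int,
                          totals: tuple[int, int],
                          planted: dict[str, float],
                          seed: int,
                          baseline: np.ndarray | None = None,
                          ) -> tuple[pd.Series, pd.Series, dict[str, float]]:
    """Two functional-category count profiles with planted fold changes.

    Counts are multinomial draws: dataset A from the baseline proportions
    (uniform unless ``baseline`` is given), dataset B from the baseline
    perturbed by the planted per-category fold changes and renormalized.
    Returns two count Series (index = category names ``C0000``…) and the
    planted-truth map.
    """
    if min(totals) < 1000:
        raise ValueError("totals must be >= 1000")
    cats = [f"C{i:04d}" for i in range(n_categories)]
    for c, fold in planted.items():
        if c not in cats:
            raise ValueError(f"planted category {c!r} not among the {n_categories} categories")
        if fold <= 0:
            raise ValueError("planted fold changes must be > 0")
    if baseline is None:
        p_a = np.full(n_categories, 1.0 / n_categories)
    else:
        p_a = np.asarray(baseline, dtype=float)
        if len(p_a) != n_categories or abs(p_a.sum() - 1.0) > 1e-9:
            raise ValueError("baseline must be a probability vector of length n_categories")
    fold_vec = np.ones(n_categories)
    for c, fold in planted.items():
        fold_vec[cats.index(c)] = fold
    p_b = p_a * fold_vec
    p_b = p_b / p_b.sum()
    rng = np.random.default_rng(seed)
    counts_a = rng.multinomial(totals[0], p_a)
    counts_b = rng.multinomial(totals[1], p_b)
    return (pd.Series(counts_a, index=cats, name="A"),
            pd.Series(counts_b, index=cats, name="B"),
            dict(planted))


def write_truth(truth: CommunityTruth, path: str | os.PathLike) -> None:
    """Write community truth as a structured TSV sidecar."""
    with open(path, "w") as fh:
        fh.write(f"#shared_fraction\t{truth.shared_fraction}\n")
        fh.write("#genome_id\tabundance\n")
        for gid, ab in zip(truth.genome_ids, truth.abundances):
            fh.write(f"#G\t{gid}\t{float(ab)!r}\n")
        fh.write("read_id\tgenome_id\tstart\tstrand\n")
        for rid, (gid, start, strand) in truth.per_read_source.items():
            fh.write(f"{rid}\t{gid}\t{start}\t{strand}\n")


def read_truth(path: str | os.PathLike) -> CommunityTruth:
    """Read a truth sidecar written by :func:`write_truth`."""
    shared: float | None = None
    genome_ids: list[str] = []
    abundances: list[float] = []
    per_read: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#shared_fraction"):
                val = line.split("\t")[1]
                shared = None if val == "None" else float(val)
            elif line.startswith("#G\t"):
                _, gid, ab = line.split("\t")
                genome_ids.append(gid)
                abundances.append(float(ab))
            elif line.startswith("#") or line.startswith("read_id\t") or not line:
                continue
            else:
                rid, gid, start, strand = line.split("\t")
                per_read[rid] = (gid, int(start), strand)
    truth = CommunityTruth(genome_ids=genome_ids, abundances=np.array(abundances),
                           per_read_source=per_read, shared_fraction=shared)
    return truth
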