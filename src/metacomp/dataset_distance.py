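"""Whole-dataset distances from alignment bit scores, and trees.

Two read datasets *A* and *B* are compared by aligning every read of each
against all reads of the other (and of itself), filtering hits to >70%
identity and >100 bp alignment length, and summing bit scores.  With
``AB_s`` the total bit score of the common hits and ``AA_s``, ``BB_s`` the
self-comparison totals, the Jaccard distance is

    D = 1 − AB_s / (AA_s + BB_s − AB_s),

i.e. one minus shared bit-score mass over union bit-score mass.  D is 0
for identical datasets, 1 for datasets without a single common hit, and —
because it is a ratio of bit-score sums — invariant to any uniform
rescaling of bit scores.  Matrices of pairwise D feed a Saitou–Nei
neighbor-joining tree (the same construction as PHYLIP ``neighbor``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from metacomp.aligner import AlignmentParams, HitTable, find_hits
from metacomp.sequence_io import ReadSet

POLICIES = ("best-per-query", "best-per-pair", "all-hsps")


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix.

    The container enforces symmetry and a zero diagonal; matrices produced
    by :func:`distance_matrix` additionally have all entries in [0, 1].
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(labels=header, values=np.array(rows))

    def to_phylip(self, path: str | os.PathLike) -> None:
        """PHYLIP-style square distance matrix export."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                fh.write(f"{lab:<10s}" + " ".join(f"{v:.6f}" for v in self.values[i]) + "\n")


def filter_distance_hits(ht: HitTable, min_identity: float = 70.0,
                         min_len: int = 100) -> HitTable:
    """Keep hits with identity strictly above 70% and length strictly above
    100 bp (the whole-dataset comparison filter; both thresholds strict)."""
    if min_identity < 0 or min_len < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [h for h in ht.hits
            if h.percent_identity > min_identity and h.align_length > min_len]
    return HitTable(query_label=ht.query_label, subject_label=ht.subject_label,
                    hits=kept)


def total_bit_score(ht: HitTable, policy: str = "best-per-query") -> float:
    """Sum bit scores over a (pre-filtered) hit table.

    Policies: ``best-per-query`` keeps each query's single best hit,
    ``best-per-pair`` the best HSP per (query, subject) pair, ``all-hsps``
    sums everything.  An empty table totals 0.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "all-hsps":
        return float(sum(h.bit_score for h in ht.hits))
    best: dict = {}
    for h in ht.hits:
        key = h.query_id if policy == "best-per-query" else (h.query_id, h.subject_id)
        if key not in best or h.bit_score > best[key]:
            best[key] = h.bit_score
    return float(sum(best.values()))


def jaccard_distance(AB_s: float, AA_s: float, BB_s: float,
                     form: str = "jaccard") -> float:
    """Dataset distance from total bit scores.

    ``jaccard`` (default): ``D = 1 − AB_s / (AA_s + BB_s − AB_s)``;
    ``dice``: the Sørensen–Dice variant ``D = 1 − 2·AB_s / (AA_s + BB_s)``.
    Requires ``0 <= AB_s <= min(AA_s, BB_s)`` — a shared score exceeding a
    self score signals inconsistent inputs.
    """
    if AA_s <= 0 or BB_s <= 0:
        raise ValueError("self scores AA_s and BB_s must be positive")
    if AB_s < 0 or AB_s > min(AA_s, BB_s) * (1 + 1e-12):
        raise ValueError("AB_s must lie in [0, min(AA_s, BB_s)]")
    if form == "jaccard":
        return 1.0 - AB_s / (AA_s + BB_s - AB_s)
    if form == "dice":
        return 1.0 - 2.0 * AB_s / (AA_s + BB_s)
    raise ValueError(f"unknown form {form!r}")


def cross_scores(a: ReadSet, b: ReadSet, params: AlignmentParams | None = None,
                 min_identity: float = 70.0, min_len: int = 100,
                 policy: str = "best-per-query") -> float:
    """Symmetrized cross bit-score total: mean of A→B and B→A totals after
    filtering."""
    ab = total_bit_score(filter_distance_hits(find_hits(a, b, params),
                                              min_identity, min_len), policy)
    ba = total_bit_score(filter_distance_hits(find_hits(b, a, params),
                                              min_identity, min_len), policy)
    return 0.5 * (ab + ba)


def self_score(a: ReadSet, params: AlignmentParams | None = None,
               min_identity: float = 70.0, min_len: int = 100,
               policy: str = "best-per-query", include_self_hits: bool = True) -> float:
    """Self-comparison bit-score total (a dataset aligned against itself).

    Self-hits (a read matching itself) are included by default, as they are
    in a dataset-versus-itself alignment run.
    """
    ht = filter_distance_hits(find_hits(a, a, params), min_identity, min_len)
    if not include_self_hits:
        ht = HitTable(ht.query_label, ht.subject_label,
                      [h for h in ht.hits if h.query_id != h.subject_id])
    return total_bit_score(ht, policy)


def distance_matrix(datasets: list[ReadSet], params: AlignmentParams | None = None,
                    min_identity: float = 70.0, min_len: int = 100,
                    policy: str = "best-per-query", form: str = "jaccard",
                    include_self_hits: bool = True) -> DistanceMatrix:
    """All-versus-all bit-score Jaccard distances between read datasets.

    For every pair the symmetrized cross total ``AB_s = (A→B + B→A)/2`` and
    the self totals enter :func:`jaccard_distance`.  Deterministic for
    fixed inputs.  A dataset whose post-filter self score is zero has no
    defined distance and raises.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    labels = [d.label for d in datasets]
    if len(set(labels)) != len(labels):
        raise ValueError("dataset labels must be unique")
    selfs = []
    for d in datasets:
        s = self_score(d, params, min_identity, min_len, policy, include_self_hits)
        if s <= 0:
            raise ValueError(f"dataset {d.label!r}: zero self score after filtering; "
                             "distance undefined")
        selfs.append(s)
    n = len(datasets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ab = cross_scores(datasets[i], datasets[j], params,
                              min_identity, min_len, policy)
            ab = min(ab, selfs[i], selfs[j])  # guard tiny sampling excess
            d = jaccard_distance(ab, selfs[i], selfs[j], form)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def distance_matrix_from_hit_tables(labels: list[str], tables,
                                    min_identity: float = 70.0, min_len: int = 100,
                                    policy: str = "best-per-query",
                                    form: str = "jaccard",
                                    include_self_hits: bool = True) -> DistanceMatrix:
    """Assemble a distance matrix from precomputed all-vs-all hit tables.

    ``tables`` maps ``(query_label, subject_label)`` to a HitTable for
    every ordered pair of labels (including self pairs).  This is the
    file-composable route: hit tables may come from :func:`find_hits` or
    from any external aligner's 12-column tabular output.
    """
    if len(labels) < 2:
        raise ValueError("need at least two datasets")
    totals: dict[tuple[str, str], float] = {}
    for qa in labels:
        for sb in labels:
            ht = filter_distance_hits(tables[(qa, sb)], min_identity, min_len)
            if qa == sb and not include_self_hits:
                ht = HitTable(ht.query_label, ht.subject_label,
                              [h for h in ht.hits if h.query_id != h.subject_id])
            totals[(qa, sb)] = total_bit_score(ht, policy)
    for lab in labels:
        if totals[(lab, lab)] <= 0:
            raise ValueError(f"dataset {lab!r}: zero self score after filtering")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ab = 0.5 * (totals[(labels[i], labels[j])] + totals[(labels[j], labels[i])])
            ab = min(ab, totals[(labels[i], labels[i])], totals[(labels[j], labels[j])])
            values[i, j] = values[j, i] = jaccard_distance(
                ab, totals[(labels[i], labels[i])], totals[(labels[j], labels[j])], form)
    return DistanceMatrix(labels=list(labels), values=values)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q-criterion.

    Exactly recovers the generating tree (topology and branch lengths) of
    any additive matrix.  Negative branch lengths are clamped to zero; ties
    in Q are broken deterministically by the ordered label pair.  Returns
    an unrooted tree as a :class:`skbio.TreeNode` with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    names: list[str] = list(dm.labels)
    d = dm.values.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]
        names = [names[x] for x in keep] + [min(names[i], names[j])]
    # join the final three nodes at a central (trifurcating) root using the
    # three-point formulas
    (a, b, c), (da_b, da_c, db_c) = nodes, (d[0, 1], d[0, 2], d[1, 2])
    a.length = max(0.0, 0.5 * (da_b + da_c - db_c))
    b.length = max(0.0, 0.5 * (da_b + db_c - da_c))
    c.length = max(0.0, 0.5 * (da_c + db_c - da_b))
    root = TreeNode()
    root.extend([a, b, c])
    return root


def write_newick(tree: TreeNode, path: str | os.PathLike,
                 outgroup: str | None = None) -> None:
    """Write a tree as Newick, optionally rooted on an outgroup's pendant edge.

    Rooting places the root at the midpoint of the outgroup's branch, so
    the outgroup becomes a direct child of the root.
    """
    if outgroup is not None:
        leaves = {t.name for t in tree.tips()}
        if outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        tree = tree.root_at(tree.find(outgroup), above=True)
    tree.write(os.fspath(path), format="newick")
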