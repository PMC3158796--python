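"""Functional-profile comparison and protein-domain abundance ratios.

Compares two functional category count profiles the way STAMP does: a
two-sided Fisher's exact test per category, Storey's FDR to convert
p-values to q-values, and a three-way filter that keeps categories with
q <= 0.05, at least 100 sequences, and more than a 2-fold ratio between
the proportions.  A separate helper computes the plain abundance ratio
used for protein-domain comparisons: % of domain in dataset X over % of
domain in dataset Y.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class CategoryCounts:
    """Per-dataset functional category counts (category -> non-negative int)."""

    label: str
    counts: pd.Series

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts).astype(int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("categories must be unique")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, label: str | None = None) -> "CategoryCounts":
        """Read a two-column ``category<TAB>count`` TSV (no header, ``#``
        comments skipped)."""
        cats, vals = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{os.fspath(path)}: line {lineno}: expected 2 columns")
                cats.append(parts[0])
                vals.append(int(parts[1]))
        if label is None:
            label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        return cls(label=label, counts=pd.Series(vals, index=cats))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for cat, c in self.counts.items():
                fh.write(f"{cat}\t{int(c)}\n")


def _lchoose(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table ((a, b), (c, d)).

    The p-value sums, over all tables with the observed margins, the
    hypergeometric point probabilities not exceeding the observed one
    (with 1e-7 relative slack, the standard convention).  Degenerate
    margins (an all-zero row or column) give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # hypergeometric log-pmf via log-binomials, vectorized over the support
    logpmf = (_lchoose(col1, support) + _lchoose(n_total - col1, row1 - support)
              - _lchoose(n_total, row1))
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def storey_qvalues(pvalues, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a single-point pi0 estimate.

    ``pi0 = min(1, #{p > lam} / ((1 − lam)·m))`` unless given explicitly
    (``pi0=1`` reproduces Benjamini–Hochberg exactly); then the step-up
    construction ``q_(i) = min_{j>=i} pi0·m·p_(j)/j`` on the sorted
    p-values, mapped back to the input order and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if not 0.0 < lam < 1.0:
            raise ValueError("lambda must lie strictly between 0 and 1")
        pi0 = min(1.0, float(np.sum(p > lam)) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_profiles(A: CategoryCounts, B: CategoryCounts,
                     q_max: float = 0.05, min_seqs: int = 100,
                     min_ratio: float = 2.0,
                     min_seqs_mode: str = "combined") -> pd.DataFrame:
    """STAMP-style enrichment comparison of two category profiles.

    Every category in either profile (absent ones imputed as 0) gets a
    2x2 table ``(countA, totalA − countA; countB, totalB − countB)``, a
    two-sided Fisher p-value, and a Storey q-value computed over all
    categories.  A category passes when ``q <= q_max``, its sequence count
    reaches ``min_seqs`` (combined across both datasets by default,
    per-dataset with ``min_seqs_mode='per-dataset'``), and the fold ratio
    between its proportions exceeds ``min_ratio``.

    Returns a DataFrame with columns category, countA, countB, propA,
    propB, ratio, p, q, passes, sorted by ascending q then p.
    """
    if A.total == 0 or B.total == 0:
        raise ValueError("profiles must have positive totals")
    if min_seqs_mode not in ("combined", "per-dataset"):
        raise ValueError("min_seqs_mode must be 'combined' or 'per-dataset'")
    cats = A.counts.index.union(B.counts.index, sort=False)
    ca = A.counts.reindex(cats, fill_value=0)
    cb = B.counts.reindex(cats, fill_value=0)
    ta, tb = A.total, B.total
    pa = ca / ta
    pb = cb / tb
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(pa, pb)
        lo = np.minimum(pa, pb)
        ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    pvals = np.array([fisher_two_sided(int(ca[c]), ta - int(ca[c]),
                                       int(cb[c]), tb - int(cb[c])) for c in cats])
    qvals = storey_qvalues(pvals)
    if min_seqs_mode == "combined":
        enough = (ca + cb) >= min_seqs
    else:
        enough = (ca >= min_seqs) & (cb >= min_seqs)
    passes = (qvals <= q_max) & enough.to_numpy() & (ratio > min_ratio)
    df = pd.DataFrame({
        "category": cats,
        "countA": ca.to_numpy(),
        "countB": cb.to_numpy(),
        "propA": pa.to_numpy(),
        "propB": pb.to_numpy(),
        "ratio": ratio,
        "p": pvals,
        "q": qvals,
        "passes": passes,
    })
    return df.sort_values(["q", "p", "category"]).reset_index(drop=True)


def domain_abundance_ratio(X: CategoryCounts, Y: CategoryCounts,
                           pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-domain abundance ratio: % of domain in X over % of domain in Y.

    Zero counts (only) are replaced by ``pseudocount`` so ratios stay
    finite; such rows are flagged.  Rows are sorted by descending ratio.
    """
    if X.total == 0 or Y.total == 0:
        raise ValueError("profiles must have positive totals")
    cats = X.counts.index.union(Y.counts.index, sort=False)
    cx = X.counts.reindex(cats, fill_value=0).astype(float)
    cy = Y.counts.reindex(cats, fill_value=0).astype(float)
    flagged = (cx == 0) | (cy == 0)
    cx_adj = cx.where(cx > 0, pseudocount)
    cy_adj = cy.where(cy > 0, pseudocount)
    pct_x = 100.0 * cx_adj / X.total
    pct_y = 100.0 * cy_adj / Y.total
    df = pd.DataFrame({
        "category": cats,
        "countX": cx.astype(int).to_numpy(),
        "countY": cy.astype(int).to_numpy(),
        "pctX": (100.0 * cx / X.total).to_numpy(),
        "pctY": (100.0 * cy / Y.total).to_numpy(),
        "ratio": (pct_x / pct_y).to_numpy(),
        "pseudocount_used": flagged.to_numpy(),
    })
    return df.sort_values("ratio", ascending=False).reset_index(drop=True)
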