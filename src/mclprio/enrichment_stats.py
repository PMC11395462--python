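"""Exact hypergeometric over-representation statistics.

The tail kernel computes P(X >= r) for X ~ Hypergeometric(N, n, R): the
probability that drawing a query set of R genes from an annotated universe of
N genes captures at least r of the n genes carrying a given annotation term.
The one-sided >= convention is the over-representation test used throughout
the pipeline (biomarker-neighborhood enrichment, pathway enrichment, disease
similarity and molecular-function enrichment of top target lists).

The summation is carried out in log space (log-binomials via ``gammaln``,
combined by ``logsumexp``) so that p-values down to ~1e-300 and universes up
to 1e6 genes neither overflow nor underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "hypergeom_tail",
    "EnrichmentRow",
    "enrich_terms",
    "benjamini_hochberg",
    "NEGLOG_P_CLAMP",
]

# p-values are clamped to this floor before any log transform
NEGLOG_P_CLAMP = 1e-300


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_tail(r: int, R: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= r | N, n, R).

    Parameters
    ----------
    r : observed hits (members of the query set carrying the term)
    R : query-set size
    n : term size in the universe
    N : annotated-universe size

    The sum ``sum_{x=r}^{min(R,n)} C(n,x) C(N-n,R-x) / C(N,R)`` is evaluated
    in log space. ``r == 0`` returns exactly 1.
    """
    r, R, n, N = int(r), int(R), int(n), int(N)
    if N < 0 or not (0 <= n <= N) or not (0 <= R <= N):
        raise ValueError(f"invalid hypergeometric arguments (r={r}, R={R}, n={n}, N={N})")
    upper = min(R, n)
    if not (0 <= r <= upper):
        raise ValueError(f"hits r={r} outside [0, min(R, n)={upper}]")
    if r == 0:
        return 1.0
    x = np.arange(r, upper + 1, dtype=float)
    log_terms = _log_binom(float(n), x) + _log_binom(float(N - n), float(R) - x)
    log_p = logsumexp(log_terms) - _log_binom(float(N), float(R))
    return float(min(1.0, np.exp(log_p)))


@dataclass(frozen=True)
class EnrichmentRow:
    """One term of an enrichment table: (term, r, R, n, N, p)."""

    term: str
    r: int
    R: int
    n: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.r <= min(self.R, self.n)) or self.R > self.N or self.n > self.N:
            raise ValueError(f"inconsistent enrichment row {self}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p out of (0, 1] in {self}")


def enrich_terms(
    query_set: Iterable[int],
    annotation_sets: Mapping[str, Iterable[int]] | Sequence,
    universe: Iterable[int],
) -> list[EnrichmentRow]:
    """Test a query gene set against a flat annotation collection.

    The universe is the set of genes carrying at least one annotation; the
    query is intersected with it to define R. One row per term with r > 0,
    sorted ascending by p with ties broken by term name.

    ``annotation_sets`` may be a mapping name -> members or a sequence of
    objects with ``name`` and ``members`` attributes (e.g. GeneSet).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty annotation universe")
    query = set(query_set) & universe
    R, N = len(query), len(universe)
    if isinstance(annotation_sets, Mapping):
        items = list(annotation_sets.items())
    else:
        items = [(gs.name, gs.members) for gs in annotation_sets]
    rows: list[EnrichmentRow] = []
    for term, members in items:
        members = set(members) & universe
        r = len(query & members)
        if r == 0:
            continue
        p = hypergeom_tail(r, R, len(members), N)
        rows.append(EnrichmentRow(term, r, R, len(members), N, p))
    rows.sort(key=lambda row: (row.p, row.term))
    return rows


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; tables report raw p)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
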