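"""Hypergeometric chain scoring and genome-wide expectation filtering.

For a chain of k genes (interstitial genes counted) of which l share an
annotation term carried by m genes genome-wide, the chance probability of the
arrangement is the upper hypergeometric tail

    p = P(X >= l),  X ~ Hypergeometric(N, m, k)
      = sum_{i=l}^{min(k,m)} C(m, i) C(N-m, k-i) / C(N, k)

with N the number of genes in the genome. The p-value is corrected for the
number of opportunities to observe such a chain anywhere in the genome, which
for all practical purposes equals N, giving the expectation value e = p * N.
Chains with e below a threshold (default 0.01) are accepted as paraclusters;
this is deliberately conservative and tends to underestimate clustering.

When the common subset holds several terms, every term is scored and the
*largest* p (the most frequent, least surprising term) is kept -- again the
conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import comb
from typing import Sequence

from scipy.stats import hypergeom

from .chaining import Chain
from .genome_model import AnnotationDataset

__all__ = [
    "EXACT_N_LIMIT",
    "ChainScore",
    "hypergeom_tail",
    "score_chain",
    "score_chains",
    "filter_significant",
]

#: exact integer arithmetic is used up to this genome size, log-gamma beyond
EXACT_N_LIMIT = 10_000


@dataclass(frozen=True)
class ChainScore:
    p_value: float
    e_value: float
    m_used: int
    term_used: str


def _validate(N: int, m: int, k: int, l: int) -> None:
    if N < 0:
        raise ValueError(f"N must be >= 0, got N={N}")
    if not 0 <= m <= N:
        raise ValueError(f"m must satisfy 0 <= m <= N, got m={m}, N={N}")
    if not 0 <= k <= N:
        raise ValueError(f"k must satisfy 0 <= k <= N, got k={k}, N={N}")
    if not 0 <= l <= k:
        raise ValueError(f"l must satisfy 0 <= l <= k, got l={l}, k={k}")


def _tail_exact(N: int, m: int, k: int, l: int) -> float:
    num = sum(comb(m, i) * comb(N - m, k - i) for i in range(l, min(k, m) + 1))
    return float(Fraction(num, comb(N, k)))


def hypergeom_tail(N: int, m: int, k: int, l: int) -> float:
    """P(X >= l) for X ~ Hypergeometric(population N, successes m, draws k).

    Exact integer binomials for N <= EXACT_N_LIMIT; scipy's log-gamma survival
    function beyond (the two paths agree to floating precision and are
    cross-checked in the test suite).
    """
    _validate(N, m, k, l)
    if l <= 0:
        return 1.0
    if l > min(k, m):
        return 0.0
    if N <= EXACT_N_LIMIT:
        return _tail_exact(N, m, k, l)
    return float(hypergeom.sf(l - 1, N, m, k))


def score_chain(chain: Chain, dataset: AnnotationDataset, N: int) -> ChainScore:
    """Score one chain against its dataset's genome-wide term frequencies.

    Every common term is scored with its frequency m; the maximum tail
    probability wins (ties broken by term id order, for determinism).
    e = p * N.
    """
    if not chain.common_terms:
        raise ValueError("chain has an empty common term set")
    best: tuple[float, int, str] | None = None
    for term in sorted(chain.common_terms):
        if term not in dataset.freq:
            raise ValueError(
                f"term {term!r} missing from frequencies of dataset {dataset.name!r}"
            )
        m = dataset.freq[term]
        p = hypergeom_tail(N, m, chain.k, chain.l)
        if best is None or p > best[0]:
            best = (p, m, term)
    p, m, term = best
    return ChainScore(p_value=p, e_value=p * N, m_used=m, term_used=term)


def score_chains(
    chains: Sequence[Chain], dataset: AnnotationDataset, N: int
) -> list[Chain]:
    """Return chains with p, e, m_used and term_used filled in."""
    out = []
    for chain in chains:
        s = score_chain(chain, dataset, N)
        out.append(
            replace(
                chain,
                p_value=s.p_value,
                e_value=s.e_value,
                m_used=s.m_used,
                term_used=s.term_used,
            )
        )
    return out


def filter_significant(chains: Sequence[Chain], threshold: float = 0.01) -> list[Chain]:
    """Keep chains with expectation value strictly below ``threshold``.

    The default 0.01 practically eliminates detections on permuted genomes;
    looser thresholds (0.05, 0.1, 0.15) are supported for sensitivity sweeps.
    """
    for c in chains:
        if c.e_value is None:
            raise ValueError("chains must be scored before filtering")
    return [c for c in chains if c.e_value < threshold]
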