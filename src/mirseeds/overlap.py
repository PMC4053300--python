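"""Hypergeometric overlap significance between two seed sets.

The point probability of sharing exactly k elements between a set of M and
a set of n drawn from a universe of N possible 7-mers is

    P_k = C(M, k) * C(N - M, n - k) / C(N, n),

and the significance of an observed overlap is the inclusive upper tail
P(X >= k).  The point mass is evaluated in log space (log-gamma binomials)
so that N = 16384-scale parameters never overflow.
"""
from __future__ import annotations

import math

from scipy.special import gammaln

from .types import OverlapResult, SEQ_BASES


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_point(N: int, M: int, n: int, k: int) -> float:
    """Exact point probability P_k of an overlap of exactly k.

    Zero when the configuration is impossible (k > min(M, n) or
    n - k > N - M).
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"invalid hypergeometric parameters N={N}, M={M}, "
                         f"n={n}, k={k}")
    if k > min(M, n) or n - k > N - M:
        return 0.0
    # P_k is symmetric in (M, n); canonicalize so the two orders give the
    # same floating-point value bit for bit
    M, n = max(M, n), min(M, n)
    log_p = _log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n)
    return math.exp(log_p)


def hypergeom_tail(N: int, M: int, n: int, k: int) -> float:
    """Inclusive upper-tail P(X >= k) by summing point probabilities."""
    if k <= max(0, n - (N - M)):  # whole support: exactly 1
        hypergeom_point(N, M, n, k)  # still validate parameters
        return 1.0
    return min(1.0, sum(hypergeom_point(N, M, n, j)
                        for j in range(k, min(M, n) + 1)))


def _validate_seed_set(seeds, name: str, k: int = 7) -> set[str]:
    out = set()
    for s in seeds:
        if len(s) != k or set(s) - SEQ_BASES:
            raise ValueError(f"{name}: invalid {k}-mer {s!r}")
        out.add(s)
    return out


def overlap_test(set_a, set_b, N: int = 16384, k_len: int = 7) -> OverlapResult:
    """Hypergeometric test of whether two seed sets overlap more than
    chance allows.

    Symmetric in its two arguments; k is the intersection size and the
    P value the inclusive upper tail from k.  ``N`` is the universe of
    possible k-mers (default 4^7 = 16384) and is configurable together
    with ``k_len`` for non-7-mer experiments.
    """
    a = _validate_seed_set(set_a, "set_a", k_len)
    b = _validate_seed_set(set_b, "set_b", k_len)
    if len(a) > N or len(b) > N:
        raise ValueError("seed set larger than universe")
    M, n = len(a), len(b)
    k = len(a & b)
    return OverlapResult(
        N=N, M=M, n=n, k=k,
        p_point=hypergeom_point(N, M, n, k),
        p_value=hypergeom_tail(N, M, n, k),
    )


def read_seed_list(path: str, k: int = 7) -> set[str]:
    """Read a plain-text seed list: one sequence per line, '#' comments.

    Sequences are uppercased and U -> T normalized (RNA input accepted),
    then deduplicated.  A line of the wrong length is an error that names
    the line.
    """
    seeds: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            seq = line.upper().replace("U", "T")
            if len(seq) != k or set(seq) - SEQ_BASES:
                raise ValueError(f"{path}:{lineno}: not a valid {k}-mer: {line!r}")
            seeds.add(seq)
    return seeds
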