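"""Isotope registry, binomial P-terms, S survival normalizers and caching.

The probability that exactly ``k`` of ``n`` unlabeled atoms of one element
are heavy by natural abundance is the binomial term

    P[n][k] = C(n, k) * p**k * (1 - p)**(n - k)

with ``p`` the element's heavy-isotope natural-abundance fraction.  The
diagonal survival factor

    S[x] = (1 - p)**(N - x)

is the probability that none of the ``N - x`` unlabeled atoms of an
``N``-atom element picks up a heavy isotope, i.e. the fraction of a
corrected isotopologue's intensity that stays at its own peak.

Because products of many large coefficient factors and tiny probability
factors can overflow or lose precision when grouped naively, the default
P-term evaluation (``org``) interleaves one binomial-coefficient factor
with one probability factor per step so intermediates stay near the final
magnitude.  Four alternative evaluations (exact factorials, exact
multiplicative coefficient, log-gamma, and a log10 interleaving) are kept
as a numerics cross-check suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import comb as _scipy_comb
from scipy.special import gammaln as _gammaln

__all__ = [
    "IsotopeSpec",
    "PTable",
    "STable",
    "TableCache",
    "DEFAULT_ISOTOPES",
    "binomial_p_term",
    "build_p_table",
    "build_s_table",
    "get_or_build",
    "P_TERM_METHODS",
]


@dataclass(frozen=True)
class IsotopeSpec:
    """A tracer isotope: label name, element and natural-abundance fraction."""

    label: str      # e.g. "13C"
    element: str    # e.g. "C"
    p: float        # natural abundance of the heavy isotope, in [0, 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"natural abundance must be in [0, 1): {self.p}")


#: Default natural-abundance fractions for the common tracer isotopes.
#: User configuration may override any of these.
DEFAULT_ISOTOPES: Dict[str, IsotopeSpec] = {
    "13C": IsotopeSpec("13C", "C", 0.01109),
    "15N": IsotopeSpec("15N", "N", 0.0037),
    "2H": IsotopeSpec("2H", "H", 0.00015),
}


def _check_args(n: int, k: int, p: float) -> None:
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    if not (0.0 <= p < 1.0):
        raise ValueError(f"require 0 <= p < 1, got p={p}")


def _p_org(n: int, k: int, p: float) -> float:
    # Interleave one coefficient factor (n-k+j)/j with one p factor and,
    # while any remain, one (1-p) factor per step; leftover (1-p) powers
    # are appended one at a time.  Keeps intermediates near the final
    # magnitude instead of forming a huge coefficient times tiny powers.
    q = 1.0 - p
    r = 1.0
    nk = n - k
    m = min(k, nk)
    for j in range(1, k + 1):
        r *= (nk + j) / j
        r *= p
        if j <= m:
            r *= q
    for _ in range(nk - m):
        r *= q
    return r


def _p_choose(n: int, k: int, p: float) -> float:
    coeff = math.factorial(n) // (math.factorial(k) * math.factorial(n - k))
    return float(coeff) * p**k * (1.0 - p) ** (n - k)


def _p_comb(n: int, k: int, p: float) -> float:
    coeff = _scipy_comb(n, k, exact=True)
    return float(coeff) * p**k * (1.0 - p) ** (n - k)


def _p_comb2(n: int, k: int, p: float) -> float:
    log_coeff = _gammaln(n + 1) - _gammaln(k + 1) - _gammaln(n - k + 1)
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    return float(
        math.exp(log_coeff + k * math.log(p) + (n - k) * math.log1p(-p))
    )


def _p_log_real(n: int, k: int, p: float) -> float:
    # log10 version of the interleaving loop.
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    q = 1.0 - p
    lp, lq = math.log10(p), math.log10(q)
    total = 0.0
    nk = n - k
    for j in range(1, k + 1):
        total += math.log10((nk + j) / j)
        total += lp
    total += nk * lq
    return 10.0**total


P_TERM_METHODS = {
    "org": _p_org,
    "choose": _p_choose,
    "comb": _p_comb,
    "comb2": _p_comb2,
    "logReal": _p_log_real,
}


def binomial_p_term(n: int, k: int, p: float, method: str = "org") -> float:
    """Evaluate P[n][k] = C(n,k) p^k (1-p)^(n-k) by the chosen method.

    Methods: ``org`` (interleaved product, the default used in table
    construction), ``choose`` (exact integer factorials), ``comb`` (exact
    multiplicative coefficient), ``comb2`` (log-gamma), ``logReal``
    (base-10 logarithmic interleaving).
    """
    _check_args(n, k, p)
    try:
        fn = P_TERM_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(P_TERM_METHODS)}"
        ) from None
    return fn(n, k, p)


@dataclass(frozen=True)
class PTable:
    """Lower-triangular table of binomial P-terms for one isotope.

    ``values[n, k]`` holds P[n][k] for ``0 <= k <= n <= nmax``; entries
    with ``k > n`` are zero.  Each row sums to one.
    """

    values: np.ndarray
    nmax: int
    p: float

    def __getitem__(self, idx: Tuple[int, int]) -> float:
        return float(self.values[idx])


@dataclass(frozen=True)
class STable:
    """Survival normalizers S[x] = (1-p)^(N-x) for an N-atom element.

    Monotone increasing in ``x`` with ``S[N] = 1``.
    """

    values: np.ndarray
    n_atoms: int
    p: float

    def __getitem__(self, x: int) -> float:
        return float(self.values[x])


def build_p_table(nmax: int, p: float) -> PTable:
    """Build the full P table up to ``nmax`` with the interleaved method."""
    if nmax < 0:
        raise ValueError(f"nmax must be >= 0, got {nmax}")
    _check_args(0, 0, p)
    values = np.zeros((nmax + 1, nmax + 1), dtype=float)
    for n in range(nmax + 1):
        for k in range(n + 1):
            values[n, k] = _p_org(n, k, p)
    values.setflags(write=False)
    return PTable(values=values, nmax=nmax, p=p)


def build_s_table(n_atoms: int, p: float) -> STable:
    """Build S[x] = (1-p)^(N-x) for x = 0..N."""
    if n_atoms < 0:
        raise ValueError(f"n_atoms must be >= 0, got {n_atoms}")
    _check_args(0, 0, p)
    q = 1.0 - p
    values = np.array([q ** (n_atoms - x) for x in range(n_atoms + 1)], dtype=float)
    values.setflags(write=False)
    return STable(values=values, n_atoms=n_atoms, p=p)


@dataclass
class TableCache:
    """Cache of (PTable, STable) pairs keyed by (isotope label, p, size).

    The abundance ``p`` is part of the key so user-overridden abundances
    never collide with defaults.  A disabled cache always rebuilds.
    """

    enabled: bool = True
    _store: Dict[Tuple[str, float, int], Tuple[PTable, STable]] = field(
        default_factory=dict, repr=False
    )
    hits: int = 0
    misses: int = 0

    def clear(self) -> None:
        self._store.clear()
        self.hits = 0
        self.misses = 0


def get_or_build(
    cache: Optional[TableCache], iso: IsotopeSpec, size: int
) -> Tuple[PTable, STable]:
    """Return the P and S tables for *iso* at element count *size*.

    Tables depend only on the element's atom count and abundance, not on
    the molecule, so any two molecules sharing both reuse one build.
    """
    if cache is None or not cache.enabled:
        if cache is not None:
            cache.misses += 1
        return build_p_table(size, iso.p), build_s_table(size, iso.p)
    key = (iso.label, iso.p, size)
    hit = cache._store.get(key)
    if hit is not None:
        cache.hits += 1
        return hit
    cache.misses += 1
    tables = (build_p_table(size, iso.p), build_s_table(size, iso.p))
    cache._store[key] = tables
    return tables
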