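"""Core n-dimensional natural-abundance correction.

An isotopologue intensity array is indexed by heavy-label counts, one
dimension per tracer isotope (up to three).  Natural abundance moves
intensity upward in every dimension: a molecule carrying ``i_e`` tracer
atoms of element ``e`` appears at index ``x >= i`` with probability

    K(x, i) = prod_e P_e[N_e - i_e][x_e - i_e]

where ``N_e`` is the element's atom count and ``P_e`` its binomial table.
The forward map (``add_na``) convolves a clean distribution with this
kernel; the inverse is a clamped ascending triangular sweep
(``solve_pass``) refined iteratively (``correct``) until the
re-contaminated reconstruction stops improving against the observation.

The kernel diagonal ``K(x, x)`` equals the product of per-element
survival factors ``S_e[x_e]``, the fraction of a corrected isotopologue
that stays at its own peak.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .isotopes import IsotopeSpec, PTable, STable, TableCache, get_or_build

__all__ = [
    "LabelOrder",
    "CorrectionResult",
    "NACorrector",
    "iterate_upto",
    "add_na",
    "solve_pass",
    "correct",
]


@dataclass(frozen=True)
class LabelOrder:
    """Ordered tuple of tracer isotopes, one per array dimension."""

    isotopes: Tuple[IsotopeSpec, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.isotopes) <= 3:
            raise ValueError("1 to 3 tracer isotopes are supported")
        elements = [iso.element for iso in self.isotopes]
        if len(set(elements)) != len(elements):
            raise ValueError(f"repeated tracer element in {elements}")

    def __len__(self) -> int:
        return len(self.isotopes)

    def __iter__(self):
        return iter(self.isotopes)


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of the iterative correction.

    ``corrected`` is the natural-abundance-free estimate, ``reconstructed``
    its re-contamination (used for convergence checking and predicted-peak
    QC), ``iterations`` the number of accepted refinement cycles and
    ``residual`` the sum of absolute differences between observation and
    reconstruction for the returned (best) iterate.
    """

    corrected: np.ndarray
    reconstructed: np.ndarray
    iterations: int
    residual: float


def iterate_upto(
    x: Sequence[int], inclusive: bool = False
) -> Iterator[Tuple[int, ...]]:
    """Stream all index tuples componentwise below (or up to) *x*.

    With ``inclusive=False`` every tuple ``i`` with ``0 <= i_e <= x_e``
    except ``x`` itself is produced (penultimate iteration); with
    ``inclusive=True`` the bound ``x`` is produced last (ultimate
    iteration).  Tuples appear in ascending C order, so each one is
    componentwise-dominated only by later tuples.
    """
    x = tuple(int(v) for v in x)
    stop = x if inclusive else None
    for i in itertools.product(*(range(v + 1) for v in x)):
        if i == x and stop is None:
            continue
        yield i


class NACorrector:
    """Natural-abundance corrector bound to one dataset shape and order.

    The constructor fetches (or builds) the per-isotope P and S tables
    for the given maxima and specializes the sweep to the dataset's
    dimensionality: one-dimensional data uses flat integer indexing, the
    general path enumerates index tuples.
    """

    def __init__(
        self,
        maxima: Sequence[int],
        order: LabelOrder,
        cache: Optional[TableCache] = None,
    ) -> None:
        maxima = tuple(int(m) for m in maxima)
        if len(maxima) != len(order):
            raise ValueError(
                f"shape {maxima} does not match {len(order)} tracer isotope(s)"
            )
        if any(m < 0 for m in maxima):
            raise ValueError(f"negative maximum label count in {maxima}")
        self.maxima = maxima
        self.order = order
        self.ptables: Tuple[PTable, ...] = ()
        self.stables: Tuple[STable, ...] = ()
        for iso, n in zip(order, maxima):
            pt, st = get_or_build(cache, iso, n)
            self.ptables += (pt,)
            self.stables += (st,)
        self._ndim = len(maxima)

    # -- kernel -------------------------------------------------------

    def kernel(self, x: Sequence[int], i: Sequence[int]) -> float:
        """K(x, i): probability that a molecule labeled *i* is observed at *x*."""
        x = tuple(x)
        i = tuple(i)
        if any(iv > xv for iv, xv in zip(i, x)):
            raise ValueError(f"kernel requires i <= x componentwise: {i} !<= {x}")
        r = 1.0
        for e in range(self._ndim):
            r *= self.ptables[e].values[self.maxima[e] - i[e], x[e] - i[e]]
        return r

    # -- forward contamination ----------------------------------------

    def add_na(self, clean: np.ndarray) -> np.ndarray:
        """Contaminate a clean distribution with natural abundance.

        ``out[x] = sum_{i <= x} clean[i] * K(x, i)``.  Total intensity is
        conserved because the index space spans 0..N_e in every dimension.
        """
        clean = self._as_array(clean)
        if self._ndim == 1:
            P = self.ptables[0].values
            N = self.maxima[0]
            out = np.zeros_like(clean)
            for x in range(N + 1):
                acc = 0.0
                for i in range(x + 1):
                    acc += clean[i] * P[N - i, x - i]
                out[x] = acc
            return out
        out = np.zeros_like(clean)
        for x in iterate_upto(self.maxima, inclusive=True):
            acc = 0.0
            for i in iterate_upto(x, inclusive=True):
                acc += clean[i] * self._k(x, i)
            out[x] = acc
        return out

    # -- inverse sweep ------------------------------------------------

    def solve_pass(self, data: np.ndarray, clamp: bool = True) -> np.ndarray:
        """One ascending triangular sweep of the inverse problem.

        ``corr[x] = (data[x] - sum_{i < x} corr[i] * K(x, i)) / K(x, x)``
        using already-updated lower entries; with ``clamp`` each entry is
        floored at zero as it is produced, so over-subtraction cannot
        propagate negative mass upward.
        """
        data = self._as_array(data)
        if self._ndim == 1:
            P = self.ptables[0].values
            S = self.stables[0].values
            N = self.maxima[0]
            corr = np.zeros_like(data)
            for x in range(N + 1):
                acc = data[x]
                for i in range(x):
                    acc -= corr[i] * P[N - i, x - i]
                v = acc / S[x]
                corr[x] = max(v, 0.0) if clamp else v
            return corr
        corr = np.zeros_like(data)
        sdiag = self._s_diag
        for x in iterate_upto(self.maxima, inclusive=True):
            acc = data[x]
            for i in iterate_upto(x, inclusive=False):
                acc -= corr[i] * self._k(x, i)
            v = acc / sdiag(x)
            corr[x] = max(v, 0.0) if clamp else v
        return corr

    # -- iterative refinement -----------------------------------------

    def correct(self, data: np.ndarray, max_iterations: int = 100) -> CorrectionResult:
        """Iteratively refine the correction until no further improvement.

        Starts from one clamped sweep; each cycle re-contaminates the
        estimate, measures the sum-of-absolute residual against the
        observation, and — while the residual strictly decreases — adds a
        signed sweep of the residual to the estimate (clamping the
        combined estimate at zero).  Returns the best iterate seen.
        Deterministic; no randomness.
        """
        data = self._as_array(data)
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite intensities in input")
        if np.any(data < 0):
            raise ValueError("negative intensities in input")

        corr = self.solve_pass(data, clamp=True)
        calc = self.add_na(corr)
        err = float(np.abs(data - calc).sum())
        best, best_calc, best_err, best_cycle = corr, calc, err, 1

        cycle = 1
        while cycle < max_iterations and best_err > 0.0:
            resid = data - calc
            delta = self.solve_pass(resid, clamp=False)
            corr = np.maximum(corr + delta, 0.0)
            calc = self.add_na(corr)
            err = float(np.abs(data - calc).sum())
            cycle += 1
            if err < best_err:
                best, best_calc, best_err, best_cycle = corr, calc, err, cycle
            else:
                break
        return CorrectionResult(
            corrected=best,
            reconstructed=best_calc,
            iterations=best_cycle,
            residual=best_err,
        )

    # -- helpers ------------------------------------------------------

    def _k(self, x: Tuple[int, ...], i: Tuple[int, ...]) -> float:
        r = 1.0
        for e in range(self._ndim):
            r *= self.ptables[e].values[self.maxima[e] - i[e], x[e] - i[e]]
        return r

    def _s_diag(self, x: Tuple[int, ...]) -> float:
        r = 1.0
        for e in range(self._ndim):
            r *= self.stables[e].values[x[e]]
        return r

    def _as_array(self, arr: np.ndarray) -> np.ndarray:
        out = np.asarray(arr, dtype=float)
        expect = tuple(m + 1 for m in self.maxima)
        if out.shape != expect:
            raise ValueError(f"array shape {out.shape} does not match {expect}")
        return out.copy()


# -- module-level convenience wrappers --------------------------------


def _corrector(
    arr: np.ndarray, order: LabelOrder, cache: Optional[TableCache]
) -> NACorrector:
    maxima = tuple(s - 1 for s in np.asarray(arr, dtype=float).shape)
    return NACorrector(maxima, order, cache)


def add_na(
    clean: np.ndarray, order: LabelOrder, cache: Optional[TableCache] = None
) -> np.ndarray:
    """Forward natural-abundance contamination of a clean array."""
    return _corrector(clean, order, cache).add_na(clean)


def solve_pass(
    data: np.ndarray,
    order: LabelOrder,
    cache: Optional[TableCache] = None,
    clamp: bool = True,
) -> np.ndarray:
    """Single clamped triangular sweep removing natural abundance."""
    return _corrector(data, order, cache).solve_pass(data, clamp=clamp)


def correct(
    data: np.ndarray,
    order: LabelOrder,
    cache: Optional[TableCache] = None,
    max_iterations: int = 100,
) -> CorrectionResult:
    """Full iterative natural-abundance correction of an observed array."""
    return _corrector(data, order, cache).correct(data, max_iterations=max_iterations)
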