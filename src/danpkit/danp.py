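"""DANP supermatrix stages: unweighted/weighted supermatrices and limiting weights.

The DEMATEL-based ANP (DANP) replaces the pairwise-comparison input of the
classical analytic network process with the DEMATEL total-influence matrix:

* the *unweighted supermatrix* ``W`` is T normalized row-wise inside each
  dimension block and then transposed, so each block-column of W distributes a
  unit of influence across the criteria of one dimension;
* the *weighted supermatrix* ``V`` rescales each block of W by the
  transposed row-normalized dimension matrix ``Q`` (from T_D), which makes
  every column of V stochastic;
* the *limiting supermatrix* is the convergent power of V; its common column
  is the global influence-weight vector (the stationary distribution of the
  column-stochastic influence chain).

Dimension weights are the sums of their member criteria's global weights, and
local weights renormalize criteria within their dimension, so that
``global = dimension weight x local weight`` holds identically before any
display rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .factor_model import FactorSystem

__all__ = [
    "SupermatrixError",
    "ConvergenceError",
    "UnweightedSupermatrix",
    "WeightedSupermatrix",
    "WeightTable",
    "unweighted_supermatrix",
    "weight_supermatrix",
    "limit_supermatrix",
    "limit_weights",
    "rank_weights",
]


class SupermatrixError(ValueError):
    """Structural defect in a supermatrix construction (zero row sums, bad columns)."""


class ConvergenceError(RuntimeError):
    """The weighted supermatrix power iteration did not reach a unique steady state."""


@dataclass(frozen=True)
class UnweightedSupermatrix:
    """Block-wise row-normalized, transposed total-influence matrix."""

    W: np.ndarray


@dataclass(frozen=True)
class WeightedSupermatrix:
    """Column-stochastic supermatrix V and the dimension weighting matrix Q."""

    V: np.ndarray
    Q: np.ndarray


@dataclass(frozen=True)
class WeightTable:
    """Limiting influence weights at criterion and dimension level.

    ``criteria`` is indexed by criterion code with columns ``dimension``,
    ``global_weight``, ``global_rank``, ``local_weight``, ``local_rank``;
    ``dimensions`` is indexed by dimension code with columns ``weight``,
    ``rank``.  Global weights sum to 1; local weights sum to 1 within each
    dimension; a dimension's weight is the sum of its criteria's global
    weights.
    """

    criteria: pd.DataFrame
    dimensions: pd.DataFrame


def unweighted_supermatrix(T: np.ndarray, system: FactorSystem) -> UnweightedSupermatrix:
    """Normalize T row-wise within each dimension block, then transpose.

    Inside block (o, p) each row segment is divided by its within-block sum, so
    after transposition every block-column of W sums to 1.  A zero within-block
    row sum means a criterion exerts no influence on an entire dimension and is
    reported as an isolated criterion rather than patched.
    """
    T = np.asarray(T, dtype=float)
    slices = system.block_slices()
    codes = system.criterion_codes
    dcodes = system.dimension_codes
    Ta = np.empty_like(T)
    for o, so in enumerate(slices):
        for p, sp in enumerate(slices):
            block = T[so, sp]
            row_sums = block.sum(axis=1)
            if np.any(row_sums <= 0):
                k = int(np.argmax(row_sums <= 0))
                raise SupermatrixError(
                    f"criterion {codes[so.start + k]!r} has zero total influence on "
                    f"dimension {dcodes[p]!r}; cannot normalize an isolated criterion"
                )
            Ta[so, sp] = block / row_sums[:, None]
    return UnweightedSupermatrix(W=Ta.T.copy())


def weight_supermatrix(
    W: UnweightedSupermatrix | np.ndarray,
    T_D: np.ndarray,
    system: FactorSystem,
    column_tol: float = 1e-6,
) -> WeightedSupermatrix:
    """Scale W's blocks by the transposed row-normalized dimension matrix.

    ``Q = (T_D / row sums)^T`` so ``Q[o, p] = T_D[p, o] / d_p``; block (o, p)
    of V is ``Q[o, p]`` times block (o, p) of W.  Every column of V then sums
    to 1 by construction; a raw column sum further than ``column_tol`` from 1
    indicates an upstream violation and raises, otherwise columns are
    renormalized to sum exactly 1.
    """
    W = W.W if isinstance(W, UnweightedSupermatrix) else np.asarray(W, dtype=float)
    T_D = np.asarray(T_D, dtype=float)
    d = T_D.sum(axis=1)
    if np.any(d <= 0):
        o = int(np.argmax(d <= 0))
        raise SupermatrixError(f"dimension {system.dimension_codes[o]!r} has zero total influence row sum")
    Q = (T_D / d[:, None]).T
    slices = system.block_slices()
    scale = np.empty_like(W)
    for o, so in enumerate(slices):
        for p, sp in enumerate(slices):
            scale[so, sp] = Q[o, p]
    V = W * scale
    col_sums = V.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) >= column_tol):
        j = int(np.argmax(np.abs(col_sums - 1.0)))
        raise SupermatrixError(
            f"column {system.criterion_codes[j]!r} of the weighted supermatrix sums to "
            f"{col_sums[j]:.8f}, not 1; upstream block normalization is broken"
        )
    return WeightedSupermatrix(V=V / col_sums, Q=Q)


def _column_spread(P: np.ndarray) -> float:
    return float((P.max(axis=1) - P.min(axis=1)).max())


def limit_weights(
    V: WeightedSupermatrix | np.ndarray,
    tol: float = 1e-10,
    max_squarings: int = 64,
) -> np.ndarray:
    """Global weight vector: the common column of ``lim V^rho``.

    Computed by repeated squaring until both the maximum spread across columns
    and the change between successive iterates fall below ``tol``.  A chain
    that stops changing while its columns still disagree is either periodic
    (period 2 — resolved by the Cesaro average of consecutive powers) or
    reducible (several stationary distributions — reported as an error, since
    the weights would depend on initialization).  The limiting column is
    renormalized to sum exactly 1.
    """
    P = V.V if isinstance(V, WeightedSupermatrix) else np.asarray(V, dtype=float)
    col_sums = P.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) > 1e-8) or np.any(P < -1e-12):
        raise SupermatrixError("limit_weights requires a column-stochastic matrix")
    base = P
    for _ in range(max_squarings):
        P_next = P @ P
        change = float(np.abs(P_next - P).max())
        P = P_next
        if change < tol:
            break
    spread = _column_spread(P)
    if spread >= tol * 10:
        # Period-2 chains alternate between two limits; their Cesaro average
        # is the unique stationary distribution when the chain is irreducible.
        cesaro = (P + base @ P) / 2.0
        if _column_spread(cesaro) < tol * 10:
            P = cesaro
        else:
            raise ConvergenceError(
                f"weighted supermatrix power did not reach a common column "
                f"(residual spread {spread:.3e}); the influence network is "
                "reducible or disconnected"
            )
    w = P.mean(axis=1)
    return w / w.sum()


def rank_weights(weights: Sequence[float]) -> np.ndarray:
    """Ranks with 1 for the largest weight; ties broken by canonical factor order.

    Equal weights receive consecutive ranks in input order, so the ranking is
    always a permutation of ``1 .. k`` and fully deterministic.
    """
    w = np.asarray(weights, dtype=float)
    order = np.lexsort((np.arange(len(w)), -w))
    ranks = np.empty(len(w), dtype=int)
    ranks[order] = np.arange(1, len(w) + 1)
    return ranks


def limit_supermatrix(
    V: WeightedSupermatrix | np.ndarray,
    system: FactorSystem,
    tol: float = 1e-10,
    max_squarings: int = 64,
) -> WeightTable:
    """Limiting weights with the derived dimension/local weight tables and ranks.

    Dimension weights are sums of member criteria's limiting global weights;
    local weights divide each global weight by its dimension's weight.  All
    ranking happens on full-precision values; display rounding is downstream.
    """
    global_w = limit_weights(V, tol=tol, max_squarings=max_squarings)
    slices = system.block_slices()
    dim_w = np.array([global_w[s].sum() for s in slices])
    local_w = np.concatenate([global_w[s] / dim_w[o] for o, s in enumerate(slices)])
    local_rank = np.concatenate([rank_weights(global_w[s]) for s in slices])
    criteria = pd.DataFrame(
        {
            "dimension": [c.dimension_code for c in system.criteria],
            "global_weight": global_w,
            "global_rank": rank_weights(global_w),
            "local_weight": local_w,
            "local_rank": local_rank,
        },
        index=pd.Index(system.criterion_codes, name="factor"),
    )
    dimensions = pd.DataFrame(
        {"weight": dim_w, "rank": rank_weights(dim_w)},
        index=pd.Index(system.dimension_codes, name="factor"),
    )
    return WeightTable(criteria=criteria, dimensions=dimensions)
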