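"""DEMATEL: expert-panel aggregation, total influence, and influence indices.

The DEMATEL (Decision-Making Trial and Evaluation Laboratory) stages implemented
here turn a panel of integer 0-4 pairwise direct-influence judgments into

* the direct-influence matrix ``A`` (entrywise panel mean),
* its normalization ``D = A / delta`` with ``delta`` the largest row or column
  sum of ``A``,
* the total-influence matrix ``T = D (I - D)^-1`` — the closed form of the
  geometric series ``D + D^2 + ...`` accumulating direct and all indirect
  influence,
* the per-factor indices: give influence ``u`` (row sums of T), receive
  influence ``r`` (column sums), influence center ``u + r`` and net cause/effect
  ``u - r``,
* the panel consensus gap — the mean relative change of ``A`` when the most
  recently added expert is removed, whose complement is the conventional
  "confidence level" quoted for DEMATEL surveys.

Criteria-level matrices live over the flat canonical criterion order of a
:class:`~danpkit.factor_model.FactorSystem`; the dimension-level matrix ``T_D``
collapses each block of ``T`` to its arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .factor_model import FactorSystem, normalize_code

__all__ = [
    "SCALE_MIN",
    "SCALE_MAX",
    "ExpertMatrix",
    "DirectInfluence",
    "NormalizedInfluence",
    "TotalInfluence",
    "ConsensusReport",
    "PanelError",
    "DegeneratePanelError",
    "aggregate",
    "normalize",
    "total_influence",
    "dimension_totals",
    "influence_indices",
    "consensus_gap",
    "read_panel_wide",
    "read_panel_long",
    "write_panel_wide",
    "write_panel_long",
]

SCALE_MIN, SCALE_MAX = 0, 4


class PanelError(ValueError):
    """Invalid expert matrix or panel (scale, shape, diagonal, emptiness)."""


class DegeneratePanelError(ValueError):
    """The panel carries no influence signal (all-zero aggregate) or breaks inversion."""


@dataclass(frozen=True)
class ExpertMatrix:
    """One respondent's n x n integer direct-influence matrix on the 0-4 scale.

    Diagonal entries must be 0: self-influence is undefined on the scale, so a
    non-zero diagonal is rejected rather than silently zeroed.
    """

    expert_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise PanelError(f"expert {self.expert_id!r}: matrix is not square, shape {values.shape}")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.round(values)):
                raise PanelError(f"expert {self.expert_id!r}: non-integer influence scores")
            values = values.astype(int)
        if values.min() < SCALE_MIN or values.max() > SCALE_MAX:
            bad = values[(values < SCALE_MIN) | (values > SCALE_MAX)][0]
            raise PanelError(
                f"expert {self.expert_id!r}: score {bad} outside the {SCALE_MIN}-{SCALE_MAX} scale"
            )
        if np.any(np.diag(values) != 0):
            raise PanelError(f"expert {self.expert_id!r}: non-zero diagonal entry")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DirectInfluence:
    """Entrywise mean of the expert matrices; entries in [0, 4], zero diagonal."""

    A: np.ndarray
    n_experts: int


@dataclass(frozen=True)
class NormalizedInfluence:
    """``D = A / delta`` with ``delta = max(max row sum, max column sum)`` of A."""

    D: np.ndarray
    delta: float


@dataclass(frozen=True)
class TotalInfluence:
    """Criteria-level total-influence matrix T and its dimension-level block means T_D."""

    T: np.ndarray
    T_D: np.ndarray


@dataclass(frozen=True)
class ConsensusReport:
    """Panel-stability statistic: relative change of A when the last expert is dropped."""

    gap: float
    n_experts: int

    @property
    def confidence(self) -> float:
        return 1.0 - self.gap


def _check_panel(panel: Sequence[ExpertMatrix]) -> int:
    if not panel:
        raise PanelError("empty expert panel")
    n = panel[0].n
    for expert in panel:
        if expert.n != n:
            raise PanelError(
                f"expert {expert.expert_id!r}: matrix is {expert.n}x{expert.n}, expected {n}x{n}"
            )
    return n


def aggregate(panel: Sequence[ExpertMatrix]) -> DirectInfluence:
    """Average the expert matrices entrywise into the direct-influence matrix A.

    Order of experts is irrelevant; every invariant of the inputs (bounds, zero
    diagonal) carries over to A.
    """
    _check_panel(panel)
    stack = np.stack([e.values for e in panel]).astype(float)
    return DirectInfluence(A=stack.mean(axis=0), n_experts=len(panel))


def normalize(direct: DirectInfluence | np.ndarray) -> NormalizedInfluence:
    """Scale A into [0, 1] by its largest row or column sum.

    ``delta = max(max_i sum_j a_ij, max_j sum_i a_ij)``; every row and column
    sum of ``D = A / delta`` is then at most 1, with equality on the arg-max
    line.  An all-zero A is a degenerate panel and is rejected.
    """
    A = direct.A if isinstance(direct, DirectInfluence) else np.asarray(direct, dtype=float)
    if np.any(A < 0):
        raise PanelError("direct-influence matrix has negative entries")
    delta = float(max(A.sum(axis=1).max(), A.sum(axis=0).max()))
    if delta == 0.0:
        raise DegeneratePanelError("all-zero direct-influence matrix (delta = 0)")
    return NormalizedInfluence(D=A / delta, delta=delta)


def total_influence(norm: NormalizedInfluence | np.ndarray) -> np.ndarray:
    """Total-influence matrix ``T = D (I - D)^-1``.

    Equals the limit of the partial sums ``D + D^2 + ... + D^k``, which exists
    because the spectral radius of D is below 1 for any normalized matrix whose
    influence network is connected.  Solved as a linear system on ``(I - D)``
    rather than through an explicit inverse; near-singularity is reported as a
    degenerate normalization.
    """
    D = norm.D if isinstance(norm, NormalizedInfluence) else np.asarray(norm, dtype=float)
    n = D.shape[0]
    eye = np.eye(n)
    # rcond guard: 1/cond_1 below 1e-12 means (I - D) is numerically singular.
    M = eye - D
    cond = np.linalg.cond(M, 1)
    if not np.isfinite(cond) or 1.0 / cond < 1e-12:
        raise DegeneratePanelError(
            "(I - D) is numerically singular; the normalized matrix does not "
            "admit a convergent influence series"
        )
    # Solve (I - D) X = D  =>  X = (I - D)^-1 D = D (I - D)^-1 (they commute).
    return np.linalg.solve(M, D)


def dimension_totals(T: np.ndarray, system: FactorSystem) -> np.ndarray:
    """Collapse T to the dimension level: ``T_D[o, p]`` = mean of block (o, p)."""
    slices = system.block_slices()
    m = system.m
    T_D = np.empty((m, m))
    for o, so in enumerate(slices):
        for p, sp in enumerate(slices):
            T_D[o, p] = T[so, sp].mean()
    return T_D


def influence_indices(T: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Per-factor influence indices from any square influence matrix.

    give ``u`` = row sums, receive ``r`` = column sums, center = ``u + r``,
    net = ``u - r``; a factor is in the *cause* group when its net influence is
    strictly positive, otherwise in the *effect* group.  Applied to T for
    criteria and to T_D for dimensions.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"influence matrix must be square, got shape {T.shape}")
    if len(labels) != T.shape[0]:
        raise ValueError(f"{len(labels)} labels for a {T.shape[0]}x{T.shape[0]} matrix")
    u = T.sum(axis=1)
    r = T.sum(axis=0)
    return pd.DataFrame(
        {
            "give": u,
            "receive": r,
            "center": u + r,
            "net": u - r,
            "group": np.where(u - r > 0, "cause", "effect"),
        },
        index=pd.Index(labels, name="factor"),
    )


def consensus_gap(panel: Sequence[ExpertMatrix]) -> ConsensusReport:
    """Mean relative change of the aggregate matrix when the last expert is removed.

    For a panel of size ``v``, with ``a^(v)`` the mean over all experts and
    ``a^(v-1)`` the mean over the first ``v - 1``::

        gap = 1 / (n (n - 1)) * sum_{i != j} |a_ij^(v) - a_ij^(v-1)| / a_ij^(v)

    Off-diagonal cells with ``a_ij^(v) = 0`` contribute 0 (both means are then
    zero, so the cell is perfectly stable).  A gap below the conventional 5%
    threshold is read as panel consensus; ``1 - gap`` is the quoted confidence
    level.  The statistic deliberately depends on expert order: it measures the
    marginal perturbation by the most recently added respondent.
    """
    n = _check_panel(panel)
    if len(panel) < 2:
        raise PanelError("consensus gap requires at least 2 experts")
    full = aggregate(panel).A
    head = aggregate(panel[:-1]).A
    off = ~np.eye(n, dtype=bool)
    num = np.abs(full - head)[off]
    den = full[off]
    ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return ConsensusReport(gap=float(ratio.sum() / (n * (n - 1))), n_experts=len(panel))


# ---------------------------------------------------------------------------
# Panel CSV I/O — two dialects.
#
# wide: one n x n file per expert with criterion codes as header row and index
#       column; the expert id is the file stem.
# long: a single file with columns expert_id, source, target, score.
# ---------------------------------------------------------------------------


def _codes_of(system: FactorSystem) -> list[str]:
    return list(system.criterion_codes)


def read_panel_wide(paths: Sequence[str | Path], system: FactorSystem) -> list[ExpertMatrix]:
    """Read one CSV per expert (codes as header row/column); expert id = file stem."""
    codes = _codes_of(system)
    panel = []
    for path in sorted(Path(p) for p in paths):
        frame = pd.read_csv(path, index_col=0)
        frame.index = [normalize_code(c) for c in frame.index]
        frame.columns = [normalize_code(c) for c in frame.columns]
        missing = set(codes) - set(frame.index) | set(codes) - set(frame.columns)
        if missing or len(frame) != len(codes):
            raise PanelError(
                f"expert file {path.name}: criterion codes do not match the factor "
                f"system (missing or extra: {sorted(missing) or sorted(set(frame.index) - set(codes))})"
            )
        values = frame.loc[codes, codes].to_numpy()
        panel.append(ExpertMatrix(expert_id=path.stem, values=values))
    return panel


def read_panel_long(path: str | Path, system: FactorSystem) -> list[ExpertMatrix]:
    """Read a long-format panel CSV with columns expert_id, source, target, score.

    Every off-diagonal (source, target) pair must be present for every expert;
    incomplete matrices are rejected rather than imputed.  Diagonal rows may be
    omitted (they are fixed at 0).
    """
    codes = _codes_of(system)
    pos = {c: i for i, c in enumerate(codes)}
    n = len(codes)
    frame = pd.read_csv(path)
    required = {"expert_id", "source", "target", "score"}
    if not required.issubset(frame.columns):
        raise PanelError(f"long panel file missing columns {sorted(required - set(frame.columns))}")
    panel = []
    for expert_id, grp in frame.groupby("expert_id", sort=True):
        values = np.zeros((n, n), dtype=int)
        seen = np.eye(n, dtype=bool)
        for src, tgt, score in zip(grp["source"], grp["target"], grp["score"]):
            i, j = pos.get(normalize_code(src)), pos.get(normalize_code(tgt))
            if i is None or j is None:
                raise PanelError(f"expert {expert_id!r}: unknown criterion code {src!r} or {tgt!r}")
            values[i, j] = score
            seen[i, j] = True
        if not seen.all():
            i, j = np.argwhere(~seen)[0]
            raise PanelError(
                f"expert {expert_id!r}: incomplete matrix, missing pair ({codes[i]}, {codes[j]})"
            )
        panel.append(ExpertMatrix(expert_id=str(expert_id), values=values))
    if not panel:
        raise PanelError("empty expert panel")
    return panel


def write_panel_wide(panel: Sequence[ExpertMatrix], system: FactorSystem, out_dir: str | Path) -> list[Path]:
    """Write one CSV per expert into ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    codes = _codes_of(system)
    paths = []
    for expert in panel:
        frame = pd.DataFrame(expert.values, index=codes, columns=codes)
        path = out_dir / f"{expert.expert_id}.csv"
        frame.to_csv(path)
        paths.append(path)
    return paths


def write_panel_long(panel: Sequence[ExpertMatrix], system: FactorSystem, path: str | Path) -> Path:
    """Write the whole panel to one long-format CSV (off-diagonal cells only)."""
    codes = _codes_of(system)
    rows = []
    for expert in panel:
        for i, src in enumerate(codes):
            for j, tgt in enumerate(codes):
                if i != j:
                    rows.append((expert.expert_id, src, tgt, int(expert.values[i, j])))
    frame = pd.DataFrame(rows, columns=["expert_id", "source", "target", "score"])
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
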