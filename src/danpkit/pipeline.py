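"""End-to-end orchestration of the DEMATEL -> DANP -> INRM pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import danp, dematel, inrm
from .factor_model import FactorSystem

__all__ = ["PipelineResult", "run_pipeline", "run_from_direct"]


@dataclass(frozen=True)
class PipelineResult:
    """Every intermediate and final product of one analysis run."""

    system: FactorSystem
    A: np.ndarray
    delta: float
    D: np.ndarray
    T: np.ndarray
    T_D: np.ndarray
    criteria_indices: pd.DataFrame
    dimension_indices: pd.DataFrame
    W: np.ndarray
    Q: np.ndarray
    V: np.ndarray
    weights: danp.WeightTable
    maps: dict[str, nx.DiGraph]
    consensus: dematel.ConsensusReport | None = None

    def combined_indices(self) -> pd.DataFrame:
        """Dimension and criteria index rows interleaved in canonical order.

        Each dimension row (from T_D) is followed by its criteria rows (from
        T), mirroring the conventional influence-structure table.
        """
        parts = []
        for dim, block in zip(self.system.dimensions, self.system.block_slices()):
            parts.append(self.dimension_indices.loc[[dim.code]])
            parts.append(self.criteria_indices.iloc[block])
        return pd.concat(parts)

    def combined_weights(self) -> pd.DataFrame:
        """Dimension and criteria weight rows interleaved in canonical order."""
        crit = self.weights.criteria
        parts = []
        for dim, block in zip(self.system.dimensions, self.system.block_slices()):
            drow = self.weights.dimensions.loc[dim.code]
            parts.append(
                pd.DataFrame(
                    {
                        "scope": ["dimension"],
                        "local_weight": [drow["weight"]],
                        "local_rank": [int(drow["rank"])],
                        "global_weight": [np.nan],
                        "global_rank": [pd.NA],
                    },
                    index=pd.Index([dim.code], name="factor"),
                )
            )
            sub = crit.iloc[block]
            parts.append(
                pd.DataFrame(
                    {
                        "scope": "criterion",
                        "local_weight": sub["local_weight"],
                        "local_rank": sub["local_rank"],
                        "global_weight": sub["global_weight"],
                        "global_rank": sub["global_rank"],
                    },
                    index=sub.index,
                )
            )
        return pd.concat(parts)


def run_from_direct(
    system: FactorSystem,
    A: np.ndarray,
    threshold: str | float = "mean",
    consensus: dematel.ConsensusReport | None = None,
) -> PipelineResult:
    """Run normalization through INRM from an already-aggregated direct matrix."""
    norm = dematel.normalize(A)
    T = dematel.total_influence(norm)
    T_D = dematel.dimension_totals(T, system)
    crit_idx = dematel.influence_indices(T, system.criterion_codes)
    dim_idx = dematel.influence_indices(T_D, system.dimension_codes)
    W = danp.unweighted_supermatrix(T, system)
    V = danp.weight_supermatrix(W, T_D, system)
    weights = danp.limit_supermatrix(V, system)
    maps = inrm.build_inrm_maps(system, crit_idx, dim_idx, T, T_D, threshold)
    return PipelineResult(
        system=system,
        A=np.asarray(A, dtype=float),
        delta=norm.delta,
        D=norm.D,
        T=T,
        T_D=T_D,
        criteria_indices=crit_idx,
        dimension_indices=dim_idx,
        W=W.W,
        Q=V.Q,
        V=V.V,
        weights=weights,
        maps=maps,
        consensus=consensus,
    )


def run_pipeline(
    system: FactorSystem,
    panel: Sequence[dematel.ExpertMatrix],
    threshold: str | float = "mean",
) -> PipelineResult:
    """Full run from an expert panel: aggregate, DEMATEL, DANP, INRM, consensus."""
    direct = dematel.aggregate(panel)
    consensus = dematel.consensus_gap(panel) if len(panel) >= 2 else None
    return run_from_direct(system, direct.A, threshold=threshold, consensus=consensus)
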