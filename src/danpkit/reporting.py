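"""Report assembly: CSV/JSON artifacts and rounded human-readable tables.

Machine-readable CSV and JSON outputs always carry full precision so that
conservation identities (global weights summing to 1, give/receive grand-sum
equality) survive the round trip; the 3-decimal rounding familiar from
published influence tables is applied only in the plain-text report, using
half-away-from-zero rounding so positive and negative net values are treated
symmetrically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .inrm import export_inrm
from .pipeline import PipelineResult

__all__ = [
    "round_half_away",
    "write_result_bundle",
    "format_report",
]

_FLOAT_FMT = "%.12g"


def round_half_away(x, decimals: int = 3):
    """Round half away from zero (0.0005 -> 0.001, -0.0005 -> -0.001).

    Display convention for influence tables; bankers' rounding would bias net
    cause/effect values toward even digits at the .5 boundary.
    """
    scale = 10.0 ** decimals
    arr = np.asarray(x, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale
    if np.isscalar(x) or arr.ndim == 0:
        return float(rounded)
    return rounded


def _matrix_records(M: np.ndarray, labels: Iterable[str]) -> dict:
    labels = list(labels)
    return {"labels": labels, "values": [[float(v) for v in row] for row in np.asarray(M)]}


def format_report(result: PipelineResult) -> str:
    """Plain-text summary with 3-decimal display rounding."""
    lines = ["Influential network structure (give / receive / center / net / group)"]
    for factor, row in result.combined_indices().iterrows():
        indent = "" if factor in result.system.dimension_codes else "  "
        lines.append(
            f"{indent}{factor:<6} {round_half_away(row['give']):8.3f} "
            f"{round_half_away(row['receive']):8.3f} {round_half_away(row['center']):8.3f} "
            f"{round_half_away(row['net']):8.3f}  {row['group']}"
        )
    lines.append("")
    lines.append("Influence weights (local / rank / global / rank)")
    for factor, row in result.combined_weights().iterrows():
        if row["scope"] == "dimension":
            lines.append(f"{factor:<6} {round_half_away(row['local_weight']):8.3f} {int(row['local_rank']):4d}")
        else:
            lines.append(
                f"  {factor:<6} {round_half_away(row['local_weight']):8.3f} {int(row['local_rank']):4d} "
                f"{round_half_away(row['global_weight']):8.3f} {int(row['global_rank']):4d}"
            )
    if result.consensus is not None:
        lines.append("")
        lines.append(
            f"Consensus gap {result.consensus.gap:.4f} "
            f"(confidence {100 * result.consensus.confidence:.2f}%, panel of {result.consensus.n_experts})"
        )
    return "\n".join(lines) + "\n"


def write_result_bundle(
    result: PipelineResult,
    out_dir: str | Path,
    inrm_formats: tuple[str, ...] = ("csv", "dot"),
    run_config: dict | None = None,
) -> list[Path]:
    """Write the complete artifact bundle for one run; returns paths written.

    Contents: ``indices.csv`` (dimension + criteria influence-structure rows),
    ``weights.csv`` (dimension + criteria weight rows), ``consensus.json``,
    ``matrices.json`` (full-precision audit of A, D, T, T_D, W, Q, V and the
    limiting weights), INRM exports per map, ``report.txt`` (rounded display)
    and ``run_log.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    indices_path = out_dir / "indices.csv"
    result.combined_indices().to_csv(indices_path, float_format=_FLOAT_FMT)
    written.append(indices_path)

    weights_path = out_dir / "weights.csv"
    result.combined_weights().to_csv(weights_path, float_format=_FLOAT_FMT)
    written.append(weights_path)

    if result.consensus is not None:
        consensus_path = out_dir / "consensus.json"
        consensus_path.write_text(
            json.dumps(
                {
                    "gap": result.consensus.gap,
                    "confidence": result.consensus.confidence,
                    "n_experts": result.consensus.n_experts,
                },
                indent=2,
            )
            + "\n"
        )
        written.append(consensus_path)

    crit_codes = result.system.criterion_codes
    dim_codes = result.system.dimension_codes
    matrices_path = out_dir / "matrices.json"
    matrices_path.write_text(
        json.dumps(
            {
                "delta": result.delta,
                "A": _matrix_records(result.A, crit_codes),
                "D": _matrix_records(result.D, crit_codes),
                "T": _matrix_records(result.T, crit_codes),
                "T_D": _matrix_records(result.T_D, dim_codes),
                "W": _matrix_records(result.W, crit_codes),
                "Q": _matrix_records(result.Q, dim_codes),
                "V": _matrix_records(result.V, crit_codes),
                "global_weights": {
                    c: float(w) for c, w in result.weights.criteria["global_weight"].items()
                },
            },
            indent=2,
        )
        + "\n"
    )
    written.append(matrices_path)

    for name, graph in result.maps.items():
        for fmt in inrm_formats:
            if fmt == "csv":
                written.extend(export_inrm(graph, "csv", out_dir / f"inrm_{name}"))
            else:
                written.extend(export_inrm(graph, fmt, out_dir / f"inrm_{name}.{fmt}"))

    report_path = out_dir / "report.txt"
    report_path.write_text(format_report(result))
    written.append(report_path)

    log_path = out_dir / "run_log.json"
    import danpkit

    log = {
        "danpkit_version": danpkit.__version__,
        "n_criteria": result.system.n,
        "n_dimensions": result.system.m,
        "delta": result.delta,
        "inrm_thresholds": {name: g.graph["threshold"] for name, g in result.maps.items()},
        "limit_tolerance": 1e-10,
        "outputs": [str(p.relative_to(out_dir)) for p in written],
    }
    if run_config:
        log["config"] = run_config
    log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    written.append(log_path)
    return written
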