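"""Dimension/criterion factor systems.

A :class:`FactorSystem` is an ordered collection of dimensions, each holding an
ordered list of criteria.  The file order of the configuration is semantic: it
defines the canonical row/column order of every matrix in the DEMATEL/DANP
pipeline, and the contiguous blocks of criteria belonging to one dimension
define the block structure used by the supermatrix construction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

__all__ = [
    "Criterion",
    "Dimension",
    "FactorSystem",
    "FactorSystemError",
    "normalize_code",
    "load_factor_system",
    "save_factor_system",
    "block_index",
    "bundled_system",
]


class FactorSystemError(ValueError):
    """Raised when a factor-system definition violates a structural invariant."""


_CODE_NOISE = re.compile(r"[*_\s]+")


def normalize_code(raw: str) -> str:
    """Normalize a factor code: strip whitespace and typographic markup, uppercase.

    Printed codes carry typographic noise (``*C*_23_`` for ``C23``); this makes
    codes from configs, CSV headers, and published tables comparable.
    """
    code = _CODE_NOISE.sub("", str(raw)).upper()
    if not code:
        raise FactorSystemError(f"factor code {raw!r} is empty after normalization")
    return code


@dataclass(frozen=True)
class Criterion:
    """A single rated factor, owned by exactly one dimension."""

    code: str
    label: str
    dimension_code: str


@dataclass(frozen=True)
class Dimension:
    """A cluster of criteria; the unit of block normalization."""

    code: str
    label: str
    criteria: tuple[Criterion, ...]


@dataclass(frozen=True)
class FactorSystem:
    """An ordered factor hierarchy: dimensions -> criteria.

    The flat criterion order (dimension order, then within-dimension order) is
    the canonical index order of every n x n matrix in the pipeline.
    """

    dimensions: tuple[Dimension, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise FactorSystemError("factor system has no dimensions")
        seen: dict[str, str] = {}
        for dim in self.dimensions:
            if dim.code in seen:
                raise FactorSystemError(f"duplicate factor code {dim.code!r}")
            seen[dim.code] = "dimension"
            if len(dim.criteria) < 2:
                raise FactorSystemError(
                    f"dimension {dim.code!r} has {len(dim.criteria)} criteria; "
                    "at least 2 are required (block normalization divides by "
                    "within-block row sums)"
                )
            for crit in dim.criteria:
                if crit.code in seen:
                    raise FactorSystemError(f"duplicate factor code {crit.code!r}")
                seen[crit.code] = "criterion"
                if crit.dimension_code != dim.code:
                    raise FactorSystemError(
                        f"criterion {crit.code!r} claims dimension "
                        f"{crit.dimension_code!r} but sits under {dim.code!r}"
                    )

    # -- sizes -----------------------------------------------------------
    @property
    def m(self) -> int:
        """Number of dimensions."""
        return len(self.dimensions)

    @property
    def m_o(self) -> tuple[int, ...]:
        """Criteria count per dimension, in canonical order."""
        return tuple(len(d.criteria) for d in self.dimensions)

    @property
    def n(self) -> int:
        """Total criterion count (sum of the block sizes)."""
        return sum(self.m_o)

    # -- canonical orderings ---------------------------------------------
    @property
    def criteria(self) -> tuple[Criterion, ...]:
        return tuple(c for d in self.dimensions for c in d.criteria)

    @property
    def criterion_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.criteria)

    @property
    def dimension_codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.dimensions)

    def block_slices(self) -> tuple[slice, ...]:
        """Contiguous index slice of each dimension's criteria."""
        out, start = [], 0
        for size in self.m_o:
            out.append(slice(start, start + size))
            start += size
        return tuple(out)

    def dimension_of(self, criterion_code: str) -> str:
        code = normalize_code(criterion_code)
        for crit in self.criteria:
            if crit.code == code:
                return crit.dimension_code
        raise FactorSystemError(f"unknown criterion code {criterion_code!r}")

    def __iter__(self) -> Iterator[Dimension]:
        return iter(self.dimensions)

    # -- (de)serialization -----------------------------------------------
    @classmethod
    def from_dict(cls, payload: Mapping) -> "FactorSystem":
        try:
            raw_dims = payload["dimensions"]
        except (KeyError, TypeError):
            raise FactorSystemError("config must contain a 'dimensions' list")
        if not isinstance(raw_dims, Sequence) or isinstance(raw_dims, (str, bytes)):
            raise FactorSystemError("'dimensions' must be a list of mappings")
        dims = []
        for raw_dim in raw_dims:
            dcode = normalize_code(raw_dim["code"])
            crits = tuple(
                Criterion(
                    code=normalize_code(raw_crit["code"]),
                    label=str(raw_crit.get("label", "")).strip(),
                    dimension_code=dcode,
                )
                for raw_crit in raw_dim.get("criteria", [])
            )
            dims.append(Dimension(code=dcode, label=str(raw_dim.get("label", "")).strip(), criteria=crits))
        return cls(dimensions=tuple(dims), name=str(payload.get("name", "")))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dimensions": [
                {
                    "code": d.code,
                    "label": d.label,
                    "criteria": [{"code": c.code, "label": c.label} for c in d.criteria],
                }
                for d in self.dimensions
            ],
        }


def load_factor_system(path: str | Path) -> FactorSystem:
    """Load and validate a factor system from a YAML or JSON config file.

    The file order of dimensions and criteria becomes the canonical matrix
    order.  Raises :class:`FactorSystemError` naming the offending code on
    duplicate codes, dimensions with fewer than two criteria, or an empty
    system.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if payload is None:
        raise FactorSystemError(f"config file {path} is empty")
    return FactorSystem.from_dict(payload)


def save_factor_system(system: FactorSystem, path: str | Path) -> None:
    """Write a factor system back to YAML (or JSON by extension), order-preserving."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(system.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(system.to_dict(), sort_keys=False, allow_unicode=True))


def block_index(system: FactorSystem) -> dict[int, tuple[int, int]]:
    """Map each flat criterion position to ``(dimension index, within-block offset)``.

    Positions ``0 .. n-1`` partition into ``m`` contiguous blocks of sizes
    ``m_o`` in dimension order; the mapping is a bijection onto
    ``{(o, k) : 0 <= k < m_o}``.
    """
    mapping: dict[int, tuple[int, int]] = {}
    pos = 0
    for o, size in enumerate(system.m_o):
        for k in range(size):
            mapping[pos] = (o, k)
            pos += 1
    return mapping


def bundled_system() -> FactorSystem:
    """The packaged work-from-home mental-health factor system.

    Three dimensions — work-related stressors (7 criteria), non-work stressors
    (6), communication issues (5) — 18 criteria in total.
    """
    ref = resources.files("danpkit.data").joinpath("memon2021.yaml")
    payload = yaml.safe_load(ref.read_text())
    return FactorSystem.from_dict(payload)
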