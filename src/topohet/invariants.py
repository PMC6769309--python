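"""Topological invariants of a persistence diagram.

For each homology dimension k, a diagram's finite cycles c have a
length l(c) = death(c) - birth(c); summing over all k-dimensional
cycles gives SL_k, and summing births and deaths gives SBT_k and SDT_k,
so SL_k = SDT_k - SBT_k.  Connected components are all born at eps = 0,
hence SBT_0 = 0 and SL_0 = SDT_0.  The Euler characteristic summary is
the alternating sum chi = SL_0 - SL_1 + SL_2 over dimensions 0-2
(higher-dimensional cycles, when computed, are reported per dimension
but never enter chi).

SDT_0 is the heterogeneity read-out: a more dispersed point cloud keeps
its components separate longer, so they die later and SDT_0 grows.
Essential classes (alive at eps_max) are counted but excluded from all
sums.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .persistence import PersistenceDiagram

__all__ = ["DimensionSummary", "DiagramSummary", "summarize"]


@dataclass(frozen=True)
class DimensionSummary:
    sl: float = 0.0
    sbt: float = 0.0
    sdt: float = 0.0
    n_finite: int = 0
    n_essential: int = 0


@dataclass(frozen=True)
class DiagramSummary:
    """Per-dimension SL/SBT/SDT sums plus the Euler characteristic."""

    per_dim: dict[int, DimensionSummary]
    chi: float
    max_dim: int

    @property
    def sdt0(self) -> float:
        return self.per_dim[0].sdt

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_dim": {str(k): asdict(v) for k, v in sorted(self.per_dim.items())},
            "chi": self.chi,
            "max_dim": self.max_dim,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize(diagram: PersistenceDiagram) -> DiagramSummary:
    """Accumulate SL/SBT/SDT per dimension and the Euler characteristic.

    Sums run over finite pairs only, in the diagram's canonical
    (dim, birth, death) order with plain left-to-right double-precision
    accumulation, so repeated runs are bit-identical.  Dimensions up to
    ``diagram.max_dim`` are always present in ``per_dim`` (zeros when
    empty).
    """
    acc: dict[int, list[float]] = {}

    def slot(dim: int) -> list[float]:
        return acc.setdefault(dim, [0.0, 0.0, 0.0, 0, 0])  # sl, sbt, sdt, nf, ne

    for dim in range(diagram.max_dim + 1):
        slot(dim)
    for p in diagram.pairs:  # canonical order
        s = slot(p.dim)
        if p.essential:
            s[4] += 1
        else:
            s[0] += p.death - p.birth
            s[1] += p.birth
            s[2] += p.death
            s[3] += 1
    per_dim = {dim: DimensionSummary(sl, sbt, sdt, nf, ne)
               for dim, (sl, sbt, sdt, nf, ne) in sorted(acc.items())}

    def sl_of(dim: int) -> float:
        return per_dim[dim].sl if dim in per_dim else 0.0

    chi = sl_of(0) - sl_of(1) + sl_of(2)
    return DiagramSummary(per_dim, chi, diagram.max_dim)
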