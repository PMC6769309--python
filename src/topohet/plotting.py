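"""Persistence-diagram plots (basic diagnostic output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .persistence import PersistenceDiagram  # noqa: E402

__all__ = ["plot_diagram"]

_MARKERS = {0: "o", 1: "^", 2: "s", 3: "D"}


def plot_diagram(diagram: PersistenceDiagram, path: str | Path,
                 title: str | None = None) -> Path:
    """Scatter of (birth, death) pairs, one marker per dimension.

    Essential classes are drawn at the top margin (just above the
    largest finite value) and annotated as essential; the diagonal is
    the zero-persistence reference.
    """
    path = Path(path)
    finite = diagram.finite()
    essential = diagram.essential()
    hi = max([p.death for p in finite] + [p.birth for p in diagram.pairs]
             + [diagram.eps_max if diagram.eps_max == diagram.eps_max else 0.0]
             + [1.0])
    top = hi * 1.1 if hi > 0 else 1.0

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, top], [0, top], color="grey", lw=0.8, zorder=1)
    for dim in sorted({p.dim for p in diagram.pairs}):
        pts = [p for p in finite if p.dim == dim]
        if pts:
            ax.scatter([p.birth for p in pts], [p.death for p in pts],
                       marker=_MARKERS.get(dim, "x"), label=f"dim {dim}",
                       alpha=0.7, zorder=2)
        ess = [p for p in essential if p.dim == dim]
        if ess:
            ax.scatter([p.birth for p in ess], [top] * len(ess),
                       marker=_MARKERS.get(dim, "x"), facecolors="none",
                       edgecolors="red", zorder=3)
    if essential:
        ax.axhline(top, color="red", lw=0.5, ls=":")
        ax.annotate("essential", xy=(0.02, top), fontsize=8, color="red",
                    va="bottom")
    ax.set_xlabel(r"birth $\varepsilon$")
    ax.set_ylabel(r"death $\varepsilon$")
    if title:
        ax.set_title(title)
    if any(True for p in finite):
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
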