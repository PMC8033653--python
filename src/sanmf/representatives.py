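"""Representative subgraphs of each trend group.

A trend group (one H row) is summarized by the subgraphs that are either
ranked in its top 100 by coefficient or carry a coefficient strictly greater
than 1. Exclusivity bookkeeping counts how many representatives describe
exactly one group; panels render each pattern as a step plot of its levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mining import Subgraph

logger = logging.getLogger(__name__)


@dataclass
class TrendGroup:
    component: int                                # 1..k
    members: list[tuple[str, float]]              # (subgraph id, coefficient), desc


def select_representatives(
    H: np.ndarray,
    subgraphs: Sequence[Subgraph],
    top_n: int = 100,
    threshold: float = 1.0,
) -> list[TrendGroup]:
    """Per component: union of the top-``top_n`` subgraphs by coefficient and
    all subgraphs with coefficient strictly greater than ``threshold``.

    Coefficient ties at the top_n rank boundary are all included, which makes
    the selection deterministic under ties.
    """
    H = np.asarray(H)
    k, m = H.shape
    if m != len(subgraphs):
        raise ValueError("H column count must match the subgraph vocabulary")
    groups: list[TrendGroup] = []
    for comp in range(k):
        coefs = H[comp]
        order = np.lexsort((np.arange(m), -coefs))
        chosen: set[int] = set()
        if m <= top_n:
            chosen.update(range(m))
        else:
            cutoff = coefs[order[top_n - 1]]
            chosen.update(np.flatnonzero(coefs >= cutoff).tolist())
        chosen.update(np.flatnonzero(coefs > threshold).tolist())
        members = sorted(
            ((subgraphs[j].id, float(coefs[j])) for j in chosen),
            key=lambda t: (-t[1], t[0]),
        )
        groups.append(TrendGroup(component=comp + 1, members=members))
    return groups


def exclusivity_summary(groups: Sequence[TrendGroup]) -> dict:
    """Union size, exclusive count, and per-component set sizes."""
    if len(groups) < 2:
        raise ValueError("exclusivity needs at least 2 trend groups")
    sets = [frozenset(sid for sid, _ in g.members) for g in groups]
    union = frozenset().union(*sets)
    exclusive = [sid for sid in union if sum(sid in s for s in sets) == 1]
    return {
        "n_unique": len(union),
        "n_exclusive": len(exclusive),
        "per_component": {g.component: len(s) for g, s in zip(groups, sets)},
        "exclusive_ids": sorted(exclusive),
    }


def representative_union(groups: Sequence[TrendGroup]) -> list[str]:
    """Sorted union of representative subgraph ids over all trend groups."""
    ids: set[str] = set()
    for g in groups:
        ids.update(sid for sid, _ in g.members)
    return sorted(ids)


def render_trend_panel(
    group: TrendGroup,
    subgraph_lookup: dict[str, Subgraph],
    out_path: str | Path,
    max_patterns: int = 30,
) -> Path | None:
    """Step-plot panel of a trend group's representative patterns.

    One facet per variable; each pattern drawn as a step polyline over its
    window span. Returns the written path, or None (with a warning) for an
    empty set.
    """
    if not group.members:
        logger.warning("trend group %d has no representatives; no panel written",
                       group.component)
        return None
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    members = group.members[:max_patterns]
    by_var: dict[str, list[tuple[tuple[int, ...], float]]] = {}
    for sid, coef in members:
        s = subgraph_lookup[sid]
        by_var.setdefault(s.variable, []).append((s.levels, coef))
    n_facets = len(by_var)
    ncol = min(4, n_facets)
    nrow = int(np.ceil(n_facets / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow),
                             squeeze=False, sharey=True)
    for ax in axes.ravel()[n_facets:]:
        ax.axis("off")
    for ax, (var, patterns) in zip(axes.ravel(), sorted(by_var.items())):
        for levels, coef in patterns:
            ax.step(range(len(levels)), levels, where="mid", alpha=0.8)
        ax.set_title(var, fontsize=8)
        ax.set_ylim(-4.5, 4.5)
        ax.set_xlabel("window")
    fig.suptitle(f"Trend group {group.component}")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
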