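"""Stimulus grouping over typability-scored items.

Three grouping algorithms, mirroring a stimulus-preparation workflow:

* **matched**: rank items by score and deal them round-robin so every
  group samples the full score range (comparable group means); when a
  group size is requested the selection window is centred on the median.
* **divergent-simple**: extreme groups from the bottom and top of the
  ranking, with intermediate groups centred on evenly spaced quantiles.
* **divergent-clusters**: one-dimensional K-means with quantile-initialised
  centres; each group takes the items nearest its cluster centre.

All three are deterministic given (items, parameters, seed); the seed only
breaks exact score ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoredItem",
    "GroupAssignment",
    "matched_groups",
    "divergent_simple",
    "divergent_clusters",
    "group_summary",
]


@dataclass(frozen=True)
class ScoredItem:
    """A text item with its typability score (z units)."""

    item_id: str
    text: str
    score: float

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError(f"item {self.item_id!r}: score must be finite")


@dataclass
class GroupAssignment:
    """Labelled groups of scored items plus per-group summaries."""

    groups: dict[str, list[ScoredItem]]
    summary: dict[str, tuple[float, float, int]]  # label -> (mean, SD, n)
    unassigned: list[ScoredItem] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)


def _sorted_items(items: list[ScoredItem], seed: int) -> list[ScoredItem]:
    """Ascending by score, ties by item_id, residual ties shuffled by seed."""
    rng = np.random.default_rng(seed)
    jitter = {id(it): rng.random() for it in items}
    return sorted(items, key=lambda it: (it.score, it.item_id, jitter[id(it)]))


def _summarise(groups: dict[str, list[ScoredItem]]) -> dict[str, tuple[float, float, int]]:
    out = {}
    for label, members in groups.items():
        scores = np.array([m.score for m in members])
        sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
        out[label] = (float(scores.mean()), sd, len(scores))
    return out


def _labels(k: int) -> list[str]:
    return [f"group_{j}" for j in range(1, k + 1)]


def matched_groups(
    items: list[ScoredItem], k: int, size: int | None = None, seed: int = 0
) -> GroupAssignment:
    """Groups with comparable mean typability via a round-robin deal.

    Items are sorted by score; if ``size`` is given, the ``k * size`` items
    whose ranks are closest to the median are selected first (one extra
    item below the median when the window is uneven).  The sorted selection
    is then dealt round-robin: lowest to group 1, next to group 2, and so
    on cyclically.
    """
    n = len(items)
    if k < 1:
        raise ValueError("k must be >= 1")
    if size is not None and k * size > n:
        raise ValueError(f"k*size = {k * size} exceeds the number of items ({n})")
    ranked = _sorted_items(items, seed)
    if size is None:
        selection = ranked
        unassigned: list[ScoredItem] = []
    else:
        m = k * size
        start = (n - m) // 2
        selection = ranked[start : start + m]
        unassigned = ranked[:start] + ranked[start + m :]
    groups: dict[str, list[ScoredItem]] = {label: [] for label in _labels(k)}
    labels = _labels(k)
    for i, item in enumerate(selection):
        groups[labels[i % k]].append(item)
    return GroupAssignment(
        groups=groups,
        summary=_summarise(groups),
        unassigned=unassigned,
        metadata={"method": "matched", "deal_order": "lowest score first, group_1 first", "seed": str(seed)},
    )


def divergent_simple(
    items: list[ScoredItem], k: int, size: int, seed: int = 0
) -> GroupAssignment:
    """Groups with distinct typability levels from quantile-centred rank windows.

    Group 1 takes the ``size`` lowest-scored items and group ``k`` the
    ``size`` highest; each intermediate group ``j`` is centred on the
    ``(j-1)/(k-1)`` quantile rank.  Colliding windows are shifted inward
    deterministically.
    """
    n = len(items)
    if k < 2:
        raise ValueError("divergent_simple requires k >= 2")
    if k * size > n:
        raise ValueError(f"k*size = {k * size} exceeds the number of items ({n})")
    ranked = _sorted_items(items, seed)
    labels = _labels(k)
    windows: dict[str, tuple[int, int]] = {
        labels[0]: (0, size),
        labels[-1]: (n - size, n),
    }
    prev_end = size
    for j in range(2, k):
        centre = round((j - 1) / (k - 1) * (n - 1))
        start = centre - size // 2
        # shift inward: after the previous window, leaving room for the rest
        start = max(start, prev_end)
        start = min(start, n - size - (k - j) * size)
        if start < prev_end:
            raise ValueError("quantile windows cannot be placed without overlap")
        windows[labels[j - 1]] = (start, start + size)
        prev_end = start + size
    groups = {label: ranked[a:b] for label, (a, b) in windows.items()}
    taken = {id(it) for members in groups.values() for it in members}
    unassigned = [it for it in ranked if id(it) not in taken]
    groups = {label: groups[label] for label in labels}
    return GroupAssignment(
        groups=groups,
        summary=_summarise(groups),
        unassigned=unassigned,
        metadata={"method": "divergent_simple", "seed": str(seed)},
    )


def divergent_clusters(
    items: list[ScoredItem], k: int, size: int | None = None, seed: int = 0
) -> GroupAssignment:
    """Distinct-typability groups from one-dimensional K-means clusters.

    Centres are initialised at evenly spaced score quantiles (reproducible
    regardless of seed) and run to convergence; groups are labelled in
    ascending centre order.  With ``size`` given, each group keeps only the
    ``size`` members nearest its centre.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("divergent_clusters requires k >= 2")
    scores = np.array([it.score for it in items])
    if k > len(np.unique(scores)):
        raise ValueError(f"k = {k} exceeds the number of distinct scores ({len(np.unique(scores))})")
    init = np.quantile(scores, np.linspace(0, 1, k)).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed).fit(scores.reshape(-1, 1))
    centres = km.cluster_centers_.ravel()
    order = np.argsort(centres, kind="stable")
    labels = _labels(k)
    cluster_to_label = {int(c): labels[rank] for rank, c in enumerate(order)}
    members: dict[str, list[ScoredItem]] = {label: [] for label in labels}
    for item, cluster in zip(items, km.labels_):
        members[cluster_to_label[int(cluster)]].append(item)
    unassigned: list[ScoredItem] = []
    if size is not None:
        for rank, c in enumerate(order):
            label = labels[rank]
            centre = centres[c]
            ranked = sorted(members[label], key=lambda it: (abs(it.score - centre), it.item_id))
            members[label] = sorted(ranked[:size], key=lambda it: (it.score, it.item_id))
            unassigned.extend(ranked[size:])
    else:
        for label in labels:
            members[label] = sorted(members[label], key=lambda it: (it.score, it.item_id))
    return GroupAssignment(
        groups=members,
        summary=_summarise(members),
        unassigned=unassigned,
        metadata={"method": "divergent_clusters", "seed": str(seed), "centres": ",".join(f"{centres[c]:.6f}" for c in order)},
    )


def group_summary(assignment: GroupAssignment) -> dict:
    """Exact per-group statistics plus pooled scores for plotting.

    Single-item groups report SD 0 with a ``degenerate_sd`` flag.
    """
    per_group = {}
    pooled = []
    for label, members in assignment.groups.items():
        if not members:
            raise ValueError(f"group {label!r} is empty")
        scores = [m.score for m in members]
        pooled.extend(scores)
        arr = np.array(scores)
        per_group[label] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": len(arr),
            "degenerate_sd": len(arr) < 2,
        }
    return {"groups": per_group, "pooled_scores": pooled}
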