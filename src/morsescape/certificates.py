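"""Path certificates: maximum-bottleneck paths and RSE existence witnesses.

Between any two genotypes there are many single-mutation paths; the
*maximum-bottleneck* (widest) path is one whose minimum fitness along the
way is as high as possible.  Between two peaks, the valley floor of that
best path is the unavoidable fitness cost of crossing between them, and its
neighborhood is where the landscape's reciprocal sign epistasis lives: a
multi-peaked strict landscape always contains at least one RSE instance.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

from .core import FitnessLandscape, LandscapeError, NeutralityError, TheoremViolationError, neighbors
from .epistasis import RSEInstance, enumerate_rse, find_peaks

__all__ = ["BottleneckCertificate", "max_bottleneck_path", "rse_existence_witness"]


@dataclass(frozen=True)
class BottleneckCertificate:
    """A maximum-bottleneck single-mutation path between two genotypes.

    ``bottleneck_value`` is the minimum fitness on the path; no other
    single-mutation path between the endpoints achieves a strictly larger
    minimum.  Among optimal paths, the certificate is a shortest one, with
    remaining ties resolved by deterministic traversal order.
    """

    endpoints: tuple[str, str]
    path: tuple[str, ...]
    bottleneck_vertex: str
    bottleneck_value: float

    def to_dict(self) -> dict:
        return {
            "from": self.endpoints[0],
            "to": self.endpoints[1],
            "path": list(self.path),
            "bottleneck_vertex": self.bottleneck_vertex,
            "bottleneck_value": self.bottleneck_value,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _bfs_path(
    landscape: FitnessLandscape, a: str, b: str, threshold: float
) -> tuple[str, ...] | None:
    """Shortest path a->b through genotypes of fitness >= threshold, or None.

    Neighbors are expanded in the canonical locus-major order, so the
    returned shortest path is deterministic.
    """
    W = landscape.fitness
    if W[a] < threshold or W[b] < threshold:
        return None
    parent: dict[str, str | None] = {a: None}
    queue = deque([a])
    while queue:
        g = queue.popleft()
        if g == b:
            path = [g]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])  # type: ignore[arg-type]
            return tuple(reversed(path))
        for h in neighbors(landscape.space, g):
            if h not in parent and W[h] >= threshold:
                parent[h] = g
                queue.append(h)
    return None


def max_bottleneck_path(
    landscape: FitnessLandscape, a: str, b: str
) -> BottleneckCertificate:
    """Find a single-mutation path a->b maximizing the minimum fitness en route.

    Threshold descent: distinct fitness values are tried from high to low;
    the first threshold whose induced subgraph connects ``a`` to ``b`` is
    the optimal bottleneck, and a breadth-first search inside that subgraph
    returns a shortest optimal path.
    """
    if a not in landscape.space or b not in landscape.space:
        raise LandscapeError(f"endpoint not in space: {a!r} or {b!r}")
    if a == b:
        raise LandscapeError("endpoints must differ")
    W = landscape.fitness
    cap = min(W[a], W[b])
    levels = sorted((w for w in set(W.values()) if w <= cap), reverse=True)
    for threshold in levels:
        path = _bfs_path(landscape, a, b, threshold)
        if path is not None:
            values = [W[g] for g in path]
            bottleneck_value = min(values)
            bottleneck_vertex = path[values.index(bottleneck_value)]
            return BottleneckCertificate(
                endpoints=(a, b),
                path=path,
                bottleneck_vertex=bottleneck_vertex,
                bottleneck_value=bottleneck_value,
            )
    raise TheoremViolationError(
        "no single-mutation path found — the Hamming graph is connected, "
        "so this signals an implementation bug"
    )


def rse_existence_witness(landscape: FitnessLandscape) -> RSEInstance | None:
    """Produce an RSE instance whenever the landscape has two or more peaks.

    With at least two peaks an instance is guaranteed to exist; its absence
    from the enumeration raises an internal error rather than returning
    None.  With a single peak no witness is required and None is returned
    (the landscape may still contain RSE instances).
    """
    if not landscape.strict:
        raise NeutralityError("rse_existence_witness requires a strict landscape")
    peaks = find_peaks(landscape)
    instances = enumerate_rse(landscape)
    if len(peaks) >= 2:
        if not instances:
            raise TheoremViolationError(
                f"{len(peaks)} peaks but no RSE instance — contradicts the "
                "peaks-vs-RSE bound; implementation bug"
            )
        return instances[0]
    return None
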