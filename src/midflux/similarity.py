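"""Pairwise MID alignment, Canberra distances and similarity networks.

MID vectors are globally aligned (Needleman-Wunsch with an affine-free gap
penalty, default 0.4, minimizing the summed absolute abundance differences)
before the Canberra distance is computed, so that pure index shifts — gains
or losses of labeled fragments — yield small distances.  Distances are
normalized by the sum of the input vector dimensions, bounding them in
[0, 1], and below-cutoff pairs become network edges tagged with the
condition(s) supporting them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .core import MID, LabelingDataset, SimilarityNetwork

__all__ = [
    "GAP",
    "AlignedPair",
    "DistanceMatrix",
    "align_mid_vectors",
    "mid_distance",
    "pairwise_distances",
    "build_similarity_network",
    "nearest_neighbors",
    "to_networkx",
    "write_graphml",
    "write_edge_list",
]

#: Gap marker in aligned sequences.
GAP = None

DEFAULT_GAP_PENALTY = 0.4


@dataclass(frozen=True)
class AlignedPair:
    a_aligned: tuple[float | None, ...]
    b_aligned: tuple[float | None, ...]
    alignment_cost: float
    gap_count: int

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned sequences must have equal length")


def align_mid_vectors(
    a: MID | Sequence[float],
    b: MID | Sequence[float],
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> AlignedPair:
    """Global alignment minimizing sum|a_i - b_j| + gap_penalty * gaps.

    Traceback ties are broken deterministically: match, then consuming an
    element of a (gap placed in b), then consuming an element of b.
    """
    va = list(a.abundances if isinstance(a, MID) else a)
    vb = list(b.abundances if isinstance(b, MID) else b)
    n, m = len(va), len(vb)
    cost = np.empty((n + 1, m + 1))
    cost[0, :] = gap_penalty * np.arange(m + 1)
    cost[:, 0] = gap_penalty * np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost[i, j] = min(
                cost[i - 1, j - 1] + abs(va[i - 1] - vb[j - 1]),
                cost[i, j - 1] + gap_penalty,
                cost[i - 1, j] + gap_penalty,
            )
    a_al: list[float | None] = []
    b_al: list[float | None] = []
    i, j = n, m
    tol = 1e-12
    while i > 0 or j > 0:
        here = cost[i, j]
        if (
            i > 0
            and j > 0
            and abs(cost[i - 1, j - 1] + abs(va[i - 1] - vb[j - 1]) - here) <= tol
        ):
            a_al.append(va[i - 1])
            b_al.append(vb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and abs(cost[i - 1, j] + gap_penalty - here) <= tol:
            a_al.append(va[i - 1])
            b_al.append(GAP)
            i -= 1
        else:
            a_al.append(GAP)
            b_al.append(vb[j - 1])
            j -= 1
    a_al.reverse()
    b_al.reverse()
    gaps = sum(x is GAP for x in a_al) + sum(x is GAP for x in b_al)
    return AlignedPair(
        a_aligned=tuple(a_al),
        b_aligned=tuple(b_al),
        alignment_cost=float(cost[n, m]),
        gap_count=gaps,
    )


def mid_distance(
    a: MID | Sequence[float],
    b: MID | Sequence[float],
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    gap_terms: Literal["zero", "drop"] = "zero",
) -> float:
    """Dimension-normalized Canberra distance of two aligned MID vectors.

    With ``gap_terms='zero'`` (default) gap positions contribute a 0-valued
    abundance, so a pure index shift has distance 0; with ``'drop'`` gap
    positions are omitted from the Canberra sum.  0/0 terms count as 0 either
    way, and the sum is divided by ``dim a + dim b`` of the original inputs.

    A pair can have several cost-optimal alignments whose Canberra sums
    differ; both traceback orientations are evaluated and the smaller sum
    taken, which makes the distance symmetric.
    """
    va = a.abundances if isinstance(a, MID) else tuple(a)
    vb = b.abundances if isinstance(b, MID) else tuple(b)

    def canberra(first, second):
        pair = align_mid_vectors(first, second, gap_penalty)
        total = 0.0
        for x, y in zip(pair.a_aligned, pair.b_aligned):
            if x is GAP or y is GAP:
                if gap_terms == "drop":
                    continue
                x = 0.0 if x is GAP else x
                y = 0.0 if y is GAP else y
            denom = abs(x) + abs(y)
            if denom > 0:
                total += abs(x - y) / denom
        return total

    return min(canberra(va, vb), canberra(vb, va)) / (len(va) + len(vb))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of normalized MID distances for one condition slice."""

    compound_ids: list[str]
    values: np.ndarray
    fragment_mz: dict[str, int] = field(default_factory=dict)
    names: dict[str, str | None] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.compound_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match compound list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def distance(self, a: str, b: str) -> float:
        ia = self.compound_ids.index(a)
        ib = self.compound_ids.index(b)
        return float(self.values[ia, ib])


def pairwise_distances(
    ds: LabelingDataset,
    condition: str,
    tracer: str,
    min_r2: float = 0.95,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    gap_terms: Literal["zero", "drop"] = "zero",
) -> DistanceMatrix:
    """All pairwise normalized distances within one condition x tracer slice.

    Per compound, the heaviest fragment with r2 above ``min_r2`` (fragments
    without r2 qualify) is selected and its replicate-mean MID used;
    compounds with no qualifying fragment are excluded and reported.
    """
    chosen: dict[str, MID] = {}
    fragment_mz: dict[str, int] = {}
    names: dict[str, str | None] = {}
    excluded: dict[str, str] = {}
    sliced = ds.slice(condition, tracer)
    for cid in sliced.compound_ids():
        recs = sliced.records_for(cid, condition, tracer)
        qualifying: set[int] = set()
        for rec in recs:
            for frag in rec.fragments:
                if frag.r2 is None or frag.r2 > min_r2:
                    qualifying.add(frag.fragment_mz)
        if not qualifying:
            excluded[cid] = "no_fragment_above_min_r2"
            continue
        mz = max(qualifying)
        mid = sliced.mean_fragment_mid(cid, condition, tracer, mz)
        if mid is None:  # pragma: no cover - qualifying implies presence
            excluded[cid] = "no_measurement"
            continue
        chosen[cid] = mid
        fragment_mz[cid] = mz
        names[cid] = recs[0].name

    ids = sorted(chosen)
    k = len(ids)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = mid_distance(
                chosen[ids[i]], chosen[ids[j]], gap_penalty, gap_terms
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        compound_ids=ids,
        values=values,
        fragment_mz=fragment_mz,
        names=names,
        excluded=excluded,
    )


def build_similarity_network(
    matrices: dict[str, DistanceMatrix],
    cutoff: float,
    keep_isolated: bool = False,
) -> SimilarityNetwork:
    """Overlay per-condition distance matrices into one network.

    An edge is created for every condition in which the pair's distance is at
    or below ``cutoff``; the edge carries the supporting condition set and the
    per-condition distances.  Nodes without edges are omitted unless
    ``keep_isolated`` is set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    net = SimilarityNetwork(cutoff=cutoff)
    for condition, matrix in matrices.items():
        ids = matrix.compound_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = float(matrix.values[i, j])
                if d <= cutoff:
                    net.add_edge(ids[i], ids[j], d, condition)
        if keep_isolated:
            net.nodes.update(ids)
    return net


def nearest_neighbors(
    matrix: DistanceMatrix, compound_id: str, k: int
) -> list[tuple[str, float]]:
    """The k most MID-similar compounds, ascending by distance.

    Ties break by compound_id; among multiple derivatives sharing a metabolite
    name only the nearest is reported (unnamed compounds are never merged).
    """
    if compound_id not in matrix.compound_ids:
        raise KeyError(f"compound {compound_id!r} not in distance matrix")
    idx = matrix.compound_ids.index(compound_id)
    candidates = sorted(
        (
            (float(matrix.values[idx, j]), other)
            for j, other in enumerate(matrix.compound_ids)
            if other != compound_id
        ),
    )
    own_name = matrix.names.get(compound_id)
    seen_names: set[str] = set()
    out: list[tuple[str, float]] = []
    for dist, other in candidates:
        name = matrix.names.get(other)
        if name is not None:
            if name in seen_names or name == own_name:
                continue
            seen_names.add(name)
        out.append((other, dist))
        if len(out) == k:
            break
    return out


def to_networkx(net: SimilarityNetwork) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(sorted(net.nodes))
    for (a, b), attrs in sorted(net.edges.items()):
        graph.add_edge(
            a,
            b,
            distance=min(attrs["distances"].values()),
            conditions=";".join(sorted(attrs["conditions"])),
        )
    return graph


def write_graphml(net: SimilarityNetwork, path) -> None:
    nx.write_graphml(to_networkx(net), path)


def write_edge_list(net: SimilarityNetwork, path) -> None:
    """Flat TSV: source, target, distance, semicolon-joined conditions."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tdistance\tconditions\n")
        for (a, b), attrs in sorted(net.edges.items()):
            d = min(attrs["distances"].values())
            conds = ";".join(sorted(attrs["conditions"]))
            fh.write(f"{a}\t{b}\t{d:.6g}\t{conds}\n")
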