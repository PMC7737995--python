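"""Minimum-spanning haplotype networks.

Nodes are haplotypes sized by frequency and annotated with their
composition (per individual, population, or group); links carry integer
mutational-step weights equal to the Hamming distance of their
endpoints. The backbone is a minimum spanning tree computed with
Kruskal's algorithm under deterministic tie-breaking (weight, then
lexicographic endpoint pair); on top of it, "alternative" links record
equally parsimonious connections: every non-tree pair whose weight
equals the weight of the edge that first connected its two components
during MST construction. A looser exploratory rule (all non-tree pairs
with weight <= a threshold) is available via ``alt_threshold``.
No median/inferred intermediate nodes are ever created.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .haplotype import HaplotypeSet
from .seqio import PopulationMap

__all__ = ["Link", "HaploNetwork", "build_network", "mst_total_weight"]


@dataclass(frozen=True)
class Link:
    u: str
    v: str
    weight: int
    kind: str  # "mst" | "alternative"


@dataclass
class HaploNetwork:
    """Haplotype nodes with sizes/compositions plus weighted links."""

    node_ids: list[str]
    sizes: dict[str, int]
    compositions: dict[str, dict[str, int]]
    links: list[Link]
    level: str = "population"

    @property
    def mst_links(self) -> list[Link]:
        return [l for l in self.links if l.kind == "mst"]

    @property
    def alternative_links(self) -> list[Link]:
        return [l for l in self.links if l.kind == "alternative"]

    def categories(self) -> list[str]:
        cats: set[str] = set()
        for comp in self.compositions.values():
            cats.update(comp)
        return sorted(cats)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.u, l.v, l.weight, l.kind) for l in self.links],
            columns=["from", "to", "weight", "kind"],
        )

    def node_table(self) -> pd.DataFrame:
        cats = self.categories()
        rows = [
            [h, self.sizes[h]] + [self.compositions[h].get(c, 0) for c in cats]
            for h in self.node_ids
        ]
        return pd.DataFrame(rows, columns=["id", "size"] + cats).set_index("id")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "level": self.level,
            "nodes": [
                {
                    "id": h,
                    "size": self.sizes[h],
                    "composition": self.compositions[h],
                }
                for h in self.node_ids
            ],
            "links": [
                {"from": l.u, "to": l.v, "weight": l.weight, "kind": l.kind}
                for l in self.links
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_network(
    d: DistanceMatrix,
    hs: HaplotypeSet,
    pm: Optional[PopulationMap] = None,
    level: str = "individual",
    alt_threshold: Optional[int] = None,
) -> HaploNetwork:
    """Build the minimum-spanning haplotype network.

    ``d`` must be the integer Hamming matrix over the haplotypes of
    ``hs``. The composition of each node is tabulated at ``level``
    ("individual", "population", "group"); the latter two require a
    :class:`~haplokit.seqio.PopulationMap`. ``alt_threshold`` adds every
    non-tree pair with weight <= the threshold as an alternative link,
    on top of the equal-cost-at-merge-time rule.
    """
    if sorted(d.labels) != sorted(hs.ids):
        raise ValueError("distance matrix labels do not match haplotype ids")
    if not np.allclose(d.values, np.round(d.values)):
        raise ValueError("haplotype network needs integer (Hamming) distances")
    if level in ("population", "group") and pm is None:
        raise ValueError(f"level={level!r} requires a PopulationMap")

    ids = list(d.labels)
    index = {h: i for i, h in enumerate(ids)}
    k = len(ids)

    # Kruskal with deterministic tie-break: weight, then lexicographic pair
    edges = sorted(
        (
            (int(round(d.values[index[a], index[b]])), a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ),
        key=lambda e: (e[0], *sorted((e[1], e[2]))),
    )
    uf = _UnionFind(k)
    # weight of the MST edge that first connected each pair's components
    merge_weight = np.zeros((k, k))
    components: dict[int, set[int]] = {i: {i} for i in range(k)}
    mst: list[tuple[str, str, int]] = []
    for w, a, b in edges:
        ia, ib = index[a], index[b]
        ra, rb = uf.find(ia), uf.find(ib)
        if ra == rb:
            continue
        for x in components[ra]:
            for y in components[rb]:
                merge_weight[x, y] = merge_weight[y, x] = w
        uf.union(ia, ib)
        root = uf.find(ia)
        merged = components.pop(ra) | components.pop(rb)
        components[root] = merged
        mst.append((*sorted((a, b)), w))
        if len(mst) == k - 1:
            break

    mst_pairs = {(a, b) for a, b, _ in mst}
    links = [Link(a, b, w, "mst") for a, b, w in mst]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa, pb = sorted((a, b))
            if (pa, pb) in mst_pairs:
                continue
            w = int(round(d.values[index[a], index[b]]))
            is_alt = w == merge_weight[index[a], index[b]]
            if alt_threshold is not None:
                is_alt = is_alt or w <= alt_threshold
            if is_alt:
                links.append(Link(pa, pb, w, "alternative"))
    links.sort(key=lambda l: (l.kind != "mst", l.weight, l.u, l.v))

    sizes = {h.id: h.hf for h in hs}
    compositions: dict[str, dict[str, int]] = {}
    for h in hs:
        comp: dict[str, int] = {}
        for m in h.members:
            cat = m if level == "individual" else pm.category_of(m, level)  # type: ignore[union-attr]
            comp[cat] = comp.get(cat, 0) + 1
        compositions[h.id] = comp

    return HaploNetwork(
        node_ids=ids,
        sizes=sizes,
        compositions=compositions,
        links=links,
        level=level,
    )


def mst_total_weight(net: HaploNetwork) -> int:
    """Total mutational steps on the spanning-tree backbone (minimal
    over all spanning trees)."""
    return sum(l.weight for l in net.mst_links)
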