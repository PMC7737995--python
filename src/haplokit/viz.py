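"""Figure rendering: alignment+tree panel, clustered distance heatmap,
haplotype network with pies and mutation ticks, and annotated
(rectangular or circular) NJ trees.

Colors default to the conventions of the reference analysis where those
are recorded: nucleotides rosybrown/sienna/light-goldenrod/light-sky-blue
for A/C/G/T, bootstrap confidence black/red/pink/white from strong to
poor, and blue/red/green for the greenhouse/firm/nature provenance
groups. Every palette is overridable through :class:`PlotSpec`. Layout
is deterministic for fixed input (the network layout is force-directed
with a fixed seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, ListedColormap, Normalize
from matplotlib.patches import Patch, Wedge
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix
from .network import HaploNetwork
from .phylo import Tree, TreeNode, bin_support
from .seqio import Alignment, PopulationMap

__all__ = [
    "PlotSpec",
    "NUCLEOTIDE_COLORS",
    "SUPPORT_COLORS",
    "GROUP_COLORS",
    "plot_msa_tree",
    "plot_heatmap",
    "plot_network",
    "plot_tree",
]

#: A, C, G, T plus a reserved gap color and N.
NUCLEOTIDE_COLORS = {
    "A": "#BC8F8F",  # rosybrown
    "C": "#FF8247",  # sienna1
    "G": "#FFEC8B",  # lightgoldenrod1
    "T": "#B0E2FF",  # lightskyblue1
    "-": "#D9D9D9",  # reserved gap color
    "N": "#8C8C8C",
}

#: Bootstrap-confidence palette ordered strong -> poor.
SUPPORT_COLORS = {
    "strong": "black",
    "moderate": "red",
    "weak": "#FFB5C5",  # pink1
    "poor": "white",
}

GROUP_COLORS = {"greenhouse": "blue", "firm": "red", "nature": "green"}

_BRANCH_CMAP = LinearSegmentedColormap.from_list(
    "branchlength", ["#8B3E2F", "#B0E2FF"]  # coral4 (short) -> lightskyblue1 (long)
)


@dataclass
class PlotSpec:
    """Rendering options shared by all figure kinds."""

    width: float = 8.0
    height: float = 6.0
    dpi: int = 150
    nucleotide_colors: dict[str, str] = field(
        default_factory=lambda: dict(NUCLEOTIDE_COLORS)
    )
    support_colors: dict[str, str] = field(
        default_factory=lambda: dict(SUPPORT_COLORS)
    )
    category_colors: Optional[dict[str, str]] = None
    size_mode: str = "area"  # node area (default) or radius scales with hf


def _rainbow(categories: list[str]) -> dict[str, str]:
    cmap = plt.get_cmap("hsv")
    n = max(len(categories), 1)
    return {
        c: matplotlib.colors.to_hex(cmap(i / n)) for i, c in enumerate(categories)
    }


def _category_colors(categories: list[str], spec: PlotSpec) -> dict[str, str]:
    if spec.category_colors:
        missing = [c for c in categories if c not in spec.category_colors]
        if missing:
            raise ValueError(f"no colors for categories: {missing}")
        return {c: spec.category_colors[c] for c in categories}
    if set(categories) <= set(GROUP_COLORS):
        return {c: GROUP_COLORS[c] for c in categories}
    return _rainbow(categories)


# --- tree layout -----------------------------------------------------------


def _rect_layout(tree: Tree):
    """Rectangular layout: x = path length from root, tips evenly
    spaced in y, internal nodes centred over their children. Returns
    (coords keyed by id(node), ordered tip list, node list)."""
    coords: dict[int, tuple[float, float]] = {}
    tip_order: list[TreeNode] = []
    nodes: list[TreeNode] = []

    def walk(n: TreeNode, x: float) -> float:
        nodes.append(n)
        x_here = x + float(n.length or 0.0)
        if n.is_tip:
            y = float(len(tip_order))
            tip_order.append(n)
        else:
            ys = [walk(c, x_here) for c in n.children]
            y = (min(ys) + max(ys)) / 2.0
        coords[id(n)] = (x_here, y)
        return y

    walk(tree.root, 0.0)
    return coords, tip_order, nodes


def _draw_rect_tree(ax, tree: Tree, coords, edge_color=lambda child: "black", lw=1.0):
    def walk(n: TreeNode) -> None:
        x, y = coords[id(n)]
        for c in n.children:
            cx, cy = coords[id(c)]
            col = edge_color(c)
            ax.plot([x, x], [y, cy], color=col, lw=lw)
            ax.plot([x, cx], [cy, cy], color=col, lw=lw)
            walk(c)

    walk(tree.root)


def _polar(x: float, y: float, n_tips: int, max_x: float, inner: float = 0.1):
    theta = 2.0 * math.pi * y / n_tips
    r = inner + x / max_x if max_x > 0 else inner
    return r * math.cos(theta), r * math.sin(theta), theta, inner + (
        x / max_x if max_x > 0 else 0.0
    )


def _draw_circular_tree(ax, tree: Tree, coords, n_tips: int, edge_color, lw=1.0):
    max_x = max(c[0] for c in coords.values()) or 1.0

    def to_xy(x, y):
        theta = 2.0 * math.pi * y / n_tips
        r = 0.1 + x / max_x
        return r * math.cos(theta), r * math.sin(theta)

    def walk(n: TreeNode) -> None:
        x, y = coords[id(n)]
        for c in n.children:
            cx, cy = coords[id(c)]
            col = edge_color(c)
            # arc at the parent's radius from parent's angle to child's angle
            r = 0.1 + x / max_x
            th = np.linspace(
                2.0 * math.pi * y / n_tips, 2.0 * math.pi * cy / n_tips, 24
            )
            ax.plot(r * np.cos(th), r * np.sin(th), color=col, lw=lw)
            # radial segment out to the child
            x0, y0 = to_xy(x, cy)
            x1, y1 = to_xy(cx, cy)
            ax.plot([x0, x1], [y0, y1], color=col, lw=lw)
            walk(c)

    walk(tree.root)
    return to_xy


def _scale_bar(ax, length: float, label: str, color: str = "#8B3E2F") -> None:
    x0, x1 = ax.get_xlim()
    y0, y1 = ax.get_ylim()
    y = y0 + 0.04 * (y1 - y0)
    x = x0 + 0.05 * (x1 - x0)
    ax.plot([x, x + length], [y, y], color=color, lw=2)
    ax.text(x + length / 2, y, label, ha="center", va="bottom", fontsize=8, color=color)


def _round_scale(extent: float) -> float:
    if extent <= 0:
        return 1.0
    return 10.0 ** math.floor(math.log10(extent / 3.0)) if extent > 0 else 1.0


# --- figures ---------------------------------------------------------------


def plot_msa_tree(
    tree: Tree, al: Alignment, path: str | Path, spec: Optional[PlotSpec] = None
) -> dict:
    """Aligned sequences as colored cells, one row per tip, row order
    matching the plotted tree; the tree is drawn to the left with a
    scale bar. Gap characters use the reserved fifth color."""
    spec = spec or PlotSpec()
    tips = tree.tips()
    missing = [t for t in tips if t not in al.labels]
    if missing:
        raise ValueError(f"tips missing from alignment: {missing}")
    coords, tip_order, _ = _rect_layout(tree)

    fig, (ax_t, ax_m) = plt.subplots(
        1,
        2,
        figsize=(spec.width, spec.height),
        dpi=spec.dpi,
        gridspec_kw={"width_ratios": [1, 2]},
        sharey=True,
    )
    _draw_rect_tree(ax_t, tree, coords)
    for node in tip_order:
        x, y = coords[id(node)]
        ax_t.text(x, y, " " + (node.name or ""), va="center", fontsize=6)
    max_x = max(c[0] for c in coords.values()) or 1.0
    _scale_bar(ax_t, _round_scale(max_x), f"{_round_scale(max_x):g}")
    ax_t.axis("off")

    chars = sorted(spec.nucleotide_colors)
    char_idx = {c: i for i, c in enumerate(chars)}
    cmap = ListedColormap([spec.nucleotide_colors[c] for c in chars])
    order = [al.labels.index(n.name) for n in tip_order]
    mat = np.array(
        [[char_idx.get(c, char_idx.get("N", 0)) for c in al.sequences[i]] for i in order]
    )
    ax_m.imshow(
        mat,
        aspect="auto",
        cmap=cmap,
        vmin=0,
        vmax=len(chars) - 1,
        interpolation="nearest",
        extent=(0, al.length, len(tips) - 0.5, -0.5),
    )
    ax_m.set_yticks([])
    ax_m.set_xlabel("site")
    present = sorted({c for s in al.sequences for c in s})
    fig.legend(
        handles=[Patch(color=spec.nucleotide_colors[c], label=c) for c in present],
        loc="lower right",
        ncol=len(present),
        fontsize=7,
    )
    fig.savefig(path)
    plt.close(fig)
    return {
        "path": str(path),
        "n_rows": len(tips),
        "tip_order": [n.name for n in tip_order],
        "legend": present,
    }


def plot_heatmap(
    d: DistanceMatrix, path: str | Path, spec: Optional[PlotSpec] = None
) -> dict:
    """Symmetric distance heatmap with complete-linkage dendrograms on
    both margins; dark red marks small distances (close relationships),
    white large ones. Row and column order are identical."""
    spec = spec or PlotSpec()
    cmap = LinearSegmentedColormap.from_list("closeness", ["darkred", "#FFD6D6", "white"])
    fig = plt.figure(figsize=(spec.width, spec.height), dpi=spec.dpi)

    if d.k == 1:
        ax = fig.add_subplot(111)
        ax.imshow([[0.0]], cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks([0]), ax.set_yticks([0])
        ax.set_xticklabels(d.labels), ax.set_yticklabels(d.labels)
        fig.savefig(path)
        plt.close(fig)
        return {"path": str(path), "order": list(d.labels)}

    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    leaves = hierarchy.leaves_list(Z)
    order = [d.labels[i] for i in leaves]
    M = d.values[np.ix_(leaves, leaves)]

    ax_top = fig.add_axes([0.25, 0.76, 0.55, 0.18])
    ax_left = fig.add_axes([0.05, 0.18, 0.18, 0.55])
    ax_hm = fig.add_axes([0.25, 0.18, 0.55, 0.55])
    ax_cb = fig.add_axes([0.84, 0.18, 0.03, 0.55])
    with plt.rc_context({"lines.linewidth": 0.8}):
        hierarchy.dendrogram(Z, ax=ax_top, no_labels=True, color_threshold=0)
        hierarchy.dendrogram(
            Z, ax=ax_left, no_labels=True, orientation="left", color_threshold=0
        )
    ax_left.invert_yaxis()
    ax_top.axis("off")
    ax_left.axis("off")
    im = ax_hm.imshow(M, cmap=cmap, interpolation="nearest", aspect="auto")
    ax_hm.set_xticks(range(d.k))
    ax_hm.set_yticks(range(d.k))
    ax_hm.set_xticklabels(order, rotation=90, fontsize=6)
    ax_hm.set_yticklabels(order, fontsize=6)
    fig.colorbar(im, cax=ax_cb)
    fig.savefig(path)
    plt.close(fig)
    return {"path": str(path), "order": order}


def _node_radii(net: HaploNetwork, spec: PlotSpec, scale: float) -> dict[str, float]:
    sizes = np.array([net.sizes[h] for h in net.node_ids], dtype=float)
    if spec.size_mode == "area":
        raw = np.sqrt(sizes)
    elif spec.size_mode == "radius":
        raw = sizes
    else:
        raise ValueError(f"unknown size_mode: {spec.size_mode!r}")
    raw = raw / raw.max() if raw.max() > 0 else raw
    return {h: float(0.04 * scale + 0.10 * scale * r) for h, r in zip(net.node_ids, raw)}


def _edge_ticks(ax, p0, p1, r0, r1, weight: int, color="0.3") -> None:
    """Draw `weight` short dashes perpendicular to the visible part of
    the link (one dash per mutational step)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    v = p1 - p0
    L = np.hypot(*v)
    if L <= r0 + r1 or weight <= 0:
        return
    u = v / L
    n = np.array([-u[1], u[0]])
    a, b = r0 / L, 1.0 - r1 / L
    ts = a + (b - a) * (np.arange(1, weight + 1) / (weight + 1))
    half = 0.012 * max(L, 1e-9) / max(weight ** 0.25, 1.0)
    half = min(half, 0.02)
    for t in ts:
        c = p0 + t * v
        ax.plot(
            [c[0] - half * n[0], c[0] + half * n[0]],
            [c[1] - half * n[1], c[1] + half * n[1]],
            color=color,
            lw=1.0,
        )


def plot_network(
    net: HaploNetwork,
    path: str | Path,
    spec: Optional[PlotSpec] = None,
    seed: int = 0,
) -> dict:
    """Haplotype network: pies sized by frequency (area by default),
    one slice per composition category, mutation ticks on links, and a
    category legend. MST links are solid, alternative links dashed."""
    spec = spec or PlotSpec()
    cats = net.categories()
    colors = _category_colors(cats, spec)

    G = nx.Graph()
    G.add_nodes_from(net.node_ids)
    for l in net.mst_links:
        G.add_edge(l.u, l.v, weight=l.weight)
    pos = nx.spring_layout(G, seed=seed, weight=None)
    span = max(
        (max(p[0] for p in pos.values()) - min(p[0] for p in pos.values())),
        (max(p[1] for p in pos.values()) - min(p[1] for p in pos.values())),
        1e-6,
    )
    radii = _node_radii(net, spec, scale=span / 4.0)

    fig, ax = plt.subplots(figsize=(spec.width, spec.height), dpi=spec.dpi)
    for l in net.links:
        p0, p1 = pos[l.u], pos[l.v]
        style = "-" if l.kind == "mst" else "--"
        ax.plot(
            [p0[0], p1[0]],
            [p0[1], p1[1]],
            style,
            color="0.55" if l.kind == "mst" else "0.8",
            lw=1.2 if l.kind == "mst" else 0.8,
            zorder=1,
        )
        if l.kind == "mst":
            _edge_ticks(ax, p0, p1, radii[l.u], radii[l.v], l.weight)
    for h in net.node_ids:
        x, y = pos[h]
        r = radii[h]
        comp = net.compositions[h]
        total = sum(comp.values()) or 1
        start = 90.0
        for cat in cats:
            frac = comp.get(cat, 0) / total
            if frac <= 0:
                continue
            sweep = 360.0 * frac
            ax.add_patch(
                Wedge(
                    (x, y), r, start, start + sweep,
                    facecolor=colors[cat], edgecolor="black", lw=0.5, zorder=2,
                )
            )
            start += sweep
        ax.text(x, y - r, h, ha="center", va="top", fontsize=7, zorder=3)
    ax.legend(
        handles=[Patch(color=colors[c], label=c) for c in cats],
        loc="upper right",
        fontsize=6,
        ncol=1 if len(cats) <= 12 else 3,
    )
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path)
    plt.close(fig)
    return {
        "path": str(path),
        "n_nodes": len(net.node_ids),
        "n_links": len(net.links),
        "legend": cats,
    }


def plot_tree(
    tree: Tree,
    mode: str,
    layout: str = "rectangular",
    path: str | Path = "tree.png",
    pm: Optional[PopulationMap] = None,
    spec: Optional[PlotSpec] = None,
    support_convention: str = "code",
) -> dict:
    """Annotated NJ tree.

    ``mode`` selects the annotation: ``population-color`` (tips colored
    by population, legend per population; requires ``pm``),
    ``branchlength-color`` (edges on a continuous short->long gradient
    with a colorbar), or ``support-nodes`` (internal node points filled
    by bootstrap confidence bin). ``layout`` is ``rectangular`` or
    ``circular``. A scale bar is always drawn.
    """
    spec = spec or PlotSpec()
    if mode not in ("population-color", "branchlength-color", "support-nodes"):
        raise ValueError(f"unknown mode: {mode!r}")
    if layout not in ("rectangular", "circular"):
        raise ValueError(f"unknown layout: {layout!r}")
    if mode == "population-color" and pm is None:
        raise ValueError("population-color mode requires a PopulationMap")
    if mode == "support-nodes":
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        if not supports:
            raise ValueError("support-nodes mode requires bootstrap supports")

    coords, tip_order, _nodes = _rect_layout(tree)
    n_tips = len(tip_order)
    lengths = [
        float(c.length or 0.0)
        for n in [tree.root] + tree.internal_nodes()
        for c in n.children
    ]
    norm = Normalize(vmin=min(lengths) if lengths else 0, vmax=max(lengths) or 1)

    if mode == "branchlength-color":
        edge_color = lambda child: _BRANCH_CMAP(norm(float(child.length or 0.0)))
    else:
        edge_color = lambda child: "black"

    fig, ax = plt.subplots(figsize=(spec.width, spec.height), dpi=spec.dpi)
    legend_entries: list[str] = []
    max_x = max(c[0] for c in coords.values()) or 1.0

    if layout == "rectangular":
        _draw_rect_tree(ax, tree, coords, edge_color=edge_color)
        tip_xy = {n.name: coords[id(n)] for n in tip_order}
        label_rot = {}
    else:
        to_xy = _draw_circular_tree(ax, tree, coords, n_tips, edge_color=edge_color)
        tip_xy = {}
        label_rot = {}
        for n in tip_order:
            x, y = coords[id(n)]
            tip_xy[n.name] = to_xy(x, y)
            label_rot[n.name] = math.degrees(2.0 * math.pi * y / n_tips)

    if mode == "population-color":
        pops = sorted({pm.population_of(t) for t in tree.tips()})
        pop_colors = _category_colors(pops, spec)
        for name, (x, y) in tip_xy.items():
            ax.text(
                x, y, " " + name,
                color=pop_colors[pm.population_of(name)],
                fontsize=6, va="center",
                rotation=label_rot.get(name, 0), rotation_mode="anchor",
            )
        ax.legend(
            handles=[Patch(color=pop_colors[p], label=p) for p in pops],
            loc="upper right", fontsize=6,
        )
        legend_entries = pops
    else:
        for name, (x, y) in tip_xy.items():
            ax.text(
                x, y, " " + name, fontsize=6, va="center",
                rotation=label_rot.get(name, 0), rotation_mode="anchor",
            )

    if mode == "branchlength-color":
        sm = plt.cm.ScalarMappable(norm=norm, cmap=_BRANCH_CMAP)
        cb = fig.colorbar(sm, ax=ax, shrink=0.6)
        cb.set_label("branch length")
        legend_entries = ["branch length"]

    if mode == "support-nodes":
        for n in tree.internal_nodes():
            if n.support is None:
                continue
            cat = bin_support(n.support, convention=support_convention)
            x, y = coords[id(n)]
            if layout == "circular":
                x, y = to_xy(x, y)
            ax.plot(
                [x], [y], "o",
                markerfacecolor=spec.support_colors[cat],
                markeredgecolor="black", markersize=7, zorder=3,
            )
        order = ["strong", "moderate", "weak", "poor"]
        ax.legend(
            handles=[
                Patch(facecolor=spec.support_colors[c], edgecolor="black", label=c)
                for c in order
            ],
            loc="lower right", fontsize=7, title="bootstrap",
        )
        legend_entries = order

    if layout == "rectangular":
        ax.set_xlim(-0.02 * max_x, 1.35 * max_x)
    scale = _round_scale(max_x)
    _scale_bar(ax, scale if layout == "rectangular" else scale / max_x, f"{scale:g}")
    ax.axis("off")
    fig.savefig(path)
    plt.close(fig)
    return {
        "path": str(path),
        "mode": mode,
        "layout": layout,
        "legend": legend_entries,
        "n_tips": n_tips,
    }
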