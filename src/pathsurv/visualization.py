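"""Hierarchy-aware visualization of pathway-level survival statistics.

The pathway hierarchy (a DAG) is expanded into a tree — a node with several
parents is duplicated under each — joined by a synthetic root, and rendered
as a sunburst: rings are hierarchy levels, angular segments are pathways,
and the fill encodes the signed significance ``sign(beta) * min(-log10(q),
cap)`` on a diverging map centered at zero (protective vs hazardous).  The
output is one deterministic, self-contained HTML file with an embedded SVG
(hover tooltips carry name, p, q, beta and size).  Static concordance-index
histograms are drawn with matplotlib.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps, colors

from .errors import ValidationError
from .io_formats import PathwayHierarchy

__all__ = ["SunburstNode", "expand_dag_to_tree", "render_sunburst",
           "plot_cindex_histograms"]

ROOT_KEY = "__root__"


@dataclass
class SunburstNode:
    """One segment of the expanded tree (a pathway may appear in several)."""

    key: str                 # unique path key within the expanded tree
    pathway_id: str
    display_name: str
    parent: str | None       # parent key in the expanded tree (None for root)
    depth: int
    children: list[str] = field(default_factory=list)
    value: float = 0.0       # sign(beta) * min(-log10(q), cap); 0 = neutral
    angular_weight: float = 0.0
    # filled at render time
    theta0: float = 0.0
    theta1: float = 0.0
    hover: str = ""


def expand_dag_to_tree(hierarchy: PathwayHierarchy) -> dict[str, SunburstNode]:
    """Duplicate multi-parent nodes so the DAG becomes a rooted tree.

    Every node with k parents yields k copies (identical statistics); a
    synthetic root joins the hierarchy's top-level pathways.  Returns a dict
    keyed by unique path key, with the root at ``ROOT_KEY``.
    """
    children_map: dict[str, list[str]] = {}
    for parent, child in hierarchy.edges:
        children_map.setdefault(parent, []).append(child)

    nodes: dict[str, SunburstNode] = {
        ROOT_KEY: SunburstNode(ROOT_KEY, ROOT_KEY, "all pathways", None, 0)
    }

    def walk(pathway_id: str, parent_key: str, depth: int) -> None:
        key = f"{parent_key}/{pathway_id}"
        nodes[key] = SunburstNode(key, pathway_id, pathway_id, parent_key, depth)
        nodes[parent_key].children.append(key)
        for child in children_map.get(pathway_id, []):
            walk(child, key, depth + 1)

    for root in hierarchy.roots:
        walk(root, ROOT_KEY, 1)
    return nodes


def _assign_angles(nodes: dict[str, SunburstNode], size_weights=None) -> None:
    """Equal angular weight per leaf (or pathway-size weights); sibling
    angles sum exactly to the parent's span, the first ring spans 360 deg."""

    def leaf_weight(key: str) -> float:
        node = nodes[key]
        if not node.children:
            w = 1.0 if size_weights is None else float(size_weights.get(node.pathway_id, 1.0))
            node.angular_weight = w
            return w
        node.angular_weight = sum(leaf_weight(c) for c in node.children)
        return node.angular_weight

    def spread(key: str, theta0: float, theta1: float) -> None:
        node = nodes[key]
        node.theta0, node.theta1 = theta0, theta1
        total = sum(nodes[c].angular_weight for c in node.children)
        start = theta0
        for child in node.children:
            span = (theta1 - theta0) * nodes[child].angular_weight / total
            spread(child, start, start + span)
            start += span

    leaf_weight(ROOT_KEY)
    spread(ROOT_KEY, 0.0, 2.0 * math.pi)


def _annular_sector_path(cx, cy, r0, r1, theta0, theta1) -> str:
    if theta1 - theta0 >= 2.0 * math.pi - 1e-9:
        theta1 = theta0 + 2.0 * math.pi - 1e-6
    large = 1 if (theta1 - theta0) > math.pi else 0
    x0o, y0o = cx + r1 * math.cos(theta0), cy + r1 * math.sin(theta0)
    x1o, y1o = cx + r1 * math.cos(theta1), cy + r1 * math.sin(theta1)
    x1i, y1i = cx + r0 * math.cos(theta1), cy + r0 * math.sin(theta1)
    x0i, y0i = cx + r0 * math.cos(theta0), cy + r0 * math.sin(theta0)
    return (f"M {x0o:.3f} {y0o:.3f} "
            f"A {r1:.3f} {r1:.3f} 0 {large} 1 {x1o:.3f} {y1o:.3f} "
            f"L {x1i:.3f} {y1i:.3f} "
            f"A {r0:.3f} {r0:.3f} 0 {large} 0 {x0i:.3f} {y0i:.3f} Z")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Pathway survival sunburst</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
path:hover {{ stroke: #000; stroke-width: 1.5; cursor: pointer; }}
#legend {{ font-size: 0.85em; color: #444; }}
</style>
</head>
<body>
<h2>Pathway-level survival significance</h2>
<p id="legend">Fill: sign(&beta;) &middot; min(&minus;log<sub>10</sub> q, {cap})
&mdash; blue protective, red hazardous, white neutral. Hover a segment for
name, &beta;, p, q and size.</p>
{svg}
</body>
</html>
"""


def render_sunburst(tree: dict[str, SunburstNode], results, out_path,
                    cap: float = 10.0, size_weights=None,
                    signed: bool = True) -> None:
    """Write a self-contained interactive sunburst HTML.

    ``results`` is an iterable with ``pathway_id``, ``beta``, ``p``, ``q``
    and ``n_genes_used`` attributes (pathways missing a result render
    neutral).  Duplicated DAG copies of a pathway carry identical values.
    With ``signed=False`` the fill encodes significance only.
    """
    by_id = {r.pathway_id: r for r in results}
    for node in tree.values():
        if node.key == ROOT_KEY:
            continue
        r = by_id.get(node.pathway_id)
        if r is None or not np.isfinite(r.q) or not np.isfinite(r.beta):
            node.value = 0.0
            node.hover = f"{node.display_name}: no result"
            continue
        magnitude = min(-math.log10(max(r.q, 1e-300)), cap)
        sign = math.copysign(1.0, r.beta) if signed else 1.0
        node.value = sign * magnitude
        node.hover = (f"{node.display_name or node.pathway_id}\n"
                      f"beta={r.beta:.4g} p={r.p:.3g} q={r.q:.3g} "
                      f"size={getattr(r, 'n_genes_used', '?')}")
    _assign_angles(tree, size_weights=size_weights)

    depth = max(n.depth for n in tree.values())
    ring = 52.0
    radius = 30.0 + depth * ring
    cx = cy = radius + 10.0
    cmap = colormaps["RdBu_r"]
    norm = colors.Normalize(vmin=-cap, vmax=cap)

    parts = [f'<svg width="{2 * cx:.0f}" height="{2 * cy:.0f}" '
             f'xmlns="http://www.w3.org/2000/svg">']
    for key in sorted(tree):
        node = tree[key]
        if node.key == ROOT_KEY:
            continue
        r0 = 30.0 + (node.depth - 1) * ring
        r1 = r0 + ring - 2.0
        fill = colors.to_hex(cmap(norm(node.value)))
        path = _annular_sector_path(cx, cy, r0, r1, node.theta0, node.theta1)
        tooltip = html.escape(node.hover or node.display_name)
        parts.append(f'<path d="{path}" fill="{fill}" stroke="#fff" '
                     f'stroke-width="0.5"><title>{tooltip}</title></path>')
    parts.append("</svg>")
    content = _HTML_TEMPLATE.format(cap=f"{cap:g}", svg="\n".join(parts))
    try:
        with open(out_path, "w") as handle:
            handle.write(content)
    except OSError as exc:
        raise ValidationError(f"cannot write sunburst to {out_path}: {exc}") from exc


def plot_cindex_histograms(groups: dict[str, list], out_path, n_bins: int = 50) -> None:
    """Overlaid histograms of mean concordance indices, fixed bins on [0, 1].

    Typical use: one group of per-pathway mean C values against one of
    per-transcript values, the pathway-vs-transcript comparison.
    """
    if not groups:
        raise ValidationError("no groups to plot")
    for name, values in groups.items():
        if len(values) == 0:
            raise ValidationError(f"group {name!r} is empty")
    bins = np.linspace(0.0, 1.0, n_bins + 1)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, values in groups.items():
        ax.hist(np.asarray(values, dtype=float), bins=bins, alpha=0.55,
                label=name, edgecolor="none")
    ax.axvline(0.5, color="grey", linestyle="--", linewidth=1,
               label="null prediction (C = 0.5)")
    ax.set_xlabel("mean cross-validated concordance index")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
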