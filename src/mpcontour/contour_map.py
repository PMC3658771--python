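"""Adaptive contour map and inclusion tree.

A multipass run yields a chain of strictly nested inner regions.  The
contour map assigns every pixel the index of the deepest pass whose inner
region contains it (0 = outside all contours), and stores the sub-pixel
zero-level polylines of each pass.  The inclusion tree records the
nesting: the root is the whole domain w0; pass k splits the chain node
w_{k-1} into the inner child w_k (re-split by the next pass) and the
annotated outer sibling w-bar_k (a leaf).  Because only inner regions are
re-split, the chain of inner nodes is a path.

Coordinates are 0-based (row, col) with pixel centers at integer
positions; polylines interpolate the zero crossing linearly along pixel
edges (marching squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .multipass import MultipassResult
from .preprocessing import as_image_field

__all__ = [
    "ContourMap",
    "InclusionNode",
    "InclusionTree",
    "extract_zero_contours",
    "build_contour_map",
    "build_inclusion_tree",
]


@dataclass
class ContourMap:
    """Per-pixel depth labels plus the per-pass zero-level polylines.

    ``labels[p] == k`` iff pixel p lies in the inner region of pass k but
    not of pass k+1; label 0 is reserved for "outside all contours", so
    label values equal contour depth.  ``contours[k]`` holds the polylines
    of pass k+1 (0-based list index), each an (N, 2) array of (row, col)
    vertices.
    """

    labels: np.ndarray
    contours: list[list[np.ndarray]] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.contours)

    def inner_mask(self, k: int) -> np.ndarray:
        """Reconstruct the inner mask of pass k (1-based): labels >= k."""
        return self.labels >= k


@dataclass
class InclusionNode:
    """One region of the inclusion tree with its annotations."""

    name: str
    kind: str  # "root" | "inner" | "outer"
    depth: int
    area: int
    mean_intensity: float
    parent: str | None
    children: list[str] = field(default_factory=list)


@dataclass
class InclusionTree:
    """Path-shaped nesting tree over the contour map's regions."""

    nodes: dict[str, InclusionNode]
    root: str = "w0"

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": {
                name: {
                    "kind": n.kind,
                    "depth": n.depth,
                    "area": n.area,
                    "mean_intensity": n.mean_intensity,
                    "parent": n.parent,
                    "children": n.children,
                }
                for name, n in self.nodes.items()
            },
        }

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())


def extract_zero_contours(phi, parent_mask=None) -> list[np.ndarray]:
    """Sub-pixel polylines of the zero level set, clipped to a parent mask.

    Marching-squares extraction with linear interpolation on pixel edges;
    pixels outside ``parent_mask`` are treated as strictly outside the
    curve, so contours are clipped to the mask.  Polylines are (N, 2)
    float arrays of (row, col) vertices; a polyline is closed (first
    vertex repeated last) wherever the region does not touch the domain
    boundary.  Returns an empty list when phi has no zero crossing.
    """
    p = np.asarray(phi, dtype=float)
    if parent_mask is not None:
        m = np.asarray(parent_mask).astype(bool)
        fill = float(np.abs(p).max()) + 1.0
        p = np.where(m, p, fill)
    if p.min() >= 0 or p.max() <= 0:
        return []
    return [c for c in measure.find_contours(p, 0.0)]


def build_contour_map(result: MultipassResult) -> ContourMap:
    """Assemble labels and polylines from an ordered multipass result.

    The label of a pixel is the number of passes whose inner region
    contains it (valid because the regions are nested); the contour count
    equals the number of productive passes.
    """
    if result.n_passes == 0:
        shape = result.denoised.shape if result.denoised is not None else (0, 0)
        return ContourMap(np.zeros(shape, dtype=int), [])
    labels = np.zeros(result.passes[0].phi_final.shape, dtype=int)
    contours: list[list[np.ndarray]] = []
    parent = np.ones_like(labels, dtype=bool)
    for p in result.passes:
        labels += p.inner_mask.astype(int)
        contours.append(extract_zero_contours(p.phi_final, parent))
        parent = p.inner_mask
    return ContourMap(labels, contours)


def build_inclusion_tree(cmap: ContourMap, image) -> InclusionTree:
    """Annotated nesting tree of the contour map's regions.

    Chain nodes w0 > w1 > ... > wK follow the nested inner regions (each
    annotated with the area and mean intensity of the full nested region
    labels >= k); every split also produces an annotated outer-leaf
    sibling w-bar_k (pixels at exactly depth k-1).  The outer leaves plus
    the terminal wK partition the image, so their areas sum to the image
    area.
    """
    img = as_image_field(image)
    labels = cmap.labels
    if labels.shape != img.shape:
        raise ValueError(f"label shape {labels.shape} does not match image shape {img.shape}")
    k_max = int(labels.max()) if labels.size else 0
    nodes: dict[str, InclusionNode] = {}
    nodes["w0"] = InclusionNode(
        "w0", "root", 0, int(img.size), float(img.mean()) if img.size else float("nan"), None
    )
    for k in range(1, k_max + 1):
        inner = labels >= k
        outer = labels == (k - 1)
        parent = f"w{k - 1}"
        w_name = f"w{k}"
        wbar_name = f"wbar{k}"
        nodes[wbar_name] = InclusionNode(
            wbar_name,
            "outer",
            k,
            int(outer.sum()),
            float(img[outer].mean()) if outer.any() else float("nan"),
            parent,
        )
        nodes[w_name] = InclusionNode(
            w_name,
            "inner",
            k,
            int(inner.sum()),
            float(img[inner].mean()) if inner.any() else float("nan"),
            parent,
        )
        nodes[parent].children.extend([wbar_name, w_name])
    return InclusionTree(nodes)
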