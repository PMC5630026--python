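"""Fixed six-species primate phylogeny used throughout the package.

The study system is liver regulatory elements in six primates: human,
chimpanzee, rhesus macaque, marmoset (Haplorrhini) and mouse lemur,
bushbaby (Strepsirrhini outgroup).  The topology is fixed; branch lengths
are expected substitutions per site and default to values that place the
human-chimp pairwise divergence near 1% and human-mouse lemur near 15%,
matching the observed ordering of primate liver CRE divergences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

SPECIES: Tuple[str, ...] = (
    "human",
    "chimp",
    "rhesus",
    "marmoset",
    "mouse_lemur",
    "bushbaby",
)

#: clade name -> species descended from the branch subtending that clade
CLADES: Dict[str, FrozenSet[str]] = {
    "human": frozenset({"human"}),
    "chimp": frozenset({"chimp"}),
    "rhesus": frozenset({"rhesus"}),
    "marmoset": frozenset({"marmoset"}),
    "mouse_lemur": frozenset({"mouse_lemur"}),
    "bushbaby": frozenset({"bushbaby"}),
    "ape": frozenset({"human", "chimp"}),
    "catarrhini": frozenset({"human", "chimp", "rhesus"}),
    "haplorrhini": frozenset({"human", "chimp", "rhesus", "marmoset"}),
    "strepsirrhini": frozenset({"mouse_lemur", "bushbaby"}),
    "root": frozenset(SPECIES),
}


@dataclass(frozen=True)
class TreeNode:
    """A rooted tree node; ``length`` is the branch above this node."""

    name: str
    length: float
    children: Tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class SpeciesTree:
    """The rooted six-primate tree with per-branch substitution distances.

    ``scale`` multiplies every branch length; it is the knob the synthetic
    data generator exposes to sweep overall sequence divergence.
    """

    root: TreeNode
    scale: float = 1.0

    def __post_init__(self) -> None:
        leaves = sorted(self.root.leaves())
        if leaves != sorted(SPECIES):
            raise ValueError(f"tree must have exactly the six study species, got {leaves}")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")

    def leaf_distances(self) -> Dict[str, float]:
        """Root-to-leaf path lengths (scaled)."""
        out: Dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length * self.scale
            if node.is_leaf:
                out[node.name] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, 0.0)
        return out

    def pairwise_distance(self, a: str, b: str) -> float:
        """Patristic distance between two leaves (scaled)."""

        def path(node: TreeNode, target: str) -> List[TreeNode] | None:
            if node.name == target and node.is_leaf:
                return [node]
            for c in node.children:
                p = path(c, target)
                if p is not None:
                    return [node] + p
            return None

        pa, pb = path(self.root, a), path(self.root, b)
        if pa is None or pb is None:
            raise KeyError(f"unknown species {a!r}/{b!r}")
        shared = 0
        for x, y in zip(pa, pb):
            if x is y:
                shared += 1
            else:
                break
        dist = sum(n.length for n in pa[shared:]) + sum(n.length for n in pb[shared:])
        return dist * self.scale


def default_tree(scale: float = 1.0) -> SpeciesTree:
    """The default-calibrated primate tree.

    Branch lengths give pairwise human-X substitution distances of about
    0.01 (chimp), 0.05 (rhesus), 0.08 (marmoset) and 0.165 (mouse lemur,
    bushbaby) — observed mismatch fractions of ~0.01 and ~0.15 at the
    extremes under Jukes-Cantor — echoing the increasing divergence with
    phylogenetic distance seen across primate liver CREs.
    """
    root = TreeNode(
        "root",
        0.0,
        (
            TreeNode(
                "haplorrhini",
                0.010,
                (
                    TreeNode("marmoset", 0.040),
                    TreeNode(
                        "catarrhini",
                        0.015,
                        (
                            TreeNode("rhesus", 0.025),
                            TreeNode(
                                "ape",
                                0.020,
                                (TreeNode("human", 0.005), TreeNode("chimp", 0.005)),
                            ),
                        ),
                    ),
                ),
            ),
            TreeNode(
                "strepsirrhini",
                0.020,
                (TreeNode("mouse_lemur", 0.095), TreeNode("bushbaby", 0.095)),
            ),
        ),
    )
    return SpeciesTree(root=root, scale=scale)


def newick(tree: SpeciesTree) -> str:
    """Newick string of the (scaled) tree."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length * tree.scale:g}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.name}:{node.length * tree.scale:g}"

    return fmt(tree.root) + ";"
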