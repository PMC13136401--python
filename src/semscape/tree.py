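"""Rooted language family trees.

Languages sit at the leaves; the children of the root are the language
families, so every leaf has exactly one family ancestor at depth 1.  The
tree supports the step-counting distance used as a linguistic-history
proxy: the number of upward steps from each leaf until the two converge at
their lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class FamilyTree:
    graph: nx.DiGraph = field(repr=False)
    root: str = "ROOT"

    def __post_init__(self) -> None:
        if not nx.is_arborescence(self.graph):
            raise ValueError("family tree must be a rooted tree (arborescence)")
        if self.graph.in_degree(self.root) != 0:
            raise ValueError(f"{self.root!r} is not the root")

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    @property
    def families(self) -> list[str]:
        return list(self.graph.successors(self.root))

    def parent(self, node: str) -> str | None:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def path_to_root(self, leaf: str) -> list[str]:
        if leaf not in self.graph:
            raise KeyError(f"{leaf!r} not in tree")
        path = [leaf]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path

    def family_of(self, leaf: str) -> str:
        path = self.path_to_root(leaf)
        if len(path) < 2:
            raise ValueError(f"{leaf!r} is the root")
        return path[-2]

    def family_map(self) -> dict[str, str]:
        return {l: self.family_of(l) for l in self.leaves}
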