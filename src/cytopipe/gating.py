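"""Config-driven hierarchical gating.

Replaces interactive manual gating with an auditable threshold-gate tree on
the arcsinh(x/5) scale.  The default tree roots at the mononuclear gate
(CD45+ CD66−) — the denominator for every reported frequency — and
annotates the 13 reported mononuclear populations: CD4 and CD8 T cells,
activated (HLA-DR+Ki67+) CD8 T cells, double-negative (CD3+CD4−CD8−) T
cells, B cells and their IgM+ subset, CD56+CD16− and CD16+ NK cells, pDC,
mDC, and classical / intermediate / non-classical monocytes.  Intermediate
monocytes are gated CD11b+CD16+ (with HLA-DR to separate them from CD16+
NK cells).

Gate cutoffs live in config; the defaults sit midway between the synthetic
generator's negative and positive staining modes.  Events may satisfy no
reported leaf and remain unlabeled "other" mononuclear cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic import COFACTOR, EventMatrix

#: midpoint between the default synthetic negative (0.35) and positive (4.0)
#: staining modes on the arcsinh(x/5) scale
DEFAULT_CUTOFF = 2.2

ROOT = "mononuclear"


@dataclass
class GateNode:
    name: str
    parent: str | None
    rules: list            # (channel, op, cutoff) with op in {">", "<"}
    reported: bool = True

    def __post_init__(self) -> None:
        for ch, op, cut in self.rules:
            if op not in (">", "<"):
                raise ValueError(f"{self.name}: operator {op!r} not in >, <")
            float(cut)


@dataclass
class GateTree:
    nodes: dict[str, GateNode] = field(default_factory=dict)

    def validate(self, channels: list[str] | None = None) -> None:
        for name, node in self.nodes.items():
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(f"{name}: unknown parent {node.parent!r}")
            if node.parent == name:
                raise ValueError(f"{name}: node is its own parent")
            if channels is not None:
                for ch, _, _ in node.rules:
                    if ch not in channels:
                        raise ValueError(f"{name}: unknown channel {ch!r}")
        # cycle check by walking every chain to a root
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through node {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    @property
    def reported(self) -> list[str]:
        return [n for n, node in self.nodes.items() if node.reported]

    def children(self, name: str) -> list[str]:
        return [n for n, node in self.nodes.items() if node.parent == name]

    def topological(self) -> list[str]:
        order, placed = [], set()
        frontier = [n for n, nd in self.nodes.items() if nd.parent is None]
        while frontier:
            cur = frontier.pop(0)
            order.append(cur)
            placed.add(cur)
            frontier.extend(c for c in self.children(cur) if c not in placed)
        if len(order) != len(self.nodes):
            raise ValueError("gate tree is not a connected hierarchy")
        return order

    def to_dict(self) -> dict:
        return {"nodes": [
            {"name": n.name, "parent": n.parent, "reported": n.reported,
             "rules": [[ch, op, float(cut)] for ch, op, cut in n.rules]}
            for n in self.nodes.values()]}

    @classmethod
    def from_dict(cls, d: dict) -> "GateTree":
        tree = cls()
        for nd in d["nodes"]:
            name = nd["name"]
            if name in tree.nodes:
                raise ValueError(f"duplicate gate name {name!r}")
            tree.nodes[name] = GateNode(
                name=name, parent=nd.get("parent"),
                rules=[tuple(r) for r in nd.get("rules", [])],
                reported=bool(nd.get("reported", True)))
        tree.validate()
        return tree

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_gate_tree(cutoff: float = DEFAULT_CUTOFF) -> GateTree:
    """The default 13-population tree under the CD45+CD66− root."""
    c = cutoff
    layout = [
        (ROOT, None, [("CD45", ">", c), ("CD66", "<", c)], False),
        ("CD4T", ROOT, [("CD3", ">", c), ("CD4", ">", c), ("CD8", "<", c)], True),
        ("CD8T", ROOT, [("CD3", ">", c), ("CD8", ">", c), ("CD4", "<", c)], True),
        ("CD8T_act", "CD8T", [("HLA-DR", ">", c), ("Ki67", ">", c)], True),
        ("DNT", ROOT, [("CD3", ">", c), ("CD4", "<", c), ("CD8", "<", c)], True),
        ("B", ROOT, [("CD3", "<", c), ("CD20", ">", c)], True),
        ("B_IgM", "B", [("IgM", ">", c)], True),
        ("NK_CD56", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD56", ">", c),
                           ("CD16", "<", c), ("HLA-DR", "<", c)], True),
        ("NK_CD16", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD56", "<", c),
                           ("CD16", ">", c), ("HLA-DR", "<", c)], True),
        ("pDC", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD123", ">", c),
                       ("CD11c", "<", c), ("HLA-DR", ">", c)], True),
        ("mDC", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD11c", ">", c),
                       ("CD14", "<", c), ("CD16", "<", c), ("CD123", "<", c),
                       ("HLA-DR", ">", c)], True),
        ("cMC", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD14", ">", c),
                       ("CD16", "<", c), ("HLA-DR", ">", c)], True),
        ("intMC", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD11b", ">", c),
                         ("CD16", ">", c), ("HLA-DR", ">", c)], True),
        ("ncMC", ROOT, [("CD3", "<", c), ("CD20", "<", c), ("CD14", "<", c),
                        ("CD16", ">", c), ("CD11b", "<", c), ("CD11c", ">", c),
                        ("HLA-DR", ">", c)], True),
    ]
    tree = GateTree()
    for name, parent, rules, reported in layout:
        tree.nodes[name] = GateNode(name, parent, rules, reported)
    tree.validate()
    return tree


def build_gate_tree(config: dict | None = None, cutoff: float = DEFAULT_CUTOFF
                    ) -> GateTree:
    """Build a gate tree from a config mapping, or the default tree."""
    if config is None:
        return default_gate_tree(cutoff)
    return GateTree.from_dict(config)


@dataclass
class PopulationCounts:
    """Reported gate counts for one sample."""

    counts: dict            # population -> event count
    mononuclear_total: int

    def __post_init__(self) -> None:
        if self.mononuclear_total < 0 or any(v < 0 for v in self.counts.values()):
            raise ValueError("negative counts")
        for pop, v in self.counts.items():
            if v > self.mononuclear_total:
                raise ValueError(f"{pop}: count exceeds mononuclear total")


@dataclass
class GateResult:
    membership: pd.DataFrame     # events × nodes, boolean
    counts: PopulationCounts


def apply_gates(events: EventMatrix, tree: GateTree,
                cofactor: float = COFACTOR) -> GateResult:
    """Evaluate the gate hierarchy top-down on arcsinh-transformed events.

    An event belongs to a node iff it satisfies the node's own rule
    conjunction and its full ancestor chain, so child membership is a subset
    of parent membership by construction.  Events outside the mononuclear
    root contribute to no count and no denominator.
    """
    used = sorted({ch for node in tree.nodes.values()
                   for ch, _, _ in node.rules})
    missing = [ch for ch in used if ch not in events.data.columns]
    if missing:
        raise ValueError(f"events lack gating channels {missing}")
    tree.validate(channels=list(events.data.columns))

    z = {ch: np.arcsinh(events.data[ch].to_numpy() / cofactor) for ch in used}
    n = events.n_events
    membership: dict[str, np.ndarray] = {}
    for name in tree.topological():
        node = tree.nodes[name]
        mask = membership[node.parent].copy() if node.parent is not None \
            else np.ones(n, dtype=bool)
        for ch, op, cut in node.rules:
            mask &= (z[ch] > cut) if op == ">" else (z[ch] < cut)
        membership[name] = mask

    mono = int(membership[ROOT].sum()) if ROOT in membership else n
    counts = {name: int(membership[name].sum()) for name in tree.reported}
    return GateResult(
        membership=pd.DataFrame(membership),
        counts=PopulationCounts(counts=counts, mononuclear_total=mono),
    )
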