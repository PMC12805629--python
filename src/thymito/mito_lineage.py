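"""Mitochondrial mutation lineage trees from heteroplasmy VAFs.

Because a cell carries many mtDNA copies, conventional phylogenetics cannot
order its somatic mutations; instead the tree is grown from the VAFs
directly under three rules: (1) variants are ordered by descending VAF
below an unmutated root A0 at 100%; (2) branches are extended one variant
at a time starting from the largest VAF; (3) a node never takes on children
whose summed VAFs exceed its own (the pigeonhole constraint on genome
copies). Near-equal VAFs can optionally be merged into multi-mutation
clones before construction. The rules constrain but do not uniquely fix
each attachment, so two deterministic parent-selection policies are
provided: ``deepest`` (attach to the deepest node with enough residual
capacity, maximizing linearity) and ``residual`` (attach to the node with
the most spare capacity, favouring branching).

A clone's *proportion* is its VAF minus the summed VAFs of its children —
the fraction of mtDNA copies carrying exactly its mutation set — and the
proportions over any feasible tree sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_EPS = 1e-9


class InfeasibleTreeError(ValueError):
    """No placed node can accommodate the clone under rule 3."""


@dataclass(frozen=True)
class Mutation:
    """One mtDNA mutation entering the lineage construction."""

    id: str
    vaf: float
    region: str = ""
    pos: int = 0
    alt: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside (0, 1]")


def mutation_from_variant(v) -> Mutation:
    """Adapt a :class:`~thymito.mito_hetero.MitoVariant` for tree building."""
    return Mutation(
        id=f"m.{v.pos}{v.ref}>{v.alt}",
        vaf=v.h_tumour,
        region=getattr(v, "region", ""),
        pos=v.pos,
        alt=v.alt,
    )


@dataclass
class Clone:
    """A set of co-clonal mutations sharing one VAF (their mean)."""

    mutations: tuple[Mutation, ...]
    vaf: float

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.mutations)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(m.region for m in self.mutations)


@dataclass
class LineageNode:
    """One clone in the tree; the root is the unmutated state at VAF 1.0."""

    name: str
    vaf: float
    mutations: tuple[Mutation, ...] = ()
    children: list["LineageNode"] = field(default_factory=list)

    @property
    def residual(self) -> float:
        """Spare capacity: own VAF minus the summed VAFs of children."""
        return self.vaf - sum(c.vaf for c in self.children)

    @property
    def proportion(self) -> float:
        return self.residual

    def walk(self) -> Iterable["LineageNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class LineageTree:
    root: LineageNode

    @property
    def nodes(self) -> list[LineageNode]:
        return list(self.root.walk())

    @property
    def n_clones(self) -> int:
        return len(self.nodes) - 1

    @property
    def depth(self) -> int:
        def d(node):
            return 1 + max((d(c) for c in node.children), default=0)

        return d(self.root)

    @property
    def topology_class(self) -> str:
        """``linear`` iff every node has at most one child."""
        return (
            "linear"
            if all(len(n.children) <= 1 for n in self.nodes)
            else "branching"
        )

    @property
    def first_hit(self) -> LineageNode | None:
        """The clone with the largest VAF (child A1 of the root)."""
        if not self.root.children:
            return None
        return max(self.root.children, key=lambda n: n.vaf)

    def clone_proportions(self) -> dict[str, float]:
        """Node name -> proportion; validates rule-3 feasibility."""
        props = {}
        for node in self.nodes:
            p = node.residual
            if p < -_EPS:
                raise InfeasibleTreeError(
                    f"node {node.name}: children VAFs exceed own VAF by {-p:g}"
                )
            props[node.name] = max(p, 0.0)
        return props

    def to_indented_text(self) -> str:
        lines: list[str] = []

        def render(node: LineageNode, depth: int) -> None:
            muts = ",".join(m.id for m in node.mutations) or "-"
            lines.append(
                f"{'  ' * depth}{node.name} vaf={node.vaf:.3f} "
                f"p={node.residual:.3f} n={len(node.mutations)} [{muts}]"
            )
            for c in node.children:
                render(c, depth + 1)

        render(self.root, 0)
        return "\n".join(lines)

    def to_newick(self) -> str:
        """Newick string with clone proportion as a branch comment."""

        def render(node: LineageNode) -> str:
            label = f"{node.name}[&n={len(node.mutations)},p={node.residual:.3f}]"
            if not node.children:
                return label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def order_variants(mutations: Sequence[Mutation]) -> list[Mutation]:
    """Descending-VAF ordering A1..An; ties broken by (position, alt, id)."""
    return sorted(mutations, key=lambda m: (-m.vaf, m.pos, m.alt, m.id))


def merge_coclonal(
    ordered: Sequence[Mutation], delta: float = 0.02
) -> list[Clone]:
    """Merge adjacent near-equal VAFs into multi-mutation clones.

    Mutations whose consecutive VAF gaps are each < ``delta`` merge
    transitively along the ordered run; the clone's VAF is the member mean.
    ``delta=0`` disables merging.
    """
    clones: list[Clone] = []
    run: list[Mutation] = []
    for m in ordered:
        if run and run[-1].vaf - m.vaf < delta:
            run.append(m)
        else:
            if run:
                clones.append(_close_run(run))
            run = [m]
    if run:
        clones.append(_close_run(run))
    return clones


def _close_run(run: list[Mutation]) -> Clone:
    vaf = sum(m.vaf for m in run) / len(run)
    return Clone(mutations=tuple(run), vaf=vaf)


def build_tree(
    clones: Sequence[Clone], parent_rule: str = "deepest"
) -> LineageTree:
    """Grow the tree by inserting clones in descending VAF order.

    Each clone attaches to a placed node whose residual capacity covers its
    VAF. ``deepest`` picks the deepest such node (ties: the most recently
    placed), which always yields maximal depth; ``residual`` picks the node
    with the largest residual (ties: shallower, then earlier placed), the
    policy under which branching topologies arise. Raises
    :class:`InfeasibleTreeError` when no placed node has capacity.
    """
    if parent_rule not in ("deepest", "residual"):
        raise ValueError(f"unknown parent_rule {parent_rule!r}")
    root = LineageNode(name="A0", vaf=1.0)
    placed: list[tuple[LineageNode, int]] = [(root, 0)]  # (node, depth)
    ordered = sorted(
        clones, key=lambda c: (-c.vaf, c.mutations[0].pos, c.mutations[0].id)
    )
    for i, clone in enumerate(ordered, start=1):
        feasible = [
            (node, depth, order)
            for order, (node, depth) in enumerate(placed)
            if node.residual >= clone.vaf - _EPS
        ]
        if not feasible:
            raise InfeasibleTreeError(
                f"clone A{i} (VAF {clone.vaf:.3f}, mutations "
                f"{','.join(clone.ids)}) fits under no placed node"
            )
        if parent_rule == "deepest":
            parent, depth, _ = max(feasible, key=lambda t: (t[1], t[2]))
        else:
            parent, depth, _ = max(
                feasible, key=lambda t: (t[0].residual, -t[1], -t[2])
            )
        node = LineageNode(name=f"A{i}", vaf=clone.vaf, mutations=clone.mutations)
        parent.children.append(node)
        placed.append((node, depth + 1))
    return LineageTree(root=root)


def build_lineage(
    mutations: Sequence[Mutation],
    delta: float = 0.02,
    parent_rule: str = "deepest",
) -> LineageTree:
    """Order, merge and build in one call (empty input gives a bare root)."""
    clones = merge_coclonal(order_variants(mutations), delta=delta)
    return build_tree(clones, parent_rule=parent_rule)


def first_hit_stats(trees: Mapping[str, LineageTree]) -> pd.DataFrame:
    """Per-case first-hit summary across a cohort.

    Returns one row per case with the first-hit clone's VAF, mutation ids,
    regions and topology class; cases with an empty tree are skipped. The
    frame's ``attrs['fraction_vaf_ge_50']`` holds the cohort fraction of
    first-hit VAFs at or above 0.5.
    """
    rows = []
    skipped = []
    for case, tree in trees.items():
        hit = tree.first_hit
        if hit is None:
            skipped.append(case)
            continue
        rows.append(
            {
                "case": case,
                "first_hit_vaf": hit.vaf,
                "mutations": ",".join(m.id for m in hit.mutations),
                "regions": ",".join(m.region for m in hit.mutations),
                "n_clones": tree.n_clones,
                "topology": tree.topology_class,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "case",
            "first_hit_vaf",
            "mutations",
            "regions",
            "n_clones",
            "topology",
        ],
    )
    df.attrs["fraction_vaf_ge_50"] = (
        float((df["first_hit_vaf"] >= 0.5).mean()) if len(df) else float("nan")
    )
    df.attrs["skipped_cases"] = skipped
    return df
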