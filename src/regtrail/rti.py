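"""Regulator–target interaction (RTI) collections.

An RTI is a binary edge asserting that a regulator binds a regulatory region
of a target gene. Collections are built either from predefined edge lists or
by assigning regulator binding sites (BED regions) to genes whose TSS lies
within a chosen interval scheme of the site.

The four built-in interval schemes mirror the promoter-window conventions of
the common RTI databases: [-1 kb, +1 kb], [-5 kb, +5 kb], [-10 kb, +10 kb]
and [-10 kb, +1 kb] around the most-5' TSS. Asymmetric schemes are oriented
by gene strand ("upstream" means 5' of the gene), so a -10 kb/+1 kb window
for a minus-strand gene extends 10 kb to the right of the TSS in genome
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._errors import InputError
from .io import GeneModel, GenomicRegion


@dataclass(frozen=True)
class IntervalScheme:
    upstream_bp: int
    downstream_bp: int
    label: str = ""

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise InputError("interval scheme extents must be non-negative")
        if self.upstream_bp + self.downstream_bp == 0:
            raise InputError("interval scheme must have positive total extent")

    def window(self, tss: int, strand: str) -> tuple[int, int]:
        """Half-open genomic window accepting sites for a gene at ``tss``."""
        if strand == "+":
            lo, hi = tss - self.upstream_bp, tss + self.downstream_bp
        else:
            lo, hi = tss - self.downstream_bp, tss + self.upstream_bp
        return max(lo, 0), hi + 1  # closed position interval -> half-open


BUILTIN_SCHEMES: dict[str, IntervalScheme] = {
    "1k": IntervalScheme(1000, 1000, "1k"),
    "5k": IntervalScheme(5000, 5000, "5k"),
    "10k": IntervalScheme(10000, 10000, "10k"),
    "10k-1k": IntervalScheme(10000, 1000, "10k-1k"),
}


@dataclass
class RTICollection:
    """Mapping regulator -> ordered target set over a gene universe."""

    edges: dict[str, tuple[str, ...]]
    universe: frozenset[str]
    provenance: tuple[str, ...] = ()
    scheme: IntervalScheme | str = "predefined"

    def __post_init__(self):
        for reg, targets in self.edges.items():
            if not targets:
                raise InputError(f"regulator {reg} has an empty target set")
            stray = set(targets) - self.universe
            if stray:
                raise InputError(
                    f"targets of {reg} outside the universe: {sorted(stray)[:5]}"
                )

    @property
    def regulators(self) -> list[str]:
        return list(self.edges)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.edges.values())

    def targets(self, regulator: str) -> set[str]:
        return set(self.edges.get(regulator, ()))

    def edge_list(self) -> list[tuple[str, str]]:
        return [(r, t) for r, targets in self.edges.items() for t in targets]


def from_edge_list(
    edges: list[tuple[str, str]],
    universe: set[str] | None = None,
    provenance: str = "edge_list",
) -> RTICollection:
    """Group (regulator, target) edges into a collection.

    The universe defaults to all targets plus any regulators that also appear
    as targets. An edge whose target falls outside an explicit universe is an
    error.
    """
    grouped: dict[str, list[str]] = {}
    for reg, target in edges:
        bucket = grouped.setdefault(reg, [])
        if target not in bucket:
            bucket.append(target)
    if universe is None:
        targets = {t for _, t in edges}
        regs_as_targets = {r for r, _ in edges} & targets
        universe = targets | regs_as_targets
    return RTICollection(
        {r: tuple(t) for r, t in grouped.items()},
        frozenset(universe),
        (provenance,),
        "predefined",
    )


def assign_sites_to_genes(
    sites: dict[str, list[GenomicRegion]],
    genes: list[GeneModel],
    scheme: IntervalScheme,
    orient_by_strand: bool = True,
    mode: str = "overlap",
) -> RTICollection:
    """Assign each regulator's binding sites to genes by TSS proximity.

    A site is assigned to a gene when it overlaps the gene's acceptance
    window by at least 1 bp (``mode="overlap"``) or when the site midpoint
    falls inside the window (``mode="midpoint"``). With
    ``orient_by_strand=False`` asymmetric schemes are applied in fixed genome
    orientation instead of gene orientation. Duplicate assignments collapse
    to a single edge; the universe is every gene in ``genes``.
    """
    if not genes:
        raise InputError("assign_sites_to_genes requires a non-empty gene list")
    if mode not in ("overlap", "midpoint"):
        raise InputError(f"unknown assignment mode {mode!r}")

    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        strand = gene.strand if orient_by_strand else "+"
        lo, hi = scheme.window(gene.tss, strand)
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene.gene_id)

    edges: dict[str, tuple[str, ...]] = {}
    for reg, regions in sites.items():
        hit: list[str] = []
        seen: set[str] = set()
        for r in regions:
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            if mode == "overlap":
                found = tree.overlap(r.start, r.end)
            else:
                mid = int(r.midpoint)
                found = tree.overlap(mid, mid + 1)
            for iv in sorted(found, key=lambda iv: iv.data):
                if iv.data not in seen:
                    seen.add(iv.data)
                    hit.append(iv.data)
        if hit:
            edges[reg] = tuple(hit)

    return RTICollection(
        edges,
        frozenset(g.gene_id for g in genes),
        (f"sites@{scheme.label or (scheme.upstream_bp, scheme.downstream_bp)}",),
        scheme,
    )


def merge_collections(collections: list[RTICollection]) -> RTICollection:
    """Union of edges and universes; provenance concatenated."""
    if not collections:
        raise InputError("merge_collections requires at least one collection")
    edges: dict[str, list[str]] = {}
    universe: set[str] = set()
    provenance: list[str] = []
    for coll in collections:
        universe |= coll.universe
        provenance.extend(coll.provenance)
        for reg, targets in coll.edges.items():
            bucket = edges.setdefault(reg, [])
            for t in targets:
                if t not in bucket:
                    bucket.append(t)
    scheme = collections[0].scheme if len(collections) == 1 else "merged"
    return RTICollection(
        {r: tuple(t) for r, t in edges.items()},
        frozenset(universe),
        tuple(provenance),
        scheme,
    )


def restrict_to_universe(c: RTICollection, universe: set[str]) -> RTICollection:
    """Intersect target sets with ``universe``; drop emptied regulators."""
    if not universe:
        raise InputError("restriction universe is empty")
    edges: dict[str, tuple[str, ...]] = {}
    for reg, targets in c.edges.items():
        kept = tuple(t for t in targets if t in universe)
        if kept:
            edges[reg] = kept
    if not edges:
        raise InputError(
            "no regulator retains targets after restriction; the RTI collection "
            "and the analysis background use disjoint gene identifiers"
        )
    return RTICollection(edges, frozenset(universe), c.provenance, c.scheme)
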