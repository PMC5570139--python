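"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use straight loops, exact rational arithmetic
or explicit interval arithmetic — never the code paths they are checking.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from regtrail import GeneModel, GenomicRegion, IntervalScheme, PSEM

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# exact-test oracles (full outcome enumeration, exact rationals)
# ---------------------------------------------------------------------------

def enumerate_overlap_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by enumerating every size-n draw from an N-universe
    whose first K elements are the regulator's targets."""
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if bisect_right(draw, K - 1) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


def binomial_tail_exact(n: int, k: int, p0: Fraction) -> Fraction:
    """P(X >= k), X ~ Binomial(n, p0), summed over outcome classes."""
    if k <= 0:
        return Fraction(1)
    return sum(
        comb(n, j) * p0 ** j * (1 - p0) ** (n - j) for j in range(k, n + 1)
    ) or Fraction(0)


# ---------------------------------------------------------------------------
# TRAP oracle (per-position loops on plain strings)
# ---------------------------------------------------------------------------

def trap_oracle(seq: str, psem: PSEM) -> float:
    seq = seq.upper()
    rc = "".join(_COMP.get(c, "N") for c in reversed(seq))
    m = psem.m
    total = 0.0
    for strand_seq in (seq, rc):
        for i in range(len(strand_seq) - m + 1):
            window = strand_seq[i:i + m]
            if any(c not in "ACGT" for c in window):
                continue
            energy = sum(
                psem.energies["ACGT".index(c), j] for j, c in enumerate(window)
            )
            x = psem.R0 * np.exp(-energy)
            total += x / (1.0 + x)
    return total


# ---------------------------------------------------------------------------
# interval-assignment oracle (explicit arithmetic per pair)
# ---------------------------------------------------------------------------

def assignment_oracle(
    sites: dict[str, list[GenomicRegion]],
    genes: list[GeneModel],
    scheme: IntervalScheme,
    orient_by_strand: bool = True,
) -> set[tuple[str, str]]:
    edges = set()
    for reg, regions in sites.items():
        for region in regions:
            for gene in genes:
                if gene.chrom != region.chrom:
                    continue
                strand = gene.strand if orient_by_strand else "+"
                if strand == "+":
                    lo = gene.tss - scheme.upstream_bp
                    hi = gene.tss + scheme.downstream_bp
                else:
                    lo = gene.tss - scheme.downstream_bp
                    hi = gene.tss + scheme.upstream_bp
                # closed position interval [lo, hi]; site half-open
                if region.start <= hi and region.end - 1 >= lo:
                    edges.add((reg, gene.gene_id))
    return edges


# ---------------------------------------------------------------------------
# common fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_universe_rti():
    """10-gene universe; one regulator with 5 targets, 4 of which form the
    hit list — the worked hypergeometric example."""
    from regtrail import from_edge_list

    genes = [f"G{i}" for i in range(1, 11)]
    targets = genes[:5]
    edges = [("R1", t) for t in targets] + [("R2", g) for g in genes[5:8]]
    return from_edge_list(edges, universe=set(genes)), genes, targets
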