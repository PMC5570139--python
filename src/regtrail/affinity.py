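"""Biophysical TF affinity scoring of candidate regions (TRAP) and
decay-weighted aggregation into a gene x TF score matrix.

A position count matrix (PCM) is converted to a position-specific energy
matrix (PSEM) using the Berg–von Hippel mismatch-energy formulation: with
pseudocounted counts c, the energy of base b at motif position i is

    E(b, i) = (1/lambda) * ln(c_max,i / c_b,i)

so the per-position consensus base has energy 0. The TRAP occupancy of one
m-mer site with total mismatch energy E is R0 * e^-E / (1 + R0 * e^-E) with
the length-dependent prefactor ln R0 = 0.584 * m - 5.66; a sequence's
affinity is the sum of occupancies over every start offset on both strands.

Gene-level scores aggregate the affinities of all candidate regions within a
window centered on the gene's most-5' TSS, each weighted by exp(-d / d0)
where d is the distance between region midpoint and TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError
from .io import GeneModel, GenomicRegion, PCMRecord, extract_sequence

TRAP_LAMBDA = 0.7
TRAP_LNR0_SLOPE = 0.584
TRAP_LNR0_INTERCEPT = -5.66
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_WINDOW_BP = 50_000
DEFAULT_DECAY_BP = 5_000
DEFAULT_MIN_IC_PER_COLUMN = 0.25

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PSEM:
    """Position-specific energy matrix with TRAP scaling constants."""

    tf_name: str
    energies: np.ndarray  # 4 x m, consensus base 0 per column
    lam: float
    R0: float

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 2 or e.shape[0] != 4:
            raise InputError("PSEM energies must be 4 x m")
        if (e < 0).any():
            raise InputError("PSEM energies must be non-negative")
        if not np.allclose(e.min(axis=0), 0.0):
            raise InputError("each PSEM column must contain a zero (consensus) energy")
        if self.lam <= 0 or self.R0 <= 0:
            raise InputError("PSEM lambda and R0 must be positive")
        object.__setattr__(self, "energies", e)

    @property
    def m(self) -> int:
        return self.energies.shape[1]


@dataclass
class GeneTFScoreMatrix:
    """Genes x TFs non-negative decay-weighted affinity scores."""

    scores: pd.DataFrame  # index gene_ids, columns tf_names
    window_bp: int
    decay_bp: float

    def __post_init__(self):
        if (self.scores.to_numpy(float) < 0).any():
            raise InputError("gene-TF scores must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def tf_names(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, window_bp: int = DEFAULT_WINDOW_BP,
                 decay_bp: float = DEFAULT_DECAY_BP) -> "GeneTFScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, window_bp, decay_bp)


# ---------------------------------------------------------------------------
# PCM quality filtering
# ---------------------------------------------------------------------------

def pcm_information_content(pcm: PCMRecord) -> float:
    """Total information content in bits against a uniform background.

    IC = sum over positions and bases of f * log2(f / 0.25), with
    frequencies taken from the raw counts (no pseudocount) and 0*log(0) = 0.
    """
    f = pcm.counts / pcm.counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / 0.25), 0.0)
    return float(terms.sum())


def filter_pcms(
    pcms: Sequence[PCMRecord],
    min_ic_per_column: float = DEFAULT_MIN_IC_PER_COLUMN,
) -> list[PCMRecord]:
    """Drop low-information PCMs and collapse primaries per TF.

    A PCM is removed when its information content per column falls below
    ``min_ic_per_column`` bits. Among a TF's primary motifs only the most
    informative survives (ties: shorter motif, then lexicographic motif ID);
    secondary binding motifs that pass the filter are kept alongside.
    """
    passing = [p for p in pcms if pcm_information_content(p) / p.length >= min_ic_per_column]
    if not passing:
        raise InputError(
            f"no PCM passes the information filter ({min_ic_per_column} bits/column)"
        )
    best_primary: dict[str, PCMRecord] = {}
    for p in passing:
        if p.is_secondary:
            continue
        cur = best_primary.get(p.tf_name)
        if cur is None:
            best_primary[p.tf_name] = p
            continue
        key_new = (-pcm_information_content(p), p.length, p.motif_id)
        key_cur = (-pcm_information_content(cur), cur.length, cur.motif_id)
        if key_new < key_cur:
            best_primary[p.tf_name] = p
    kept_ids = {id(p) for p in best_primary.values()}
    return [p for p in passing if p.is_secondary or id(p) in kept_ids]


# ---------------------------------------------------------------------------
# PSEM conversion and TRAP scoring
# ---------------------------------------------------------------------------

def pcm_to_psem(
    pcm: PCMRecord,
    lam: float = TRAP_LAMBDA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PSEM:
    """Berg–von Hippel mismatch energies from a position count matrix."""
    if lam <= 0:
        raise InputError("lambda must be positive")
    if pseudocount < 0:
        raise InputError("pseudocount must be non-negative")
    c = pcm.counts + pseudocount
    if (c <= 0).any():
        raise InputError(
            f"PCM {pcm.motif_id} has zero counts; a positive pseudocount is required"
        )
    energies = np.log(c.max(axis=0, keepdims=True) / c) / lam
    R0 = float(np.exp(TRAP_LNR0_SLOPE * pcm.length + TRAP_LNR0_INTERCEPT))
    return PSEM(pcm.tf_name, energies, lam, R0)


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return out


def _strand_occupancy_sum(codes: np.ndarray, energies: np.ndarray, R0: float) -> float:
    m = energies.shape[1]
    if codes.size < m:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return 0.0
    w = windows[valid]
    e_site = energies[w, np.arange(m)[None, :]].sum(axis=1)
    x = R0 * np.exp(-e_site)
    return float((x / (1.0 + x)).sum())


def trap_affinity(seq: str, psem: PSEM) -> float:
    """TRAP affinity of a sequence: occupancies summed over all offsets and
    both strands. Windows containing a non-ACGT character contribute 0;
    sequences shorter than the motif score 0."""
    seq = seq.upper()
    codes = _encode(seq)
    fwd = _strand_occupancy_sum(codes, psem.energies, psem.R0)
    # reverse strand: score the reverse complement with the same matrix
    rc = np.where(codes >= 0, 3 - codes, -1)[::-1]
    rev = _strand_occupancy_sum(rc, psem.energies, psem.R0)
    return fwd + rev


# ---------------------------------------------------------------------------
# peak-to-gene aggregation
# ---------------------------------------------------------------------------

def candidate_regions_for_gene(
    gene: GeneModel,
    regions: Sequence[GenomicRegion],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[tuple[GenomicRegion, float]]:
    """Regions overlapping the window centered on the gene's most-5' TSS.

    The window is ``[tss - window_bp/2, tss + window_bp/2)``; a 1-bp overlap
    suffices. Returned distances are |region midpoint - TSS|.
    """
    if window_bp <= 0:
        raise InputError("window_bp must be positive")
    half = window_bp / 2.0
    lo, hi = gene.tss - half, gene.tss + half
    out = []
    for r in regions:
        if r.chrom != gene.chrom:
            continue
        if r.start < hi and r.end > lo:
            out.append((r, abs(r.midpoint - gene.tss)))
    return out


def gene_tf_scores(
    regions: Sequence[GenomicRegion],
    genes: Sequence[GeneModel],
    psems: Sequence[PSEM],
    genome: Mapping[str, object],
    window_bp: int = DEFAULT_WINDOW_BP,
    decay_bp: float = DEFAULT_DECAY_BP,
) -> GeneTFScoreMatrix:
    """Aggregate region affinities into a gene x TF matrix.

    score(g, t) = sum over candidate regions r of
    trap_affinity(seq(r), psem_t) * exp(-distance(r, g) / decay_bp). Genes
    without candidate regions receive all-zero rows. BED score columns are
    ignored: regions are weighted by distance only.
    """
    if decay_bp <= 0:
        raise InputError("decay_bp must be positive")
    available = set(map(str, genome.keys())) if hasattr(genome, "keys") else set()
    bad = sorted({r.chrom for r in regions} - available)
    if bad:
        raise InputError(f"region chromosomes absent from genome: {bad}")

    # affinity of every region for every TF, computed once
    affinities = np.zeros((len(regions), len(psems)))
    for i, region in enumerate(regions):
        seq = extract_sequence(genome, region)
        for j, psem in enumerate(psems):
            affinities[i, j] = trap_affinity(seq, psem)

    index_of = {id(r): i for i, r in enumerate(regions)}
    scores = np.zeros((len(genes), len(psems)))
    for gi, gene in enumerate(genes):
        for region, dist in candidate_regions_for_gene(gene, regions, window_bp):
            weight = np.exp(-dist / decay_bp)
            scores[gi] += weight * affinities[index_of[id(region)]]

    df = pd.DataFrame(
        scores,
        index=[g.gene_id for g in genes],
        columns=[p.tf_name for p in psems],
    )
    if df.columns.duplicated().any():
        # secondary motifs share the TF name; disambiguate
        df.columns = [
            f"{name}.{i}" if dup else name
            for i, (name, dup) in enumerate(zip(df.columns, df.columns.duplicated()))
        ]
    return GeneTFScoreMatrix(df, window_bp, float(decay_bp))
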