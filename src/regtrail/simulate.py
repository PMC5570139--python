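"""Seeded synthetic fixtures with planted ground truth.

Every generator is a pure function of a :class:`FixtureSpec`: the seed fully
determines the output, so written files are byte-identical across reruns.
The fixtures emulate the four analysis scenarios at desk scale — a regulator
-> target edge collection, two-group log-scale expression with planted
differential targets and a correlation-flip regulator, a toy genome with
planted motif occurrences near gene TSSs, and a gene-TF score matrix with a
planted linear expression model. None of this models read-level noise,
chromatin state or real genome composition; it exists to make planted-truth
recovery testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InputError
from .affinity import GeneTFScoreMatrix
from .expression import GroupDesign
from .io import (
    ExpressionMatrix, GeneModel, GenomicRegion, PCMRecord,
    write_bed, write_fasta, write_pcm_jaspar,
)
from .rti import RTICollection, from_edge_list


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults are chosen as a small but realistic regulatory-genomics toy
    problem: tens of genes, ~10 regulators with 5–15 targets each, 10
    samples per group with a 2.0 log2-unit planted effect over 0.5-sd noise,
    8-bp motifs planted in accessible regions near TSSs.
    """

    seed: int = 0
    n_genes: int = 60
    n_regulators: int = 10
    n_samples_per_group: int = 20
    target_set_size: tuple[int, int] = (5, 15)
    # expression simulation
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    de_effect_size: float = 2.0
    n_de_regulators: int = 1
    flip_regulator_coupling: float = 1.0
    # genome simulation
    genome_length_bp: int = 600_000
    n_regions: int = 40
    region_length_bp: int = 200
    motif_length: int = 8
    n_planted_occurrences: int = 5
    # INVOKE simulation
    n_tfs: int = 40
    n_planted_tfs: int = 6
    coefficient_range: tuple[float, float] = (0.5, 2.0)
    feature_correlation: float = 0.2
    invoke_noise_ratio: float = 0.5

    def __post_init__(self):
        if self.n_regulators > self.n_genes:
            raise InputError("cannot have more regulators than genes")
        if min(self.n_genes, self.n_regulators, self.n_samples_per_group) < 1:
            raise InputError("all counts must be >= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _regulator_ids(n: int) -> list[str]:
    return [f"R{i:02d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# scenario 1: RTI collection with known structure
# ---------------------------------------------------------------------------

def simulate_rti(spec: FixtureSpec) -> tuple[RTICollection, dict]:
    """Random regulator -> target sets over the gene universe.

    The truth table records every membership; regulators are distinct IDs
    (not genes), matching the predefined-RTI upload path.
    """
    rng = spec.rng(1)
    genes = _gene_ids(spec.n_genes)
    lo, hi = spec.target_set_size
    hi = min(hi, spec.n_genes)
    edges: list[tuple[str, str]] = []
    truth: dict[str, list[str]] = {}
    for reg in _regulator_ids(spec.n_regulators):
        size = int(rng.integers(lo, hi + 1))
        targets = sorted(rng.choice(genes, size=size, replace=False).tolist())
        truth[reg] = targets
        edges.extend((reg, t) for t in targets)
    collection = from_edge_list(edges, universe=set(genes), provenance="simulated")
    return collection, {"targets": truth, "universe": genes}


# ---------------------------------------------------------------------------
# scenario 2: two-group expression with planted structure
# ---------------------------------------------------------------------------

def simulate_expression(
    spec: FixtureSpec, rti: RTICollection | None = None
) -> tuple[ExpressionMatrix, GroupDesign, dict]:
    """Two-group log-scale expression with planted DE and RIF structure.

    The targets of the first ``n_de_regulators`` regulators are shifted by
    ``de_effect_size`` in the case group. One further regulator (the
    "correlation-flip" regulator, last in the panel) is itself measured: in
    the case group its targets track its expression with coupling
    ``flip_regulator_coupling``; in the control group they are independent.
    Expression is simulated directly on the log2 scale, so the fold-change
    score is a plain mean difference and planted effects stay interpretable.
    """
    if rti is None:
        rti, _ = simulate_rti(spec)
    rng = spec.rng(2)
    genes = _gene_ids(spec.n_genes)
    regs = _regulator_ids(spec.n_regulators)
    all_rows = genes + regs
    n = spec.n_samples_per_group
    case_ids = [f"case_{i + 1}" for i in range(n)]
    control_ids = [f"ctrl_{i + 1}" for i in range(n)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(all_rows))
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(all_rows), 2 * n))

    row = {g: i for i, g in enumerate(all_rows)}
    de_regulators = regs[: spec.n_de_regulators]
    flip_reg = regs[-1]
    flip_targets = sorted(rti.targets(flip_reg))
    # the correlation-flip regulator's targets are themselves differentially
    # expressed, so the impact-weighted RIF terms carry signal
    de_genes = sorted(
        {t for r in de_regulators for t in rti.targets(r)} | set(flip_targets)
    )
    for g in de_genes:
        values[row[g], :n] += spec.de_effect_size

    reg_case = values[row[flip_reg], :n]
    centered = reg_case - reg_case.mean()
    # couple at twice the noise sd so within-case correlations are strong
    driver = centered / centered.std() * (2.0 * spec.noise_sd)
    for t in flip_targets:
        values[row[t], :n] += spec.flip_regulator_coupling * driver

    df = pd.DataFrame(values, index=all_rows, columns=case_ids + control_ids)
    groups = {s: "case" for s in case_ids}
    groups.update({s: "control" for s in control_ids})
    expr = ExpressionMatrix(df, groups)
    design = GroupDesign(tuple(case_ids), tuple(control_ids))
    truth = {
        "de_regulators": de_regulators,
        "de_genes": de_genes,
        "flip_regulator": flip_reg,
        "flip_targets": flip_targets,
        "effect_size": spec.de_effect_size,
    }
    return expr, design, truth


# ---------------------------------------------------------------------------
# scenario 3: toy genome with planted motif occurrences
# ---------------------------------------------------------------------------

def _random_pcm(rng: np.random.Generator, tf_name: str, motif_id: str,
                length: int, total: int = 100) -> PCMRecord:
    """Informative random PCM: ~91% consensus base per position."""
    consensus = rng.integers(0, 4, size=length)
    counts = np.full((4, length), 3.0)
    counts[consensus, np.arange(length)] = total - 9
    return PCMRecord(tf_name, motif_id, counts)


def _consensus(pcm: PCMRecord) -> str:
    return "".join("ACGT"[i] for i in pcm.counts.argmax(axis=0))


def simulate_genome_with_motifs(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> dict:
    """Toy genome + annotation + candidate regions + motif set, with truth.

    A uniform-composition chromosome carries ``n_genes`` evenly spaced genes
    of random strand. Candidate regions are placed at seeded distances from
    gene TSSs (within a 50 kb window). The consensus of the planted TF's
    motif is embedded ``n_planted_occurrences`` times in every region near
    the planted gene; a decoy TF motif is never planted. When ``out_dir`` is
    given, FASTA/GTF/BED/JASPAR files plus ``truth.json`` are written.
    """
    if spec.genome_length_bp < 10 * spec.n_genes * 1000:
        raise InputError(
            "genome too short: need >= 10 kb x 1000 x n_genes "
            f"({10 * spec.n_genes * 1000} bp), got {spec.genome_length_bp}"
        )
    rng = spec.rng(3)
    chrom = "chr1"
    seq = rng.choice(list("ACGT"), size=spec.genome_length_bp)

    spacing = spec.genome_length_bp // (spec.n_genes + 1)
    genes: list[GeneModel] = []
    for i in range(spec.n_genes):
        tss = spacing * (i + 1) + int(rng.integers(-spacing // 4, spacing // 4))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i + 1:04d}", chrom, strand, (tss,)))

    pcm_planted = _random_pcm(rng, "TF_PLANTED", "SIM0001", spec.motif_length)
    pcm_decoy = _random_pcm(rng, "TF_DECOY", "SIM0002", spec.motif_length)
    planted_gene = genes[int(rng.integers(0, spec.n_genes))]

    regions: list[GenomicRegion] = []
    planted_region_idx: list[int] = []
    L = spec.region_length_bp
    for i in range(spec.n_regions):
        gene = genes[int(rng.integers(0, spec.n_genes))]
        offset = int(rng.integers(-20_000, 20_000))
        start = max(0, min(gene.tss + offset - L // 2, spec.genome_length_bp - L))
        region = GenomicRegion(chrom, start, start + L, f"peak{i + 1}")
        regions.append(region)
        near_planted = abs(region.midpoint - planted_gene.tss) <= 25_000
        if near_planted:
            cons = list(_consensus(pcm_planted))
            for _ in range(spec.n_planted_occurrences):
                pos = int(rng.integers(start, start + L - spec.motif_length))
                seq[pos:pos + spec.motif_length] = cons
            planted_region_idx.append(i)
    if not planted_region_idx:
        # guarantee recoverable signal: add one region right at the TSS
        start = max(0, min(planted_gene.tss - L // 2, spec.genome_length_bp - L))
        region = GenomicRegion(chrom, start, start + L, "peak_planted")
        regions.append(region)
        cons = list(_consensus(pcm_planted))
        for _ in range(spec.n_planted_occurrences):
            pos = int(rng.integers(start, start + L - spec.motif_length))
            seq[pos:pos + spec.motif_length] = cons
        planted_region_idx.append(len(regions) - 1)

    genome = {chrom: "".join(seq)}
    truth = {
        "planted_tf": "TF_PLANTED",
        "decoy_tf": "TF_DECOY",
        "planted_gene": planted_gene.gene_id,
        "planted_regions": [regions[i].name for i in planted_region_idx],
        "consensus": _consensus(pcm_planted),
    }
    result = {
        "genome": genome,
        "genes": genes,
        "regions": regions,
        "pcms": [pcm_planted, pcm_decoy],
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_bed(regions, out / "regions.bed")
        write_pcm_jaspar(result["pcms"], out / "motifs.jaspar")
        with open(out / "genes.gtf", "w") as fh:
            for g in genes:
                # single-transcript genes; GTF is 1-based inclusive
                start1 = g.tss + 1 if g.strand == "+" else g.tss + 1 - 999
                end1 = g.tss + 1 + 999 if g.strand == "+" else g.tss + 1
                start1 = max(1, start1)
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write("\t".join([
                    g.chrom, "sim", "transcript", str(start1), str(end1),
                    ".", g.strand, ".", attrs,
                ]) + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return result


# ---------------------------------------------------------------------------
# scenario 4: gene-TF scores with a planted linear model
# ---------------------------------------------------------------------------

def simulate_invoke_dataset(
    spec: FixtureSpec, n_genes: int | None = None
) -> tuple[GeneTFScoreMatrix, pd.Series, dict]:
    """Non-negative gene-TF scores plus an expression response that is
    linear in the standardized log-scores.

    Feature columns share pairwise correlation ``feature_correlation``.
    ``n_planted_tfs`` coefficients are drawn from +/-[coefficient_range];
    noise is Gaussian with sd = ``invoke_noise_ratio`` x sd(signal). The
    response is emitted on the raw scale as ``2^(signal + noise + 8) - 1``
    so that the modeling pipeline's own log2(x+1) transform and centering
    recover exactly the planted linear model.
    """
    if spec.n_planted_tfs > spec.n_tfs:
        raise InputError("more planted TFs than TFs")
    rng = spec.rng(4)
    n = n_genes if n_genes is not None else spec.n_genes
    genes = _gene_ids(n)
    tfs = [f"TF{i:03d}" for i in range(1, spec.n_tfs + 1)]

    rho = spec.feature_correlation
    shared = rng.normal(size=(n, 1))
    V = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=(n, spec.n_tfs))
    X = np.exp2(V + 4.0)  # non-negative, lognormal-like affinity scale

    F = np.log2(X + 1.0)
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=0)

    planted_idx = np.sort(rng.choice(spec.n_tfs, size=spec.n_planted_tfs, replace=False))
    lo, hi = spec.coefficient_range
    beta = np.zeros(spec.n_tfs)
    beta[planted_idx] = rng.uniform(lo, hi, size=spec.n_planted_tfs) * rng.choice(
        [-1.0, 1.0], size=spec.n_planted_tfs
    )
    signal = F @ beta
    noise_sd = spec.invoke_noise_ratio * signal.std()
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    z = signal + noise
    # keep the raw-scale response non-negative; the constant offset is
    # absorbed when the modeling pipeline centers the response
    offset = max(8.0, 0.5 - float(z.min()))
    y = np.exp2(z + offset) - 1.0

    scores = GeneTFScoreMatrix(pd.DataFrame(X, index=genes, columns=tfs), 50_000, 5000.0)
    response = pd.Series(y, index=genes, name="expression")
    truth = {
        "planted_tfs": [tfs[i] for i in planted_idx],
        "beta": {tfs[i]: float(beta[i]) for i in planted_idx},
        "noise_sd": float(noise_sd),
    }
    return scores, response, truth
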