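"""Readers and writers for the standard formats the toolkit touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open ``[start, end)``, matching
BED. GTF input (1-based, closed) is converted at the parsing boundary: a GTF
position ``p`` becomes ``p - 1`` internally. Transcription start sites are
stored as single 0-based base positions.

Genome sequences are accessed through any mapping from chromosome name to a
sliceable sequence; both a plain ``dict`` of strings and a
:class:`pyfaidx.Fasta` satisfy the protocol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError, ParseError

_ALPHABET = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """Strand-aware interval on a named sequence (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise InputError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise InputError(
                f"region end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcript start positions and derived most-5' TSS.

    ``tss_candidates`` holds the 0-based 5' end of every transcript. The
    most-5' TSS is the minimum on the ``+`` strand and the maximum on the
    ``-`` strand (farthest upstream in gene orientation).
    """

    gene_id: str
    chrom: str
    strand: str
    tss_candidates: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.tss_candidates:
            raise InputError(f"gene {self.gene_id}: no transcript start positions")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return min(self.tss_candidates)
        return max(self.tss_candidates)


class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    Thin wrapper around a pandas DataFrame (index = gene IDs, columns =
    sample IDs) that enforces uniqueness and finiteness, plus an optional
    sample -> group assignment ("case" / "control").
    """

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str] | None = None):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene IDs: {dupes[:5]}")
        if values.columns.duplicated().any():
            raise InputError("duplicate sample IDs in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError("expression matrix contains non-finite values")
        self.values = values.astype(float)
        if groups is not None:
            unknown = set(groups) - set(values.columns)
            if unknown:
                raise InputError(f"group samples not in matrix: {sorted(unknown)}")
            labels = set(groups.values())
            if not labels <= {"case", "control"}:
                raise InputError(f"group labels must be case/control, got {labels}")
            for lab in ("case", "control"):
                if lab not in labels:
                    raise InputError(f"group {lab!r} is empty")
        self.groups = dict(groups) if groups is not None else None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self):  # pragma: no cover
        g = "grouped" if self.groups else "ungrouped"
        return f"ExpressionMatrix({len(self.gene_ids)} genes x {len(self.sample_ids)} samples, {g})"


@dataclass(frozen=True)
class PCMRecord:
    """Position count matrix: per-position base counts, rows A,C,G,T."""

    tf_name: str
    motif_id: str
    counts: np.ndarray
    is_secondary: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise InputError(
                f"PCM {self.motif_id}: counts must be 4 x m with m >= 1, got {counts.shape}"
            )
        if (counts < 0).any():
            raise InputError(f"PCM {self.motif_id}: negative count")
        if (counts.sum(axis=0) <= 0).any():
            raise InputError(f"PCM {self.motif_id}: zero column sum")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Parse a BED3–BED6 file; columns beyond 6 are ignored.

    ``track``/``browser``/``#`` lines and blank lines are skipped. Malformed
    coordinates raise :class:`ParseError` naming the line number.
    """
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"BED line has {len(fields)} columns, need >= 3",
                    str(path), lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer BED coordinate: {fields[1]!r}/{fields[2]!r}",
                    str(path), lineno,
                ) from None
            if end <= start or start < 0:
                raise ParseError(
                    f"invalid BED interval [{start}, {end})", str(path), lineno
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"non-numeric BED score {fields[4]!r}", str(path), lineno
                    ) from None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            regions.append(GenomicRegion(chrom, start, end, name, score, strand))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None or r.strand != ".":
                fields.append(r.name if r.name is not None else ".")
                fields.append(repr(r.score) if r.score is not None else ".")
                fields.append(r.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF gene annotation
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Build one :class:`GeneModel` per ``gene_id`` from GTF transcript rows.

    Transcript 5' ends define the TSS candidates: the GTF ``start`` field for
    ``+`` transcripts, the ``end`` field for ``-`` transcripts (both converted
    to 0-based). Exon and CDS records are ignored — transcripts define starts.
    A gene whose transcripts disagree on strand or chromosome is an error.
    """
    path = Path(path)
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"GTF line has {len(fields)} columns, need 9", str(path), lineno
                )
            feature = fields[2]
            if feature != "transcript":
                continue
            chrom, strand = fields[0], fields[6]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError("non-integer GTF coordinate", str(path), lineno) from None
            if strand not in ("+", "-"):
                raise ParseError(f"transcript strand {strand!r}", str(path), lineno)
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError("transcript without gene_id attribute", str(path), lineno)
            # GTF is 1-based inclusive: 5' end is start for +, end for -.
            tss0 = start1 - 1 if strand == "+" else end1 - 1
            rec = per_gene.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "tss": []}
            )
            if rec["strand"] != strand:
                raise InputError(
                    f"gene {gene_id} has transcripts on conflicting strands"
                )
            if rec["chrom"] != chrom:
                raise InputError(f"gene {gene_id} spans multiple chromosomes")
            rec["tss"].append(tss0)
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], tuple(sorted(set(rec["tss"]))))
        for gid, rec in per_gene.items()
    ]


# ---------------------------------------------------------------------------
# expression matrices and gene lists
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    case_samples: Sequence[str] | None = None,
    control_samples: Sequence[str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene IDs, header sample IDs).

    Group membership may be given either as two sample-ID lists or as an
    explicit ``sample -> {case, control}`` mapping.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot read expression TSV: {exc}", str(path)) from exc
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ParseError(
            f"non-numeric expression values in column(s) {non_numeric}", str(path)
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if groups is None and case_samples is not None:
        if control_samples is None:
            raise InputError("case_samples given without control_samples")
        groups = {str(s): "case" for s in case_samples}
        groups.update({str(s): "control" for s in control_samples})
        if len(groups) < len(case_samples) + len(control_samples):
            raise InputError("case and control sample lists overlap")
    return ExpressionMatrix(df, groups)


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out: list[str] = []
    seen = set()
    with open(path) as fh:
        for raw in fh:
            gid = raw.strip().split("\t")[0]
            if not gid or gid.startswith("#"):
                continue
            if gid not in seen:
                seen.add(gid)
                out.append(gid)
    return out


# ---------------------------------------------------------------------------
# motif files (JASPAR / TRANSFAC dialects)
# ---------------------------------------------------------------------------

def _finish_jaspar_record(header: str, rows: dict[str, list[float]],
                          secondary_suffix: str, path: str, lineno: int) -> PCMRecord:
    missing = [b for b in _ALPHABET if b not in rows]
    if missing:
        raise ParseError(f"JASPAR record missing rows for {missing}", path, lineno)
    lengths = {len(rows[b]) for b in _ALPHABET}
    if len(lengths) != 1:
        raise ParseError("ragged JASPAR rows", path, lineno)
    parts = header[1:].split()
    motif_id = parts[0] if parts else "motif"
    tf_name = parts[1] if len(parts) > 1 else motif_id
    counts = np.array([rows[b] for b in _ALPHABET], dtype=float)
    is_secondary = tf_name.endswith(secondary_suffix) or motif_id.endswith(secondary_suffix)
    if is_secondary:
        tf_name = tf_name.removesuffix(secondary_suffix)
    return PCMRecord(tf_name, motif_id, counts, is_secondary)


def _read_jaspar(path: Path, secondary_suffix: str) -> list[PCMRecord]:
    records: list[PCMRecord] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(
                        _finish_jaspar_record(header, rows, secondary_suffix, str(path), lineno)
                    )
                header, rows = line, {}
                continue
            if header is None:
                raise ParseError("JASPAR counts before any '>' header", str(path), lineno)
            base = line[0].upper()
            if base not in _ALPHABET:
                raise ParseError(f"unexpected JASPAR row {line[:20]!r}", str(path), lineno)
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                values = [float(x) for x in body.split()]
            except ValueError:
                raise ParseError("non-numeric JASPAR count", str(path), lineno) from None
            if any(v < 0 for v in values):
                raise ParseError("negative JASPAR count", str(path), lineno)
            rows[base] = values
    if header is not None:
        records.append(
            _finish_jaspar_record(header, rows, secondary_suffix, str(path), lineno)
        )
    return records


def _read_transfac(path: Path, secondary_suffix: str) -> list[PCMRecord]:
    records: list[PCMRecord] = []
    motif_id: str | None = None
    tf_name: str | None = None
    order: list[str] | None = None
    position_rows: list[list[float]] = []

    def finish(lineno: int) -> None:
        nonlocal motif_id, tf_name, order, position_rows
        if motif_id is None and not position_rows:
            return
        if not position_rows:
            raise ParseError(f"TRANSFAC block {motif_id} has no positions", str(path), lineno)
        mat = np.array(position_rows, dtype=float).T  # positions x 4 -> 4 x m
        if order != list(_ALPHABET):
            idx = [order.index(b) for b in _ALPHABET]
            mat = mat[idx]
        name = tf_name or motif_id or "motif"
        mid = motif_id or name
        is_secondary = name.endswith(secondary_suffix) or mid.endswith(secondary_suffix)
        records.append(
            PCMRecord(name.removesuffix(secondary_suffix), mid, mat, is_secondary)
        )
        motif_id, tf_name, order, position_rows = None, None, None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tag = line.split(None, 1)[0]
            if tag == "//":
                finish(lineno)
            elif tag == "ID":
                motif_id = line.split(None, 1)[1].strip() if " " in line else None
            elif tag == "NA":
                tf_name = line.split(None, 1)[1].strip()
            elif tag == "P0" or tag == "PO":
                order = [b.upper() for b in line.split()[1:5]]
                if sorted(order) != sorted(_ALPHABET):
                    raise ParseError(f"TRANSFAC P0 row {order}", str(path), lineno)
            elif tag.isdigit():
                if order is None:
                    raise ParseError("TRANSFAC counts before P0 row", str(path), lineno)
                cells = line.split()[1:5]
                if len(cells) < 4:
                    raise ParseError("ragged TRANSFAC row", str(path), lineno)
                try:
                    values = [float(x) for x in cells]
                except ValueError:
                    raise ParseError("non-numeric TRANSFAC count", str(path), lineno) from None
                if any(v < 0 for v in values):
                    raise ParseError("negative TRANSFAC count", str(path), lineno)
                position_rows.append(values)
            # other TRANSFAC tags (XX, BF, CC ...) are ignored
        finish(lineno)
    return records


def read_pcm(path: str | Path, dialect: str = "jaspar",
             secondary_suffix: str = "_secondary") -> list[PCMRecord]:
    """Parse position count matrices from JASPAR or TRANSFAC text.

    Counts are returned 4 x m in A,C,G,T row order regardless of dialect.
    Records whose name or ID ends with ``secondary_suffix`` are flagged as
    secondary binding motifs (the suffix is stripped from the TF name).
    """
    path = Path(path)
    if dialect == "jaspar":
        return _read_jaspar(path, secondary_suffix)
    if dialect == "transfac":
        return _read_transfac(path, secondary_suffix)
    raise InputError(f"unknown PCM dialect {dialect!r} (use 'jaspar' or 'transfac')")


def write_pcm_jaspar(records: Iterable[PCMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name = rec.tf_name + ("_secondary" if rec.is_secondary else "")
            fh.write(f">{rec.motif_id} {name}\n")
            for i, base in enumerate(_ALPHABET):
                row = " ".join(repr(v) if v % 1 else str(int(v)) for v in rec.counts[i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# RTI edge tables
# ---------------------------------------------------------------------------

def read_rti_table(path: str | Path, header: bool | None = None) -> list[tuple[str, str]]:
    """Read (regulator, target) edges from a 2+ column TSV.

    Edges are deduplicated preserving first-occurrence order. A first line
    reading ``regulator<TAB>target`` is treated as a header; pass ``header``
    explicitly to override the guess.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("RTI line needs >= 2 tab-separated columns",
                                 str(path), lineno)
            reg, target = fields[0].strip(), fields[1].strip()
            if lineno == 1:
                is_header = header if header is not None else (
                    reg.lower() == "regulator" and target.lower() == "target"
                )
                if is_header:
                    continue
            if not reg or not target:
                raise ParseError("blank regulator or target field", str(path), lineno)
            if (reg, target) not in seen:
                seen.add((reg, target))
                edges.append((reg, target))
    return edges


# ---------------------------------------------------------------------------
# genome sequence access
# ---------------------------------------------------------------------------

def extract_sequence(genome: Mapping[str, object], region: GenomicRegion) -> str:
    """Forward-strand sequence of ``region``, uppercased.

    ``genome`` may be a ``dict`` of strings, a :class:`pyfaidx.Fasta`, or any
    mapping of chromosome name to a sliceable sequence. The region's strand
    field is ignored; affinity scoring handles both strands itself.
    """
    try:
        seq_obj = genome[region.chrom]
    except KeyError:
        avail = list(genome.keys()) if hasattr(genome, "keys") else []
        raise InputError(
            f"chromosome {region.chrom!r} not in genome (available: {sorted(map(str, avail))[:10]})"
        ) from None
    if region.end > len(seq_obj):
        raise InputError(
            f"region [{region.start}, {region.end}) exceeds {region.chrom} length {len(seq_obj)}"
        )
    return str(seq_obj[region.start:region.end]).upper()


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def _record_to_dict(row) -> dict:
    if dataclasses.is_dataclass(row):
        return dataclasses.asdict(row)
    if isinstance(row, Mapping):
        return dict(row)
    raise InputError(f"cannot serialize record of type {type(row).__name__}")


def write_results(rows: Sequence, path: str | Path, format: str = "csv") -> None:
    """Serialize homogeneous result records to CSV (header row always
    present) or JSON (array of objects). Numeric fields keep at least six
    significant digits; JSON keeps full precision so a round-trip parse
    recovers identical values."""
    dicts = [_record_to_dict(r) for r in rows]
    if dicts:
        keys = list(dicts[0])
        for d in dicts[1:]:
            if list(d) != keys:
                raise InputError("heterogeneous result records")
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(dicts)
        df.to_csv(path, index=False, float_format="%.8g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(dicts, fh, indent=1, default=_json_default)
            fh.write("\n")
    else:
        raise InputError(f"unknown output format {format!r} (use 'csv' or 'json')")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
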