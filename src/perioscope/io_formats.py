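"""Readers and writers for every external format the pipeline touches.

All downstream analysis consumes only the domain types defined here:
:class:`GenomeMap` (circular chromosome + gene coordinates),
:class:`ExpressionProfile` (per-gene log expression for one sample),
and :class:`TrackProfile` (a binned binding-activity track such as GyrA
ChIP signal).

Coordinate convention
---------------------
Internally everything is 1-based inclusive (the GenBank/DDBJ convention),
because bacterial annotations ship as DDBJ flat files.  bedGraph input
(0-based, half-open) is converted at the boundary and the conversion is an
exact bijection on integer intervals.  A gene that wraps the replication
origin of a circular genome is stored as a single record with
``start_bp > end_bp`` rather than split in two, so midpoint arithmetic
stays single-valued.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

ENVIRONMENT_CATEGORIES = frozenset({"regular", "temperature", "osmotic", "nutritional"})
GROWTH_PHASES = frozenset({"exponential", "stress-response"})


class FormatError(ValueError):
    """Input file does not parse in the declared dialect."""


class ConfigurationError(ValueError):
    """Inconsistent or missing configuration (e.g. no genome length)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One gene on the chromosome, 1-based inclusive coordinates.

    ``start_bp > end_bp`` is legal only for a gene wrapping the origin of a
    circular genome.
    """

    gene_id: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start_bp < 1 or self.end_bp < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be >= 1")
        self.tags = frozenset(self.tags)

    @property
    def wraps_origin(self) -> bool:
        return self.start_bp > self.end_bp

    def length_on(self, genome_length: int) -> int:
        """Gene length in bp, accounting for origin wrap."""
        return (self.end_bp - self.start_bp) % genome_length + 1


@dataclass
class GenomeMap:
    """A (usually circular) bacterial genome with its gene coordinates."""

    genome_id: str
    length_bp: int
    circular: bool = True
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if max(g.start_bp, g.end_bp) > self.length_bp:
                raise ValueError(
                    f"{g.gene_id}: coordinate exceeds genome length {self.length_bp}"
                )
            if g.wraps_origin and not self.circular:
                raise ValueError(f"{g.gene_id}: wrapping gene on a linear genome")
        self._by_id = {g.gene_id: g for g in self.genes}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id


@dataclass
class SampleMeta:
    """Sample-level metadata travelling with an expression profile."""

    strain: str | None = None
    condition: str | None = None
    environment: str | None = None
    growth_phase: str | None = None
    growth_rate: float | None = None
    replicate_group: str | None = None

    def __post_init__(self):
        if self.environment is not None and self.environment not in ENVIRONMENT_CATEGORIES:
            raise ValueError(
                f"environment {self.environment!r} not in {sorted(ENVIRONMENT_CATEGORIES)}"
            )
        if self.growth_phase is not None and self.growth_phase not in GROWTH_PHASES:
            raise ValueError(
                f"growth_phase {self.growth_phase!r} not in {sorted(GROWTH_PHASES)}"
            )


@dataclass
class ExpressionProfile:
    """Log-scale expression values for one sample, keyed by gene id."""

    sample_id: str
    genome_id: str
    values: dict
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self):
        bad = [g for g, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite expression for genes {bad[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def restrict_to(self, genome_map: GenomeMap) -> tuple["ExpressionProfile", int]:
        """Drop genes absent from the genome map; return (profile, n_dropped).

        Unmatched ids are reported and dropped, never silently kept.
        """
        kept = {g: v for g, v in self.values.items() if g in genome_map}
        n_dropped = len(self.values) - len(kept)
        if n_dropped:
            logger.warning(
                "%s: dropped %d gene ids absent from genome %s",
                self.sample_id, n_dropped, genome_map.genome_id,
            )
        return ExpressionProfile(self.sample_id, self.genome_id, kept, self.meta), n_dropped


@dataclass
class TrackProfile:
    """A genome-wide numeric track (e.g. GyrA binding) as 1-based intervals."""

    genome_id: str
    intervals: list  # (start_bp, end_bp, value), 1-based inclusive
    label: str = "track"
    source_dialect: str = "tsv"

    def __post_init__(self):
        for s, e, v in self.intervals:
            if not math.isfinite(v):
                raise ValueError(f"non-finite track value in interval ({s}, {e})")
        ivs = sorted((int(s), int(e)) for s, e, _ in self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping intervals ({s1},{e1}) and ({s2},{e2})")


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------


def read_genome_annotation(
    path: str | Path,
    format: str = "genbank",
    length_bp: int | None = None,
    circular: bool = True,
) -> GenomeMap:
    """Read gene coordinates from a GenBank/DDBJ flat file, GFF3 or TSV.

    GenBank records carry their own sequence length; GFF3 needs a
    ``##sequence-region`` directive or an explicit ``length_bp``; TSV always
    needs ``length_bp``.  Coordinates are preserved 1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path, circular)
    if format == "gff3":
        return _read_gff3(path, length_bp, circular)
    if format == "tsv":
        if length_bp is None:
            raise ConfigurationError("TSV annotation requires an explicit length_bp")
        return _read_annotation_tsv(path, length_bp, circular)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_genbank(path: Path, circular: bool) -> GenomeMap:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: unparseable GenBank file: {exc}") from exc
    length = len(record.seq)
    topology = record.annotations.get("topology", "")
    is_circular = circular if topology == "" else (topology == "circular")
    genes = []
    seen = set()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        gid = (quals.get("locus_tag") or quals.get("gene") or quals.get("protein_id") or [None])[0]
        if gid is None or gid in seen:
            continue
        seen.add(gid)
        parts = feat.location.parts
        if len(parts) > 1 and int(parts[0].end) == length and int(parts[-1].start) == 0:
            # join across the origin of a circular genome: one wrapping record
            start, end = int(parts[0].start) + 1, int(parts[-1].end)
        else:
            start, end = int(feat.location.start) + 1, int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        genes.append(GeneRecord(gid, start, end, strand))
    return GenomeMap(record.id or path.stem, length, is_circular, genes)


def _read_gff3(path: Path, length_bp: int | None, circular: bool) -> GenomeMap:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", force=True,
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: unparseable GFF3: {exc}") from exc
    genome_id = path.stem
    if length_bp is None:
        for line in db.directives:
            if line.startswith("sequence-region"):
                fields = line.split()
                genome_id = fields[1]
                length_bp = int(fields[3])
                break
    if length_bp is None:
        raise ConfigurationError(
            f"{path}: no ##sequence-region directive and no length_bp given"
        )
    genes = []
    seen = set()
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            gid = feat.attributes.get("ID", [feat.id])[0]
            if gid in seen:
                continue
            seen.add(gid)
            genes.append(GeneRecord(gid, feat.start, feat.end, feat.strand or "+"))
        if genes:
            break
    return GenomeMap(genome_id, length_bp, circular, genes)


def _read_annotation_tsv(path: Path, length_bp: int, circular: bool) -> GenomeMap:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except Exception as exc:
        raise FormatError(f"{path}: unparseable TSV: {exc}") from exc
    required = {"gene_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSV must have columns {sorted(required)}")
    genes = [
        GeneRecord(row.gene_id, int(row.start), int(row.end), row.strand)
        for row in df.itertuples()
    ]
    return GenomeMap(path.stem, length_bp, circular, genes)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, meta_path: str | Path | None = None, genome_id: str = "genome"
) -> list[ExpressionProfile]:
    """Read a gene × sample TSV of log expression plus a metadata sidecar.

    The sidecar (YAML or JSON) is keyed by sample column name; samples
    lacking metadata get an empty :class:`SampleMeta` with a logged warning.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: need a gene_id column plus >= 1 sample column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene_id rows: {sorted(set(dup))[:5]}")
    meta_by_sample: dict = {}
    if meta_path is not None:
        meta_by_sample = _read_sidecar(Path(meta_path))
    profiles = []
    sample_cols = [c for c in df.columns if c != "gene_id"]
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = int(bad[0])
            raise FormatError(
                f"{path}: non-numeric or blank cell at row {row + 2} "
                f"(gene {df['gene_id'].iloc[row]!r}), column {col!r}"
            )
        if col in meta_by_sample:
            known = {f.name for f in dataclass_fields(SampleMeta)}
            meta = SampleMeta(**{k: v for k, v in meta_by_sample[col].items()
                                 if k in known})
        else:
            if meta_path is not None:
                logger.warning("sample %s has no sidecar metadata", col)
            meta = SampleMeta()
        profiles.append(
            ExpressionProfile(col, genome_id, dict(zip(df["gene_id"], vals.astype(float))), meta)
        )
    return profiles


def _read_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text) or {}


# ---------------------------------------------------------------------------
# tracks and sequences
# ---------------------------------------------------------------------------


def read_track(
    path: str | Path, label: str = "track", genome_id: str = "genome",
    merge: str | None = None,
) -> TrackProfile:
    """Read a bedGraph (0-based half-open) or 3-column TSV (1-based) track.

    bedGraph intervals are converted to 1-based inclusive: ``(s, e)`` ->
    ``(s + 1, e)``.  Overlapping intervals are an error unless
    ``merge='mean'`` is requested.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    if not lines:
        logger.warning("%s: empty track file", path)
        return TrackProfile(genome_id, [], label, "empty")
    n_fields = len(lines[0].split())
    dialect = "bedgraph" if n_fields == 4 else "tsv"
    intervals = []
    for i, ln in enumerate(lines, 1):
        f = ln.split()
        try:
            if dialect == "bedgraph":
                start, end, value = int(f[1]) + 1, int(f[2]), float(f[3])
            else:
                start, end, value = int(f[0]), int(f[1]), float(f[2])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad track line {i}: {ln!r}") from exc
        intervals.append((start, end, value))
    intervals.sort()
    if merge == "mean":
        intervals = _merge_overlaps_mean(intervals)
    return TrackProfile(genome_id, intervals, label, dialect)


def _merge_overlaps_mean(intervals):
    merged: list = []
    for s, e, v in intervals:
        if merged and s <= merged[-1][1]:
            ps, pe, pv, pn = merged[-1]
            merged[-1] = (ps, max(pe, e), pv + v, pn + 1)
        else:
            merged.append((s, e, v, 1))
    return [(s, e, v / n, ) for s, e, v, n in merged]


def read_fasta(path: str | Path) -> tuple[str, int]:
    """Read a single-record FASTA; returns (uppercased sequence, length)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA record found")
    if len(records) > 1:
        raise FormatError(f"{path}: {len(records)} records; multi-replicon input unsupported")
    seq = str(records[0].seq).upper()
    return seq, len(seq)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _format_floats(obj):
    """Round-trip floats through 10 significant digits for bit-stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_format_floats(x) for x in obj.tolist()]
    if isinstance(obj, Mapping):
        return {k: _format_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_format_floats(x) for x in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _format_floats(asdict(obj))
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_report(results, path: str | Path, format: str = "json") -> Path:
    """Serialize a pipeline result deterministically (sorted keys, floats at
    10 significant digits); identical inputs produce byte-identical files."""
    path = Path(path)
    obj = _format_floats(results)
    if format == "json":
        path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
    elif format == "tsv":
        rows = obj if isinstance(obj, list) else [obj]
        if not rows:
            raise ValueError("nothing to write")
        cols = sorted(rows[0].keys())
        lines = ["\t".join(cols)]
        for r in rows:
            lines.append("\t".join(_cell(r.get(c)) for c in cols))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def _cell(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)
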