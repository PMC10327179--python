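"""Readers and writers for the standard formats the pipeline consumes.

BED3/BED6, narrowPeak (ENCODE 10-column), BAM fragment extraction,
JASPAR-format position frequency matrices, chromosome-sizes files,
expression tables (TSV of TF -> RPKM), label lists and a YAML run
configuration.  Everything is converted to 0-based half-open coordinates
at this boundary and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .intervals import FragmentRecord, GenomicInterval, NarrowPeakRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PositionFrequencyMatrix",
    "ExpressionTable",
    "PipelineConfig",
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_fragments",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_expression_table",
    "read_label_list",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Observed base counts per motif position, rows ordered A, C, G, T."""

    tf_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PFM counts must have shape (4, L), L >= 1")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column needs a positive sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class ExpressionTable:
    """TF gene expression in one cell line, as RPKM values."""

    cell_line: str
    rpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, value in self.rpkm.items():
            if value < 0:
                raise ValueError(f"negative RPKM for {tf}")

    def get(self, tf_name: str) -> float | None:
        return self.rpkm.get(tf_name)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one document.

    Defaults are the values the method was developed with; any subset can
    be overridden from a YAML file.
    """

    smoothing_bandwidth: int = 15          # triweight bandwidth h, bp
    maxima_min_separation: int = 150       # bp between retained maxima
    dyad_window: int = 60                  # representative-dyad window, bp
    nr_flank: int = 73                     # NR half-width, bp
    dyad_fragment_min: int = 146           # fragment sizes used for dyads
    dyad_fragment_max: int = 148
    mononucleosome_min: int = 120          # fragment sizes defining NDRs
    mononucleosome_max: int = 180
    open_chromatin_flank: int = 1000       # bp around DNase summits
    conserved_min_overlap: float = 0.8
    differential_max_overlap: float = 0.2
    motif_p_threshold: float = 1e-4
    pwm_pseudocount: float = 0.1
    profile_half_width: int = 1000         # motif profile extent, bp
    occupancy_half_width: int = 400        # occupancy correlation window
    bp_per_shl: float = 10.5
    rpkm_min: float = 10.0
    min_nr_motif_bp: int = 500             # profile filter
    min_symmetry_pcc: float = 0.4
    fold_half_width: int = 60
    tsne_perplexity: float = 10.0
    n_clusters: int = 6
    silhouette_outlier_max: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )


def _split_line(line: str, lineno: int, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise ParseError(
            f"line {lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def read_intervals(
    path: str | Path, format: str = "bed"
) -> list[GenomicInterval] | list[NarrowPeakRecord]:
    """Read a BED3/BED6 or narrowPeak file.

    Comment (``#``), ``track`` and ``browser`` lines are skipped.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unsupported interval format {format!r}")
    records: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                if format == "bed":
                    fields = _split_line(line, lineno, 3)
                    strand = fields[5] if len(fields) >= 6 else "."
                    records.append(
                        GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2]), strand
                        )
                    )
                else:
                    fields = _split_line(line, lineno, 10)
                    records.append(
                        NarrowPeakRecord(
                            chrom=fields[0],
                            start=int(fields[1]),
                            end=int(fields[2]),
                            name=fields[3],
                            score=float(fields[4]),
                            strand=fields[5],
                            signal_value=float(fields[6]),
                            p_score=float(fields[7]),
                            q_score=float(fields[8]),
                            summit_offset=int(fields[9]),
                        )
                    )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"line {lineno}: {exc}") from exc
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_intervals(
    records: Iterable,
    path: str | Path,
    format: str = "bed",
    values: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6, narrowPeak or (with ``values``) bedGraph."""
    if format not in ("bed", "bedGraph", "narrowPeak"):
        raise ValueError(f"unsupported output format {format!r}")
    records = list(records)
    with open(path, "w") as fh:
        if format == "bedGraph":
            if values is None or len(values) != len(records):
                raise ValueError("bedGraph needs one value per record")
            for iv, v in zip(records, values):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:g}\n")
            return
        for iv in records:
            if format == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                    f"{iv.score:g}\t{iv.strand}\t{iv.signal_value:g}\t"
                    f"{iv.p_score:g}\t{iv.q_score:g}\t{iv.summit_offset}\n"
                )
            else:
                strand = getattr(iv, "strand", ".")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{strand}\n"
                )


def read_fragments(
    path: str | Path, format: str = "bed", replicate_id: str = "rep1"
) -> list[FragmentRecord]:
    """Read mono-nucleosome fragments from BED or a coordinate-sorted BAM.

    For BAM, each properly paired read pair yields one fragment spanning
    the outer coordinates of the pair (template length on the forward
    mate); secondary/supplementary/unpaired records are skipped and the
    skip count logged.
    """
    if format == "bed":
        out = []
        for lineno, iv in enumerate(read_intervals(path, "bed"), start=1):
            out.append(
                FragmentRecord(iv.chrom, iv.start, iv.end, replicate_id)
            )
        if not out:
            logger.warning("no fragments read from %s", path)
        return out
    if format != "bam":
        raise ValueError(f"unsupported fragment format {format!r}")
    import pysam

    fragments: list[FragmentRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
                or read.is_reverse  # count each pair once, on the fwd mate
            ):
                if not read.is_reverse:
                    skipped += 1
                continue
            tlen = read.template_length
            if tlen <= 0:
                skipped += 1
                continue
            fragments.append(
                FragmentRecord(
                    read.reference_name,
                    read.reference_start,
                    read.reference_start + tlen,
                    replicate_id,
                )
            )
    if skipped:
        logger.info("skipped %d non-proper alignments in %s", skipped, path)
    return fragments


def read_jaspar_pfm(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Parse a JASPAR-format PFM file (possibly with multiple records).

    Format per record: a ``>ID NAME`` header then four rows like
    ``A  [ 10  3  0 ... ]`` in any base order; rows are reordered to
    A, C, G, T.
    """
    pfms: list[PositionFrequencyMatrix] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ParseError(f"PFM {name}: missing rows {sorted(missing)}")
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise ParseError(f"PFM {name}: row lengths differ ({lengths})")
        pfms.append(
            PositionFrequencyMatrix(
                name, np.array([rows[b] for b in BASES], dtype=float)
            )
        )
        name, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                # prefer the human-readable name over the matrix ID
                name = parts[1] if len(parts) > 1 else parts[0]
                continue
            base = line[0].upper()
            if base not in BASES:
                raise ParseError(f"line {lineno}: unexpected row {line[:20]!r}")
            numbers = line[1:].replace("[", " ").replace("]", " ").split()
            try:
                rows[base] = [float(x) for x in numbers]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    flush()
    if not pfms:
        raise ParseError(f"no PFM records in {path}")
    return pfms


def write_jaspar_pfm(
    pfms: Iterable[PositionFrequencyMatrix], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.tf_name} {pfm.tf_name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{int(v)}" for v in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, lineno, 2)
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_expression_table(
    path: str | Path, cell_line: str = ""
) -> ExpressionTable:
    """Read a two-column TSV of TF name -> RPKM.  A header line whose
    second column is not numeric is skipped."""
    rpkm: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line, lineno, 2)
            try:
                value = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise ParseError(f"line {lineno}: non-numeric RPKM")
            rpkm[fields[0]] = value
    return ExpressionTable(cell_line=cell_line, rpkm=rpkm)


def read_label_list(path: str | Path) -> set[str]:
    """Read a one-name-per-line label file (e.g. known pioneer factors)."""
    labels: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                labels.add(line.split("\t")[0])
    return labels


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory, uppercased."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(
    sequences: Mapping[str, str], path: str | Path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
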