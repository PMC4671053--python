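"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are 0-based, half-open internally (BED convention).  SAM
input, which is 1-based, is converted at the I/O boundary by pysam.  Reads,
genes and generic intervals are carried as pandas DataFrames with a fixed
column schema so every downstream module shares one in-memory model:

* aligned reads:  ``chrom, start, end, strand``
* gene models:    ``gene_id, chrom, strand, start, end, tss, tts``
* intervals:      ``chrom, start, end[, name, score]``

``tss`` follows the convention that a minus-strand gene spanning
``[start, end)`` has ``tss == end`` and ``tts == start`` (the TSS is the 5'
end with respect to the strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss", "tts"]


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ConfigError(ValueError):
    """An invalid parameter value was supplied."""


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome name -> length (bp) lookup."""

    chrom_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def __iter__(self):
        return iter(self.chrom_sizes)

    def __len__(self) -> int:
        return len(self.chrom_sizes)

    def items(self):
        return self.chrom_sizes.items()

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeIndex":
        """Read a two-column chrom-sizes TSV (name <TAB> length)."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
                name = parts[0]
                if name in sizes:
                    raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                try:
                    sizes[name] = int(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, size in self.chrom_sizes.items():
                fh.write(f"{name}\t{size}\n")


def _guess_format(path: str | Path, choices: dict[str, str]) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in choices:
        return choices[suffix]
    raise ConfigError(
        f"cannot infer format of {path!r} from extension; pass format= explicitly"
    )


# ---------------------------------------------------------------------------
# aligned reads
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    genome: GenomeIndex,
    format: str | None = None,
) -> pd.DataFrame:
    """Read aligned single-end tags from BED6 or SAM/BAM into the shared model.

    Records on chromosomes absent from *genome* or extending past the
    chromosome end are dropped; the counts are logged and recorded in
    ``df.attrs['n_rejected_unknown_chrom']`` / ``df.attrs['n_rejected_bounds']``.
    """
    if format is None:
        format = _guess_format(path, {"bed": "bed", "sam": "sam", "bam": "bam"})
    format = format.lower()
    if format == "bed" or format == "bed6":
        df = _read_bed_reads(path)
    elif format in ("sam", "bam"):
        df = _read_sam_reads(path, format)
    else:
        raise ConfigError(f"unknown alignment format {format!r}")

    known = df["chrom"].isin(genome.chrom_sizes).to_numpy()
    n_unknown = int((~known).sum())
    df = df[known]
    sizes = df["chrom"].map(genome.chrom_sizes).to_numpy()
    in_bounds = (df["start"].to_numpy() >= 0) & (df["end"].to_numpy() <= sizes)
    n_bounds = int((~in_bounds).sum())
    df = df[in_bounds].reset_index(drop=True)
    if n_unknown:
        log.warning("%s: dropped %d reads on unknown chromosomes", path, n_unknown)
    if n_bounds:
        log.warning("%s: dropped %d reads outside chromosome bounds", path, n_bounds)
    df.attrs["n_rejected_unknown_chrom"] = n_unknown
    df.attrs["n_rejected_bounds"] = n_bounds
    return df


def _read_bed_reads(path: str | Path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "strand": str},
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: not parseable as BED6 ({exc})") from exc
    bad = ~raw["strand"].isin(["+", "-"])
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(f"{path}:{lineno}: strand must be '+' or '-'")
    bad = raw["start"].to_numpy() >= raw["end"].to_numpy()
    if bad.any():
        lineno = int(np.flatnonzero(bad)[0]) + 1
        raise FormatError(f"{path}:{lineno}: start must be < end")
    out = raw[["chrom", "start", "end", "strand"]].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def _read_sam_reads(path: str | Path, format: str) -> pd.DataFrame:
    import pysam

    mode = "rb" if format == "bam" else "r"
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": strands,
        }
    )


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads as BED6 (name = running id, score = 0)."""
    n = len(reads)
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"].to_numpy(),
            "start": reads["start"].to_numpy(),
            "end": reads["end"].to_numpy(),
            "name": [f"r{i}" for i in range(n)],
            "score": np.zeros(n, dtype=int),
            "strand": reads["strand"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: str | Path,
    format: str | None = None,
) -> pd.DataFrame:
    """Read a gene annotation (BED12 or GTF), one gene model per transcript.

    Duplicate gene ids keep the first occurrence with a warning.
    """
    if format is None:
        format = _guess_format(path, {"bed": "bed12", "bed12": "bed12", "gtf": "gtf"})
    format = format.lower()
    if format in ("bed", "bed12"):
        genes = _read_bed12_genes(path)
    elif format == "gtf":
        genes = _read_gtf_genes(path)
    else:
        raise ConfigError(f"unknown annotation format {format!r}")

    dup = genes["gene_id"].duplicated()
    if dup.any():
        log.warning("%s: %d duplicate gene ids, keeping first", path, int(dup.sum()))
        genes = genes[~dup]
    return genes.reset_index(drop=True)


def _gene_frame(gene_id, chrom, strand, start, end) -> pd.DataFrame:
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    strand = np.asarray(strand)
    tss = np.where(strand == "+", start, end)
    tts = np.where(strand == "+", end, start)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "chrom": chrom,
            "strand": strand,
            "start": start,
            "end": end,
            "tss": tss,
            "tts": tts,
        }
    )


def _read_bed12_genes(path: str | Path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: not parseable as BED ({exc})") from exc
    if raw.shape[1] < 6:
        raise FormatError(f"{path}: BED gene annotation needs at least 6 columns")
    return _gene_frame(raw[3], raw[0], raw[5], raw[1], raw[2])


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf_genes(path: str | Path) -> pd.DataFrame:
    transcripts: dict[str, list] = {}
    saw_transcript_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 tab-separated columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("transcript", "mRNA", "exon"):
                continue
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id") or a.get("gene_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: no transcript_id/gene_id attribute")
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature in ("transcript", "mRNA"):
                saw_transcript_feature = True
                transcripts[tid] = [chrom, strand, s, e, True]
            else:  # exon: extend span unless an explicit transcript record exists
                rec = transcripts.get(tid)
                if rec is None:
                    transcripts[tid] = [chrom, strand, s, e, False]
                elif not rec[4]:
                    rec[2] = min(rec[2], s)
                    rec[3] = max(rec[3], e)
    if not transcripts:
        raise FormatError(f"{path}: no transcript or exon features found")
    if saw_transcript_feature:
        transcripts = {k: v for k, v in transcripts.items() if v[4]}
    ids = list(transcripts)
    recs = [transcripts[i] for i in ids]
    return _gene_frame(
        ids,
        [r[0] for r in recs],
        [r[1] for r in recs],
        [r[2] for r in recs],
        [r[3] for r in recs],
    )


def write_genes_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "w") as fh:
        for rec in genes.itertuples(index=False):
            length = rec.end - rec.start
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}"
                f"\t{rec.start}\t{rec.end}\t0\t1\t{length},\t0,\n"
            )


# ---------------------------------------------------------------------------
# generic intervals (BED3+) and bedGraph tracks
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ interval file (``chrom, start, end[, name, score]``)."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: not parseable as BED ({exc})") from exc
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
        }
    )
    if raw.shape[1] > 3:
        out["name"] = raw[3]
    if raw.shape[1] > 4:
        out["score"] = raw[4]
    if (out["start"] >= out["end"]).any():
        raise FormatError(f"{path}: interval with start >= end")
    return out


def write_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


TRACK_PRECISION = 6  # significant digits kept when printing bedGraph values


def write_track(track: pd.DataFrame, path: str | Path, precision: int = TRACK_PRECISION) -> None:
    """Write per-bin values (``chrom, start, end, value``) as sorted bedGraph."""
    df = track.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n')
        for rec in df.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.value:.{precision}g}\n")


def read_track(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited expression table (header row, gene_id column)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: expression table needs a 'gene_id' column")
    return df


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
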