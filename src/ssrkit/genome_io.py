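"""Reading and writing the formats the pipeline touches.

Coordinate convention for the whole package: internal coordinates are
0-based half-open ``[start, end)``; every emitted file (TSV, GFF3) is
1-based inclusive, the convention of GFF3 and of most SSR mining tools.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for structurally invalid genome FASTA input."""


@dataclass(frozen=True)
class Chromosome:
    """One assembled sequence: name plus an uppercase DNA string over ACGTN."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of chromosomes with unique names."""

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise FastaFormatError("duplicate chromosome names in genome")
        self._by_name = {c.name: c for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    for pos, base in enumerate(seq):
        if base not in VALID_BASES:
            raise FastaFormatError(
                f"illegal character {base!r} in record {name!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path | TextIO) -> Genome:
    """Read a multi-record genome FASTA.

    Sequences are uppercased; characters outside ``ACGTN`` are rejected with
    the offending record and 0-based position named. Record order is kept.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    chroms: list[Chromosome] = []
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record name {rec.id!r}")
        seen.add(rec.id)
        chroms.append(Chromosome(rec.id, _validate_sequence(rec.id, str(rec.seq))))
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path | TextIO, width: int = 60) -> None:
    """Write a genome as FASTA, wrapped at `width` columns."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in genome
    ]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)
    else:
        writer = SeqIO.FastaIO.FastaWriter(path, wrap=width)
        writer.write_file(records)


SSR_TABLE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "canonical_motif",
    "observed_motif",
    "unit_count",
    "total_length",
    "mismatches",
)


def write_ssr_table(
    records: Sequence,
    path: str | Path | TextIO,
    dialect: str = "tsv",
    comments: Iterable[str] = (),
) -> None:
    """Write detected SSRs as TSV or GFF3 with 1-based inclusive coordinates.

    `records` must already be sorted by (chromosome, start); SSR coordinates
    are strandless (the canonical motif folds in both strands).

    Parameters
    ----------
    records:
        SSRRecord sequence, sorted by (chromosome, start).
    dialect:
        ``"tsv"`` (header row + 8 columns) or ``"gff3"`` (9-column feature
        lines, type ``microsatellite``).
    comments:
        Extra '#'-prefixed provenance lines written before the header.
    """
    if dialect not in ("tsv", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    keys = [(r.chromosome, r.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chromosome, start)")

    buf = io.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    if dialect == "tsv":
        buf.write("\t".join(SSR_TABLE_COLUMNS) + "\n")
        for r in records:
            buf.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.chromosome,
                        r.start + 1,
                        r.end,
                        r.canonical_motif,
                        r.observed_motif,
                        r.unit_count,
                        r.total_length,
                        r.mismatches,
                    )
                )
                + "\n"
            )
    else:
        buf.write("##gff-version 3\n")
        for i, r in enumerate(records, start=1):
            attrs = (
                f"ID=ssr{i};canonical_motif={r.canonical_motif};"
                f"observed_motif={r.observed_motif};unit_count={r.unit_count};"
                f"mismatches={r.mismatches}"
            )
            buf.write(
                "\t".join(
                    (
                        r.chromosome,
                        "ssrkit",
                        "microsatellite",
                        str(r.start + 1),
                        str(r.end),
                        str(r.score),
                        ".",
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )
    text = buf.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def read_ssr_table(path: str | Path | TextIO):
    """Read a TSV written by :func:`write_ssr_table` back to SSRRecord objects.

    Emitted 1-based inclusive coordinates are converted back to the internal
    0-based half-open convention, so a write/read round trip is exact.
    """
    from .ssr_engine import SSRRecord

    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh, close = path, False
    try:
        records = []
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            start = int(row["start"]) - 1
            end = int(row["end"])
            motif = row["observed_motif"]
            mism = int(row["mismatches"])
            records.append(
                SSRRecord(
                    chromosome=row["chrom"],
                    start=start,
                    end=end,
                    period=len(motif),
                    observed_motif=motif,
                    canonical_motif=row["canonical_motif"],
                    mismatches=mism,
                    # score is not a table column; reconstruct under the
                    # default fixed penalty of 5 (exact for perfect records)
                    score=(end - start) - 6 * mism,
                )
            )
        return records
    finally:
        if close:
            fh.close()
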