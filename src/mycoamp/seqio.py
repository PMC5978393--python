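"""Sequence records and FASTA/FASTQ input/output.

All pipeline stages exchange :class:`Read` objects.  Sample identity is
carried inside the sequence header as a ``;sample=<name>`` suffix so that
reads from every sample can travel through clustering in one combined file;
the codec here strips and re-adds that suffix losslessly.

Only Phred+33 quality encoding is supported.  Files ending in ``.gz`` are
read and written through gzip transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "Read",
    "BarcodeSpec",
    "SampleSheet",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "write_fasta",
    "read_sample_sheet",
    "encode_header",
    "decode_header",
]

_VALID = set("ACGTN")
# anything outside ACGTN (including lowercase after upper()) becomes N
_NORMALIZE = {c: c if c in _VALID else "N" for c in map(chr, range(65, 91))}


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message carries the record index."""


def _normalize_seq(seq: str) -> str:
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(_NORMALIZE.get(c, "N") for c in up)


@dataclass
class Read:
    """One sequencing read.

    ``seq`` is uppercase DNA over {A,C,G,T,N}; letters outside that alphabet
    are mapped to N when records are constructed through the readers.
    ``qual`` holds Phred integers (one per base) or is None for FASTA input.
    ``sample`` is the demultiplexed sample label, or None before demux.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.qual)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BarcodeSpec:
    """Per-sample barcode/index assignment.

    Single-end layouts use a 5' ``fwd_barcode`` (optionally a 3'
    ``rev_barcode``); dual-index layouts use ``i5`` + ``i7``.
    """

    fwd_barcode: Optional[str] = None
    rev_barcode: Optional[str] = None
    i5: Optional[str] = None
    i7: Optional[str] = None

    def __post_init__(self) -> None:
        if not any([self.fwd_barcode, self.rev_barcode, self.i5, self.i7]):
            raise ValueError("BarcodeSpec needs at least one barcode/index")


@dataclass
class SampleSheet:
    """Sample → barcode mapping plus the primer pair used for the run."""

    entries: dict[str, BarcodeSpec]
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("both primers are required")
        for attr in ("fwd_barcode", "rev_barcode"):
            seen: dict[str, str] = {}
            for name, spec in self.entries.items():
                bc = getattr(spec, attr)
                if bc is None:
                    continue
                if bc in seen:
                    raise ValueError(
                        f"duplicate {attr} {bc!r} for samples "
                        f"{seen[bc]!r} and {name!r}"
                    )
                seen[bc] = name
        pairs: dict[tuple, str] = {}
        for name, spec in self.entries.items():
            if spec.i5 or spec.i7:
                key = (spec.i5, spec.i7)
                if key in pairs:
                    raise ValueError(
                        f"duplicate index pair {key} for samples "
                        f"{pairs[key]!r} and {name!r}"
                    )
                pairs[key] = name


# -- sample label codec ------------------------------------------------------

_SAMPLE_TAG = ";sample="


def encode_header(read: Read) -> str:
    """Header string for *read*, appending ``;sample=<name>`` when labeled."""
    if read.sample is None:
        return read.id
    return f"{read.id}{_SAMPLE_TAG}{read.sample}"


def decode_header(header: str) -> tuple[str, Optional[str]]:
    """Split a header into (read id, sample label or None)."""
    if _SAMPLE_TAG in header:
        rid, _, sample = header.rpartition(_SAMPLE_TAG)
        return rid, sample
    return header, None


# -- readers / writers -------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Stream :class:`Read` records from a Phred+33 FASTQ file.

    Malformed records raise :class:`FastqParseError` naming the offending
    line.  Sequences are uppercased and non-ACGTN letters become N.
    """
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@', got {header[:20]!r}"
                )
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not qual and not seq:
                raise FastqParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {lineno - 1}: expected '+' separator"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            rid, sample = decode_header(header[1:].split(" ")[0])
            yield Read(
                id=rid,
                seq=_normalize_seq(seq),
                qual=[ord(c) - 33 for c in qual],
                sample=sample,
            )


def read_fasta(path) -> Iterator[Read]:
    """Stream records from a FASTA file (qual is None)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rid, sample = decode_header(rec.id)
            yield Read(id=rid, seq=_normalize_seq(str(rec.seq)), sample=sample)


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write Phred+33 FASTQ; every read must carry qualities."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            if read.qual is None:
                raise ValueError(f"read {read.id!r} has no qualities")
            handle.write(
                f"@{encode_header(read)}\n{read.seq}\n+\n"
                + "".join(chr(q + 33) for q in read.qual)
                + "\n"
            )


def write_fasta(reads: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f">{encode_header(read)}\n{read.seq}\n")


def read_sample_sheet(path) -> SampleSheet:
    """Load a TSV sample sheet.

    Expected columns: ``sample  fwd_barcode  rev_barcode  i5  i7`` with a
    header row; empty cells mean "not used".  The primer pair is given on
    special rows named ``fwd_primer`` / ``rev_primer`` in the first two
    columns, or passed to :class:`SampleSheet` directly by the caller.
    """
    entries: dict[str, BarcodeSpec] = {}
    fwd_primer = rev_primer = None
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            row = dict(zip(header, cells + [""] * (len(header) - len(cells))))
            name = row.get("sample", "")
            if name == "fwd_primer":
                fwd_primer = row.get("fwd_barcode") or ""
                continue
            if name == "rev_primer":
                rev_primer = row.get("fwd_barcode") or ""
                continue
            if not name:
                raise ValueError(f"{path}: line {lineno}: missing sample name")
            if name in entries:
                raise ValueError(f"{path}: line {lineno}: duplicate sample {name!r}")
            entries[name] = BarcodeSpec(
                fwd_barcode=row.get("fwd_barcode") or None,
                rev_barcode=row.get("rev_barcode") or None,
                i5=row.get("i5") or None,
                i7=row.get("i7") or None,
            )
    if fwd_primer is None or rev_primer is None:
        raise ValueError(f"{path}: fwd_primer/rev_primer rows are required")
    return SampleSheet(entries=entries, fwd_primer=fwd_primer, rev_primer=rev_primer)
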