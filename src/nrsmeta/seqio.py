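"""Sequence input/output.

FASTA/FASTQ readers (plain or gzip, auto-detected from the magic bytes),
colon-separated multi-file tokens, mapping of nucleotide text onto the
internal 4-symbol alphabet {A,C,G,T} -> {0,1,2,3}, and deterministic TSV
writing used by every tabular output of the tool.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "ParseError",
    "UsageError",
    "parse_multifile_token",
    "read_records",
    "encode_symbols",
    "decode_symbols",
    "write_fasta",
    "write_fastq",
    "write_tsv",
    "format_float",
]


class Alphabet:
    """The 4-symbol DNA alphabet. ``bits_per_symbol`` is log2(4) = 2 exactly."""

    SIZE: int = 4
    BITS_PER_SYMBOL: float = 2.0
    BASES: str = "ACGT"


# byte value -> symbol index; 255 marks non-ACGT
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_BASES_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class UsageError(ValueError):
    """Bad command-line style input (empty token, invalid option combination)."""


class ParseError(ValueError):
    """Malformed FASTA/FASTQ content."""


@dataclass
class SequenceRecord:
    """One parsed FASTA/FASTQ entry over the 4-symbol alphabet.

    ``id`` is the first whitespace-delimited token of the header and is used
    as the read/reference key everywhere downstream.  ``symbols`` is an
    int8 array over {0,1,2,3}; ``n_substituted`` counts non-ACGT input
    characters that were replaced during encoding.
    """

    id: str
    description: str
    symbols: np.ndarray
    quality: str | None = None
    n_substituted: int = 0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        if self.symbols.size and (self.symbols.min() < 0 or self.symbols.max() > 3):
            raise ValueError("symbols must lie in {0,1,2,3}")
        if self.quality is not None and len(self.quality) != self.symbols.size:
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {self.symbols.size}"
            )

    @property
    def length(self) -> int:
        return int(self.symbols.size)

    @property
    def sequence(self) -> str:
        return decode_symbols(self.symbols)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        rc = (3 - self.symbols[::-1]).astype(np.int8)
        return SequenceRecord(new_id or self.id, self.description, rc)


def parse_multifile_token(token: str) -> list[str]:
    """Split a colon-separated multi-file token into an ordered path list.

    ``"R1.fq.gz:R2.fq.gz"`` denotes paired-end inputs handled as a
    concatenated read stream.  Empty tokens or empty components are usage
    errors; missing files raise ``FileNotFoundError`` naming the path.
    """
    if not token:
        raise UsageError("empty file token")
    parts = token.split(":")
    if any(p == "" for p in parts):
        raise UsageError(f"empty component in file token {token!r}")
    for p in parts:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    return parts


def encode_symbols(
    text: str,
    policy: str = "random",
    rng: int | np.random.Generator = 13,
) -> tuple[np.ndarray, int]:
    """Map nucleotide text (case-insensitive) to symbols {0,1,2,3}.

    Non-ACGT characters are handled per ``policy``:

    * ``random`` (default) — replaced by a seeded pseudo-random in-alphabet
      symbol, preserving sequence length (the NRS denominator 2|x| stays
      well defined);
    * ``strict`` — raise on the first non-ACGT character;
    * ``skip``  — drop them (length shrinks).

    Returns ``(symbols, n_substituted)``; deterministic given
    ``(text, policy, rng seed/state)``.
    """
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    syms = _LUT[raw]
    bad = syms == 255
    n_bad = int(bad.sum())
    if n_bad == 0:
        return syms.astype(np.int8), 0
    if policy == "strict":
        pos = int(np.argmax(bad))
        raise ParseError(f"non-ACGT character {text[pos]!r} at position {pos}")
    if policy == "skip":
        return syms[~bad].astype(np.int8), n_bad
    if policy != "random":
        raise ValueError(f"unknown non-ACGT policy {policy!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    syms = syms.copy()
    syms[bad] = rng.integers(0, 4, size=n_bad, dtype=np.uint8)
    return syms.astype(np.int8), n_bad


def decode_symbols(symbols: np.ndarray) -> str:
    return _BASES_ARR[np.asarray(symbols, dtype=np.uint8)].tobytes().decode("ascii")


def _open_text(path: str | Path) -> io.TextIOWrapper:
    """Open plain or gzip text transparently (gzip magic bytes 0x1f 0x8b)."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="ascii")
    return io.TextIOWrapper(fh, encoding="ascii")


def _sniff_kind(handle: io.TextIOWrapper, path: str | Path) -> str:
    head = handle.read(1)
    handle.seek(0)
    if head == ">":
        return "fasta"
    if head == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot determine format (first character {head!r})")


def read_records(
    paths: Sequence[str | Path] | str | Path,
    kind: str = "auto",
    policy: str = "random",
    rng: int | np.random.Generator = 13,
) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from one or more FASTA/FASTQ files.

    Records are yielded in file order across the token's files.  gzip input
    is detected from the magic bytes and decompressed on the fly, so a file
    and its gzipped copy produce the identical record stream.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for path in paths:
        with _open_text(path) as handle:
            fmt = _sniff_kind(handle, path) if kind == "auto" else kind
            if fmt == "fasta":
                for header, seq in SimpleFastaParser(handle):
                    rec_id, _, desc = header.partition(" ")
                    syms, nsub = encode_symbols(seq, policy=policy, rng=rng)
                    yield SequenceRecord(rec_id, desc, syms, None, nsub)
            elif fmt == "fastq":
                n = 0
                try:
                    for header, seq, qual in FastqGeneralIterator(handle):
                        n += 1
                        rec_id, _, desc = header.partition(" ")
                        syms, nsub = encode_symbols(seq, policy=policy, rng=rng)
                        if policy != "skip" and len(qual) != len(seq):
                            raise ParseError(
                                f"{path}: record {n} (near line {4 * n}): quality "
                                f"length {len(qual)} != sequence length {len(seq)}"
                            )
                        qual_out = qual if policy != "skip" else None
                        yield SequenceRecord(rec_id, desc, syms, qual_out, nsub)
                except ValueError as exc:  # Biopython signals malformed FASTQ
                    if isinstance(exc, (ParseError, UsageError)):
                        raise
                    raise ParseError(
                        f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
                    ) from exc
            else:
                raise ValueError(f"unknown kind {fmt!r}")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * rec.length
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def format_float(value: float) -> str:
    """Fixed 6-decimal rendering used in every TSV so byte-identity is meaningful."""
    return f"{value:.6f}"


def write_tsv(rows: Iterable[Sequence], columns: Sequence[str], path: str | Path) -> None:
    """Write a header line then tab-separated rows.

    Floats are rendered with the fixed 6-decimal format; everything else via
    ``str``.  Zero rows yield a header-only file.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("\t".join(columns) + "\n")
        for row in rows:
            cells = [
                format_float(c) if isinstance(c, (float, np.floating)) else str(c)
                for c in row
            ]
            out.write("\t".join(cells) + "\n")
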