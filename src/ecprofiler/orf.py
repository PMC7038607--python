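"""Candidate ORF extraction from short nucleotide reads.

Shotgun reads are mid-gene fragments, so the built-in caller translates all
six frames and emits every maximal stop-free stretch above a length cutoff —
no start codon is required and no sequencing-error model is applied.
Output of an external probabilistic ORF caller (FragGeneScan-style
amino-acid FASTA) can be imported instead.
"""

from __future__ import annotations

import gzip
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Read:
    id: str
    sequence: str  # over {A,C,G,T,N}
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality length != sequence length")


@dataclass
class ORFCall:
    read_id: str
    frame: int | None  # +1..+3 forward, -1..-3 reverse; None when imported without coordinates
    start: int | None  # 0-based half-open interval on the read's forward strand
    end: int | None
    protein: str  # amino acids, no stop symbol

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if self.end - self.start != 3 * len(self.protein):
                raise ValueError("interval length must equal 3 x amino-acid length")
        if "*" in self.protein:
            raise ValueError("ORF protein may not contain a stop symbol")


def _codon_map(table: int) -> dict[str, str]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    mapping = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        mapping[stop] = "*"
    return mapping


def _translate(nt: str, table: int) -> str:
    """Codon-by-codon translation; any codon containing a non-ACGT base -> X."""
    mapping = _codon_map(table)
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa.append(mapping.get(nt[i : i + 3], "X"))
    return "".join(aa)


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def six_frame_orfs(read: Read, min_len_aa: int = 20, table: int = 11) -> list[ORFCall]:
    """All maximal stop-free translated stretches of >= min_len_aa residues.

    Frames +1/+2/+3 translate the forward strand at offsets 0/1/2; -1/-2/-3
    the reverse complement likewise. Intervals are reported 0-based
    half-open on the forward strand regardless of frame. The default code is
    the bacterial/archaeal table (11).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = read.sequence.upper()
    n = len(seq)
    calls: list[ORFCall] = []
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            aa = _translate(s[offset:], table)
            for match in re.finditer(r"[^*]+", aa):
                if match.end() - match.start() < min_len_aa:
                    continue
                nt_lo = offset + 3 * match.start()
                nt_hi = offset + 3 * match.end()
                if strand == 1:
                    start, end = nt_lo, nt_hi
                else:
                    start, end = n - nt_hi, n - nt_lo
                calls.append(
                    ORFCall(
                        read_id=read.id,
                        frame=strand * (offset + 1),
                        start=start,
                        end=end,
                        protein=match.group(),
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# I/O


def _open_maybe_gzip(path: str | Path):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def read_sequences(path: str | Path) -> Iterator[Read]:
    """Read FASTA or FASTQ (optionally gzipped) into Read objects."""
    p = Path(path)
    name = p.name[:-3] if p.suffix == ".gz" else p.name
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gzip(p) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(rec.id, str(rec.seq).upper(), qual)


_FGS_HEADER = re.compile(r"^(?P<read>.+)_(?P<start>\d+)_(?P<end>\d+)_(?P<strand>[+-])$")


def import_external_orfs(path: str | Path) -> list[ORFCall]:
    """Import amino-acid ORFs called by an external tool.

    Headers of the form ``readid_start_end_strand`` (1-based inclusive
    coordinates, FragGeneScan style) are parsed into forward-strand
    intervals; any other header is kept as an ORF with unknown coordinates.
    """
    calls: list[ORFCall] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().rstrip("*")
            if len(seq) > 50 and set(seq) <= set("ACGT"):
                warnings.warn(
                    f"record {rec.id!r} looks like nucleotide sequence, not amino acids",
                    stacklevel=2,
                )
            m = _FGS_HEADER.match(rec.id)
            if m:
                start = int(m.group("start")) - 1
                end = int(m.group("end"))
                frame = 1 if m.group("strand") == "+" else -1
                if end - start != 3 * len(seq):
                    start = end = frame = None  # header coordinates disagree with sequence
                calls.append(
                    ORFCall(m.group("read") if frame is not None else rec.id, frame, start, end, seq)
                )
            else:
                calls.append(ORFCall(rec.id, None, None, None, seq))
    if not calls:
        logger.warning("no ORFs found in %s", path)
    return calls


def write_orfs(calls: Iterable[ORFCall], path: str | Path) -> None:
    """Write ORFs as amino-acid FASTA with ``readid|frame|start|end`` headers."""
    with open(path, "w") as fh:
        for c in calls:
            frame = c.frame if c.frame is not None else "."
            start = c.start if c.start is not None else "."
            end = c.end if c.end is not None else "."
            fh.write(f">{c.read_id}|{frame}|{start}|{end}\n{c.protein}\n")
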