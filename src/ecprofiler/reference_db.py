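"""Gold-standard protein reference: EC labels, curation filters, persistence.

The training corpus for the classifier ensemble is a set of protein records
each carrying exactly one *complete* EC number (all four fields numeric).
Curation keeps only reviewed records with experimental evidence of existence
(protein- or transcript-level), a single complete EC annotation, and a
byte-unique amino-acid sequence, mirroring how curated enzyme reference
databases are assembled from reviewed repositories.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
EVIDENCE_LEVELS = ("protein-level", "transcript-level", "inferred")
EXPERIMENTAL_EVIDENCE = frozenset({"protein-level", "transcript-level"})


class ECParseError(ValueError):
    """Raised when a string is not a well-formed EC number."""


class CurationError(ValueError):
    """Raised when curation leaves no usable records."""


@dataclass(frozen=True, order=True)
class ECLabel:
    """A four-field Enzyme Commission number; ``-`` marks a wildcard field."""

    fields: tuple[str, str, str, str]

    @property
    def complete(self) -> bool:
        return all(f != "-" for f in self.fields)

    def __str__(self) -> str:
        return ".".join(self.fields)


def parse_ec(text: str) -> ECLabel:
    """Parse an EC number such as ``2.4.1.7`` or the incomplete ``2.4.1.-``.

    Each of the four dot-separated fields must be a positive integer or the
    wildcard ``-``; anything else raises :class:`ECParseError`.
    """
    if not text:
        raise ECParseError("empty EC string")
    parts = text.strip().split(".")
    if len(parts) != 4:
        raise ECParseError(f"EC number must have 4 fields, got {len(parts)}: {text!r}")
    for p in parts:
        if p == "-":
            continue
        if not p.isdigit() or int(p) <= 0:
            raise ECParseError(f"EC field must be a positive integer or '-': {p!r} in {text!r}")
    return ECLabel(tuple(parts))  # type: ignore[arg-type]


@dataclass
class ProteinRecord:
    """One annotated protein: sequence plus its EC labels and evidence status."""

    id: str
    sequence: str
    ec_labels: list[str]
    reviewed: bool = True
    evidence: str = "protein-level"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(
                f"protein {self.id}: evidence must be one of {EVIDENCE_LEVELS}, got {self.evidence!r}"
            )


@dataclass
class GoldStandard:
    """Curated reference: one complete EC label per record, deduplicated.

    ``mean_protein_length`` maps each EC bin to the arithmetic mean length
    (in amino acids) of its member proteins; this is the per-bin protein
    length p_b that the abundance normalization corrects against.
    """

    records: list[ProteinRecord]
    label_set: list[str] = field(default_factory=list)
    mean_protein_length: dict[str, float] = field(default_factory=dict)
    n_proteins: dict[str, int] = field(default_factory=dict)
    rejection_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_set:
            self.label_set = sorted({r.ec_labels[0] for r in self.records})
        if not self.mean_protein_length:
            lengths: dict[str, list[int]] = {}
            for r in self.records:
                lengths.setdefault(r.ec_labels[0], []).append(len(r.sequence))
            self.mean_protein_length = {
                ec: sum(v) / len(v) for ec, v in sorted(lengths.items())
            }
            self.n_proteins = {ec: len(v) for ec, v in sorted(lengths.items())}


# order matters: a record is charged to the first filter it fails
_FILTERS = ("unreviewed", "inferred_evidence", "multiple_ec", "incomplete_ec", "duplicate_sequence")


def curate_gold_standard(records: Iterable[ProteinRecord]) -> GoldStandard:
    """Apply the gold-standard curation filters.

    Keeps records that are reviewed, have protein- or transcript-level
    evidence, and carry exactly one complete EC label; byte-identical
    sequences are collapsed to the first-seen record. Raises
    :class:`CurationError` (carrying per-filter rejection counts) if nothing
    survives.
    """
    rejections = {f: 0 for f in _FILTERS}
    kept: list[ProteinRecord] = []
    seen_sequences: set[str] = set()
    total = 0
    for rec in records:
        total += 1
        if not rec.reviewed:
            rejections["unreviewed"] += 1
            continue
        if rec.evidence not in EXPERIMENTAL_EVIDENCE:
            rejections["inferred_evidence"] += 1
            continue
        if len(rec.ec_labels) != 1:
            rejections["multiple_ec"] += 1
            continue
        try:
            ec = parse_ec(rec.ec_labels[0])
        except ECParseError:
            rejections["incomplete_ec"] += 1
            continue
        if not ec.complete:
            rejections["incomplete_ec"] += 1
            continue
        if rec.sequence in seen_sequences:
            rejections["duplicate_sequence"] += 1
            continue
        seen_sequences.add(rec.sequence)
        kept.append(ProteinRecord(rec.id, rec.sequence, [str(ec)], rec.reviewed, rec.evidence))
    if not kept:
        raise CurationError(f"no records survived curation; rejections={rejections} of {total} input records")
    gs = GoldStandard(records=kept)
    gs.rejection_counts = rejections
    return gs


# ---------------------------------------------------------------------------
# persistence


def read_annotations(fasta_path: str | Path, tsv_path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences (FASTA) plus their annotation table.

    The TSV must have columns ``protein_id``, ``ec``, ``reviewed``,
    ``evidence``; ``ec`` may list multiple labels separated by ``;``.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records: list[ProteinRecord] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "ec", "reviewed", "evidence"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"annotation TSV must have columns {sorted(required)}")
        for row in reader:
            pid = row["protein_id"]
            if pid not in seqs:
                raise ValueError(f"annotation for {pid!r} has no FASTA sequence")
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=seqs[pid],
                    ec_labels=[e.strip() for e in row["ec"].split(";") if e.strip()],
                    reviewed=row["reviewed"].strip().lower() in ("true", "1", "yes"),
                    evidence=row["evidence"].strip(),
                )
            )
    return records


def write_gold_standard(gs: GoldStandard, out_dir: str | Path) -> None:
    """Write curated FASTA, the per-EC length table, and the curation report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description=r.ec_labels[0]) for r in gs.records),
        str(out / "gold_standard.fasta"),
        "fasta",
    )
    with open(out / "ec_lengths.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ec", "p_b", "n_proteins"])
        for ec in gs.label_set:
            w.writerow([ec, repr(gs.mean_protein_length[ec]), gs.n_proteins[ec]])
    with open(out / "curation_report.json", "w") as fh:
        json.dump(
            {"retained": len(gs.records), "rejections": gs.rejection_counts},
            fh,
            indent=2,
        )


def read_gold_standard(directory: str | Path) -> GoldStandard:
    d = Path(directory)
    ec_of: dict[str, str] = {}
    records = []
    for rec in SeqIO.parse(str(d / "gold_standard.fasta"), "fasta"):
        ec = rec.description.split()[-1]
        records.append(ProteinRecord(rec.id, str(rec.seq), [ec]))
        ec_of[rec.id] = ec
    gs = GoldStandard(records=records)
    try:
        with open(d / "curation_report.json") as fh:
            gs.rejection_counts = json.load(fh)["rejections"]
    except FileNotFoundError:
        pass
    return gs


def mean_lengths_from_tsv(path: str | Path) -> dict[str, float]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["ec"]: float(row["p_b"]) for row in reader}
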