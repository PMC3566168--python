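"""Sequence and annotation data model.

Proteins are plain amino-acid strings with 1-based binding-site
annotations restricted to cysteine (C) and histidine (H), the two
residues that coordinate Fe and Cu centers in electron-transport
chains.  Candidate sites are every C and H in a sequence; each site is
represented to the classifier by a fixed window of ``2*w + 1`` residues
centered on it, padded with ``X`` at the sequence termini.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Amino acids in PSI-BLAST column order; the canonical feature order
#: used by every encoder in this package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Terminal padding symbol; encoders map it to an all-zero row.
PAD = "X"

#: Residue types the method is defined for.
CANDIDATE_RESIDUES = ("C", "H")

METALS = ("Fe", "Cu", "other")

BINDING = "binding"
NON_BINDING = "non-binding"

DEFAULT_FLANK = 6


class LoadError(ValueError):
    """Raised when an input file cannot be loaded as a data model."""


@dataclass
class LoadReport:
    """Plain-text log of substitutions, rejections and skips at load time."""

    replaced_letters: int = 0
    lines: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.lines.append(message)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "\n".join(self.lines)


@dataclass
class ProteinRecord:
    """A protein sequence plus its annotated metal-binding positions.

    ``binding_sites`` maps 1-based positions to the bound metal
    (``Fe``, ``Cu`` or ``other``).  Every annotated position must carry
    a C or H in the sequence; :func:`read_annotations` enforces this.
    """

    id: str
    sequence: str
    binding_sites: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise LoadError(
                f"{self.id}: position {position} outside [1, {len(self.sequence)}]"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class ResidueSite:
    """A candidate residue with its binding label."""

    protein_id: str
    position: int
    residue: str
    label: str  # BINDING or NON_BINDING

    @property
    def is_binding(self) -> bool:
        return self.label == BINDING


@dataclass(frozen=True)
class Window:
    """A ``2*w + 1`` residue context centered on a candidate site.

    The center character equals ``site.residue`` and is never the
    padding symbol; ``X`` may appear only as a contiguous prefix and/or
    suffix from running off the sequence ends.
    """

    site: ResidueSite
    context: str
    w: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if len(self.context) != 2 * self.w + 1:
            raise ValueError(
                f"context length {len(self.context)} != {2 * self.w + 1}"
            )
        if self.context[self.w] != self.site.residue or self.site.residue == PAD:
            raise ValueError("window center must equal the site residue")
        core = self.context.strip(PAD)
        if PAD in core:
            raise ValueError("padding symbol must be a contiguous prefix/suffix")

    def residue_at(self, offset: int) -> str:
        """Residue at a center-relative offset in [-w, w]."""
        if not -self.w <= offset <= self.w:
            raise ValueError(f"offset {offset} outside [-{self.w}, {self.w}]")
        return self.context[self.w + offset]

    @property
    def label(self) -> str:
        return self.site.label


def _clean_sequence(raw: str, report: LoadReport, rec_id: str) -> str:
    seq = raw.upper()
    cleaned = []
    for ch in seq:
        if ch in AMINO_ACIDS:
            cleaned.append(ch)
        else:
            cleaned.append(PAD)
            report.replaced_letters += 1
            report.log(f"{rec_id}: non-standard letter {ch!r} mapped to {PAD}")
    return "".join(cleaned)


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], LoadReport]:
    """Read a multi-entry FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; non-standard letters (B, Z, U, X, ...)
    are mapped to the padding symbol and counted in the load report.
    Duplicate ids, zero-length sequences and empty files are load
    errors naming the offender.
    """
    path = Path(path)
    report = LoadReport()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise LoadError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = _clean_sequence(str(entry.seq), report, entry.id)
        if not seq:
            raise LoadError(f"{path}: record {entry.id!r} has zero-length sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise LoadError(f"{path}: no FASTA records found")
    return records, report


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


ANNOTATION_COLUMNS = ("protein_id", "position", "residue", "metal")


def read_annotations(
    path: str | Path, records: list[ProteinRecord]
) -> tuple[list[ProteinRecord], LoadReport]:
    """Attach binding-site rows from a TSV file to loaded records.

    Expected columns: ``protein_id  position  residue  metal`` with
    1-based positions.  Rows whose residue letter disagrees with the
    sequence are rejected with a per-row report; rows whose residue is
    not C or H are skipped (the method is defined only for those two);
    unknown protein ids and out-of-range positions are load errors.
    """
    path = Path(path)
    report = LoadReport()
    by_id = {r.id: r for r in records}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(ANNOTATION_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise LoadError(
                f"{path}: expected columns {ANNOTATION_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            pid = row["protein_id"]
            if pid not in by_id:
                raise LoadError(f"{path}:{i}: unknown protein id {pid!r}")
            rec = by_id[pid]
            try:
                pos = int(row["position"])
            except ValueError as exc:
                raise LoadError(f"{path}:{i}: non-integer position") from exc
            if not 1 <= pos <= len(rec.sequence):
                raise LoadError(
                    f"{path}:{i}: position {pos} outside [1, {len(rec.sequence)}] for {pid}"
                )
            res = row["residue"].upper()
            if rec.sequence[pos - 1] != res:
                report.log(
                    f"{path}:{i}: rejected — annotated residue {res} disagrees "
                    f"with sequence letter {rec.sequence[pos - 1]} at {pid}:{pos}"
                )
                continue
            if res not in CANDIDATE_RESIDUES:
                report.log(
                    f"{path}:{i}: skipped — residue {res} at {pid}:{pos} is not C or H"
                )
                continue
            metal = row["metal"]
            if metal not in METALS:
                metal = "other"
            rec.binding_sites[pos] = metal
    return records, report


def write_annotations(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for rec in records:
            for pos in sorted(rec.binding_sites):
                writer.writerow(
                    [rec.id, pos, rec.sequence[pos - 1], rec.binding_sites[pos]]
                )


def extract_sites(record: ProteinRecord) -> list[ResidueSite]:
    """All candidate C/H sites of a record, in position order.

    A site is labeled ``binding`` iff its position is annotated.
    """
    sites = []
    for pos, res in enumerate(record.sequence, start=1):
        if res in CANDIDATE_RESIDUES:
            label = BINDING if pos in record.binding_sites else NON_BINDING
            sites.append(ResidueSite(record.id, pos, res, label))
    return sites


def extract_window(
    record: ProteinRecord, position: int, w: int = DEFAULT_FLANK
) -> Window:
    """Extract the ``2*w + 1`` context around a 1-based position.

    Positions outside the sequence contribute the padding symbol.
    """
    n = len(record.sequence)
    if not 1 <= position <= n:
        raise LoadError(f"{record.id}: position {position} outside [1, {n}]")
    chars = []
    for off in range(-w, w + 1):
        p = position + off
        chars.append(record.sequence[p - 1] if 1 <= p <= n else PAD)
    residue = record.sequence[position - 1]
    label = BINDING if position in record.binding_sites else NON_BINDING
    site = ResidueSite(record.id, position, residue, label)
    return Window(site=site, context="".join(chars), w=w)


def windows_for_sites(
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    w: int = DEFAULT_FLANK,
) -> list[Window]:
    """Windows for a list of sites, resolved against their records."""
    by_id = records if isinstance(records, dict) else {r.id: r for r in records}
    out = []
    for s in sites:
        if s.protein_id not in by_id:
            raise LoadError(f"no record loaded for site {s.protein_id}:{s.position}")
        out.append(extract_window(by_id[s.protein_id], s.position, w))
    return out
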