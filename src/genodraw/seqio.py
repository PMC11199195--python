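"""Annotated-sequence model and GenBank / FASTA input.

GenBank and FASTA files are read through Biopython and converted into a
small internal model (:class:`SequenceRecord`, :class:`Feature`).  All
internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention exists only at the file boundary.  A multi-record file yields
one :class:`SequenceRecord` per entry, in file order, so homologous or
unrelated sequences shipped together are handled as independent entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError, reverse_complement

from .errors import ParseError

__all__ = [
    "DisplayOptions",
    "Feature",
    "SequenceRecord",
    "parse_genbank",
    "parse_fasta",
    "load_sequences",
]

_IUPAC = set("ACGTURYSWKMBDHVN")


@dataclass
class DisplayOptions:
    """Per-sequence style overrides applied at draw time."""

    line_color: str = "#000000"
    line_width: float = 2.0
    label: str | None = None  # defaults to the record display_name
    reverse_complement: bool = False


@dataclass
class Feature:
    """One annotated region: type, location segments, strand, qualifiers.

    ``segments`` is an ordered list of 0-based half-open ``(start, end)``
    intervals; compound (``join``) locations have several segments.
    ``strand`` is +1 / -1 / 0 (unstranded).  ``qualifiers`` maps qualifier
    names (gene, product, locus_tag, note, ...) to lists of values, kept
    verbatim from the source file.
    """

    ftype: str
    segments: list[tuple[int, int]]
    strand: int = 1
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("feature must have at least one segment")
        for start, end in self.segments:
            if not 0 <= start < end:
                raise ValueError(f"invalid feature segment ({start}, {end})")
        self.segments = sorted((int(s), int(e)) for s, e in self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length_bp(self) -> int:
        return sum(e - s for s, e in self.segments)

    def qualifier_values(self, name: str) -> list[str]:
        """Values of one qualifier, or every value when ``name == 'any'``."""
        if name == "any":
            return [v for values in self.qualifiers.values() for v in values]
        return list(self.qualifiers.get(name, []))


@dataclass
class SequenceRecord:
    """One displayed sequence: residues (optional), features, display state."""

    record_id: str
    display_name: str
    length_bp: int
    residues: str | None = None
    features: list[Feature] = field(default_factory=list)
    active: bool = True
    source_file: str | None = None
    description: str = ""
    display_options: DisplayOptions = field(default_factory=DisplayOptions)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ParseError(f"record {self.record_id!r} has zero length")
        if self.residues is not None and len(self.residues) != self.length_bp:
            raise ValueError(
                f"record {self.record_id!r}: residue count "
                f"{len(self.residues)} != length_bp {self.length_bp}"
            )
        for feat in self.features:
            if feat.end > self.length_bp:
                raise ValueError(
                    f"feature {feat.ftype} [{feat.start}, {feat.end}) exceeds "
                    f"record {self.record_id!r} length {self.length_bp}"
                )

    def require_residues(self, operation: str) -> str:
        """Residue string, or a clear error for feature-only records."""
        if self.residues is None:
            raise ParseError(
                f"record {self.record_id!r} has no residues (feature-only "
                f"entry); {operation} requires the nucleotide sequence"
            )
        return self.residues

    def oriented_residues(self) -> str:
        """Residues in displayed orientation (honours reverse_complement)."""
        seq = self.require_residues("orientation-dependent analysis")
        if self.display_options.reverse_complement:
            return reverse_complement(seq)
        return seq

    def with_active(self, active: bool) -> "SequenceRecord":
        return replace(self, active=active)


def _convert_feature(biofeat) -> Feature | None:
    """Biopython SeqFeature -> internal Feature; ``source`` rows dropped."""
    if biofeat.type == "source":
        return None
    segments = [(int(part.start), int(part.end)) for part in biofeat.location.parts]
    segments = [(s, e) for s, e in segments if e > s]
    if not segments:
        return None
    strand = biofeat.location.strand
    qualifiers = {k: [str(v) for v in vals] for k, vals in biofeat.qualifiers.items()}
    return Feature(
        ftype=biofeat.type,
        segments=segments,
        strand=0 if strand is None else int(strand),
        qualifiers=qualifiers,
    )


def parse_genbank(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    Returns one :class:`SequenceRecord` per LOCUS entry, in file order.
    Coordinates are converted to 0-based half-open; ``join`` locations
    become multi-segment features (a location wrapping the origin of a
    circular sequence therefore arrives already split at the origin).
    Records whose sequence is not materialized (CONTIG-only entries) get
    ``residues=None`` and stay usable for feature drawing only.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read GenBank file: {path} does not exist")
    records: list[SequenceRecord] = []
    try:
        biorecords = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    if not biorecords:
        raise ParseError(f"no GenBank records found in {path}")
    for rec in biorecords:
        try:
            residues: str | None = str(rec.seq).upper()
        except UndefinedSequenceError:
            residues = None
        length = len(rec.seq)
        if length == 0:
            raise ParseError(f"record {rec.id!r} in {path} has zero length")
        features = [f for f in map(_convert_feature, rec.features) if f is not None]
        bad = [f for f in features if f.end > length]
        if bad:
            raise ParseError(
                f"record {rec.id!r} in {path}: feature at "
                f"[{bad[0].start}, {bad[0].end}) exceeds sequence length {length}"
            )
        records.append(
            SequenceRecord(
                record_id=rec.id,
                display_name=rec.id,
                length_bp=length,
                residues=residues,
                features=features,
                source_file=str(path),
                description=rec.description or "",
            )
        )
    return records


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a nucleotide FASTA file into feature-less records.

    The display name is the first whitespace-delimited header token; the
    full header is kept as the description.  Residues are uppercased.
    Characters outside the IUPAC nucleotide alphabet trigger a warning
    but are kept verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read FASTA file: {path} does not exist")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"record {rec.id!r} in {path} has zero length")
        alien = set(residues) - _IUPAC
        if alien:
            warnings.warn(
                f"record {rec.id!r} in {path} contains non-IUPAC characters "
                f"{sorted(alien)}; kept as-is",
                stacklevel=2,
            )
        records.append(
            SequenceRecord(
                record_id=rec.id,
                display_name=rec.id,
                length_bp=len(residues),
                residues=residues,
                source_file=str(path),
                description=rec.description or "",
            )
        )
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def load_sequences(path: str | Path) -> list[SequenceRecord]:
    """Dispatch on content: GenBank if the file starts with LOCUS, else FASTA."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read sequence file: {path} does not exist")
    with open(path) as fh:
        head = fh.read(64).lstrip()
    if head.startswith("LOCUS"):
        return parse_genbank(path)
    if head.startswith(">"):
        return parse_fasta(path)
    # fall back on the extension
    if path.suffix.lower() in {".gb", ".gbk", ".gbff"}:
        return parse_genbank(path)
    return parse_fasta(path)
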