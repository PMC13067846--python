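"""Sequence input/output and coordinate conventions.

All public coordinates in the toolkit are 1-based inclusive, matching the
way positions are reported in the ribozyme literature ("the GU site at
position 473").  Internally, Python slices are used; :class:`Region` owns
the conversion so that the 0-based representation never leaks.

DNA input (FASTA or GenBank) is silently normalised to the RNA alphabet
(T -> U) with the source alphabet recorded on the :class:`Transcript`, since
in vitro transcription workflows routinely mix DNA templates with RNA
products.  Ambiguity codes are rejected by default; with
``ambiguity="mask"`` they are kept as ``N`` and downstream scanners treat
masked positions as unpairable and never report them as cleavage sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import AlphabetError, CoordinateError, FormatError, MissingFeatureError

RNA_BASES = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

__all__ = [
    "Transcript",
    "Region",
    "read_fasta",
    "write_fasta",
    "extract_cds",
    "reverse_complement",
    "normalize_rna",
]


def normalize_rna(seq: str, ambiguity: str = "reject") -> str:
    """Uppercase, convert T to U, and enforce the RNA alphabet.

    ``ambiguity="reject"`` raises :class:`AlphabetError` on any character
    outside ACGU; ``ambiguity="mask"`` replaces non-ACGU IUPAC codes with N.
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES
    if not bad:
        return s
    if ambiguity == "mask":
        iupac = set("RYSWKMBDHVN")
        if bad - iupac:
            raise AlphabetError(f"illegal sequence characters: {sorted(bad - iupac)}")
        return "".join(c if c in RNA_BASES else "N" for c in s)
    raise AlphabetError(f"non-ACGU characters {sorted(bad)}; use ambiguity='mask' to keep them as N")


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence held internally as RNA.

    ``cds`` is an optional 1-based inclusive ``(start, end)`` interval in
    transcript coordinates; ``source_alphabet`` records whether the input
    was written as DNA or RNA so that FASTA output can restore it.
    """

    id: str
    sequence: str
    cds: Optional[tuple[int, int]] = None
    source_alphabet: str = "RNA"
    description: str = ""

    def __post_init__(self) -> None:
        if set(self.sequence) - (RNA_BASES | {"N"}):
            raise AlphabetError(f"transcript {self.id!r} holds non-normalised characters")
        if self.cds is not None:
            start, end = self.cds
            if not (1 <= start <= end <= len(self.sequence)):
                raise CoordinateError(
                    f"CDS {self.cds} outside transcript {self.id!r} of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_sequence(self) -> str:
        if self.cds is None:
            raise MissingFeatureError(f"transcript {self.id!r} has no CDS annotation")
        start, end = self.cds
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive interval on a transcript.

    ``frame`` declares whether coordinates count from the transcript 5' end
    (``"transcript"``) or from the first CDS base (``"cds"``).
    """

    transcript_id: str
    start: int
    end: int
    frame: str = "transcript"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(f"invalid region [{self.start}, {self.end}]")
        if self.frame not in ("transcript", "cds"):
            raise CoordinateError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def to_slice(self) -> slice:
        """Internal 0-based half-open representation."""
        return slice(self.start - 1, self.end)

    @classmethod
    def from_slice(cls, transcript_id: str, sl: slice, frame: str = "transcript") -> "Region":
        return cls(transcript_id, sl.start + 1, sl.stop, frame)


def read_fasta(path: str | Path, ambiguity: str = "reject") -> list[Transcript]:
    """Read a (multi-)FASTA file into normalised transcripts, order preserved.

    A record written as DNA (contains T, no U) is converted to RNA and its
    ``source_alphabet`` set to ``"DNA"``.  Malformed records raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _validate_fasta_lines(path)
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        alphabet = "DNA" if ("T" in raw.upper() or "U" not in raw.upper()) else "RNA"
        try:
            seq = normalize_rna(raw, ambiguity=ambiguity)
        except AlphabetError as exc:
            line = _find_bad_line(path, rec.id)
            raise FormatError(f"{path}:{line}: record {rec.id!r}: {exc}") from exc
        out.append(Transcript(id=rec.id, sequence=seq, source_alphabet=alphabet,
                              description=rec.description[len(rec.id):].strip()))
    return out


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if stripped.startswith(">"):
                seen_header = True
                if len(stripped) == 1:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
            elif not seen_header:
                raise FormatError(f"{path}:{lineno}: sequence data before any '>' header")


def _find_bad_line(path: Path, record_id: str) -> int:
    """Best-effort line number of the first illegal character in a record."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith(">"):
                in_record = stripped[1:].split()[0] == record_id if len(stripped) > 1 else False
                continue
            if in_record and (set(stripped.upper()) - set("ACGTUNRYSWKMBDHV")):
                return lineno
    return 0


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 60) -> None:
    """Write transcripts as FASTA, restoring T for records that came in as DNA."""
    with open(path, "w") as fh:
        for t in transcripts:
            seq = t.sequence.replace("U", "T") if t.source_alphabet == "DNA" else t.sequence
            header = f">{t.id}" + (f" {t.description}" if t.description else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_cds(path_or_record, index: Optional[int] = None,
                ambiguity: str = "reject") -> Transcript:
    """Extract the spliced CDS of a GenBank record as a transcript.

    ``path_or_record`` is a GenBank flat-file path or a parsed ``SeqRecord``.
    Minus-strand and joined CDS features are handled through the feature's
    own extraction logic (reverse-complemented, exons concatenated).  With
    several CDS features, ``index`` (0-based) must pick one.
    """
    if isinstance(path_or_record, (str, Path)):
        try:
            record = SeqIO.read(str(path_or_record), "genbank")
        except ValueError as exc:
            raise FormatError(f"cannot parse GenBank file {path_or_record}: {exc}") from exc
    else:
        record = path_or_record
    cds_features = [f for f in record.features if f.type == "CDS"]
    if not cds_features:
        raise MissingFeatureError(f"record {record.id!r} carries no CDS feature")
    if len(cds_features) > 1 and index is None:
        raise MissingFeatureError(
            f"record {record.id!r} carries {len(cds_features)} CDS features; specify index"
        )
    feature = cds_features[index or 0]
    spliced = str(feature.extract(record.seq))
    seq = normalize_rna(spliced, ambiguity=ambiguity)
    return Transcript(id=record.id, sequence=seq, cds=(1, len(seq)), source_alphabet="DNA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the RNA alphabet (N maps to N)."""
    if set(seq) - (RNA_BASES | {"N"}):
        raise AlphabetError(f"non-ACGU characters in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]
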