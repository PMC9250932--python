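"""Genomic intervals and coordinate-convention conversions.

Internally every interval is 0-based half-open (BED convention). Two external
dialects are supported at the boundary:

* ``GTF`` — 1-based, fully closed.  ``internal (s, e)`` <-> ``GTF (s+1, e)``.
* ``BED`` — identical to the internal convention.

Printed region strings of the form ``chr3:186788310-186788416`` are treated as
1-based fully closed, so that string denotes a 107-nt interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ConfigurationError, ParseError, ValidationError

STRANDS = ("+", "-", ".")

_REGION_RE = re.compile(r"^(?P<contig>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.contig,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand if self.strand == other.strand else ".",
        )

    def distance_to(self, pos: int) -> int:
        """Distance from ``pos`` to the closest base of the interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a printed ``contig:start-end`` region (1-based, fully closed).

    ``"chr3:186788310-186788416"`` yields an internal interval of length 107.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed region string: {text!r}")
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 < 1:
        raise ValidationError(f"region start must be >= 1, got {start1}")
    if start1 > end1:
        raise ValidationError(f"region start {start1} exceeds end {end1} in {text!r}")
    return GenomicInterval(m.group("contig"), start1 - 1, end1)


def interval_convert(iv: GenomicInterval, dialect: str) -> tuple[int, int]:
    """Emit the external (start, end) pair of ``iv`` in the given dialect."""
    if dialect == "GTF":
        return iv.start + 1, iv.end
    if dialect == "BED":
        return iv.start, iv.end
    raise ConfigurationError(f"unknown coordinate dialect {dialect!r}")


def interval_from_external(
    contig: str, start: int, end: int, dialect: str, strand: str = "."
) -> GenomicInterval:
    """Build an internal interval from external (start, end) in ``dialect``."""
    if dialect == "GTF":
        return GenomicInterval(contig, start - 1, end, strand)
    if dialect == "BED":
        return GenomicInterval(contig, start, end, strand)
    raise ConfigurationError(f"unknown coordinate dialect {dialect!r}")
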