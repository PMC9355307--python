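"""Backsplice-junction identity.

A circRNA is identified by the genomic endpoints of its backsplice junction
(BSJ): the non-linear 3'->5' splice joint that closes the circle.  Everything
downstream (count matrices, annotation, networks) is keyed on this identity.

Internal coordinates are 0-based half-open; conversions to and from caller
dialects (1-based inclusive tables, BED) happen only at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_STRANDS = ("+", "-", ".")
_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+.-])$")


@dataclass(frozen=True, order=True)
class BackspliceJunction:
    """A backsplice junction: ``chrom:start-end:strand`` (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got {self.start} >= {self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_key(cls, key: str) -> "BackspliceJunction":
        m = _KEY_RE.match(key)
        if m is None:
            raise ValueError(f"not a valid junction key: {key!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), m["strand"])

    def unstranded(self) -> "BackspliceJunction":
        """Collapse strand to '.' (callers disagree on strand more than coords)."""
        return BackspliceJunction(self.chrom, self.start, self.end, ".")


def parse_key(key: str) -> BackspliceJunction:
    """Parse ``chrom:start-end:strand`` into a :class:`BackspliceJunction`."""
    return BackspliceJunction.from_key(key)
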