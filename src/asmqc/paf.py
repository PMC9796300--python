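"""PAF alignment records.

A minimal typed view of Pairwise mApping Format rows: the 12 mandatory
columns, with query/target intervals 0-based half-open. Optional SAM-style
tags are ignored on input and not written on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment with PAF semantics."""

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_start: int
    target_end: int
    n_matches: int
    block_length: int
    mapq: int
    target_length: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.query_start < self.query_end <= self.query_length:
            raise ValueError(
                f"query interval [{self.query_start},{self.query_end}) invalid "
                f"for {self.query_id!r} of length {self.query_length}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.n_matches > self.block_length:
            raise ValueError("n_matches cannot exceed block_length")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0,255]")

    @property
    def identity(self) -> float:
        """Fraction of matching bases in the alignment block."""
        return self.n_matches / self.block_length if self.block_length else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def read_paf(path: str | Path) -> list[AlignmentHit]:
    """Parse a PAF file. Lines whose target is ``*`` (unmapped markers) are
    returned with ``target_id='*'`` and zeroed target coordinates."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >=12 columns, got {len(cols)}")
            try:
                hits.append(
                    AlignmentHit(
                        query_id=cols[0],
                        query_length=int(cols[1]),
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand=cols[4] if cols[4] in "+-" else "+",
                        target_id=cols[5],
                        target_length=int(cols[6]) if cols[6] != "*" else 0,
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        n_matches=int(cols[9]),
                        block_length=int(cols[10]),
                        mapq=int(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.query_length,
                        h.query_start,
                        h.query_end,
                        h.strand,
                        h.target_id,
                        h.target_length,
                        h.target_start,
                        h.target_end,
                        h.n_matches,
                        h.block_length,
                        h.mapq,
                    )
                )
                + "\n"
            )
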