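"""Assembly sequence handling and summary statistics.

This module owns the scaffold-level view of an assembly: FASTA input and
output (gzip-aware), the standard contiguity panel (total length, scaffold
and contig N50/L50, largest/mean/median scaffold, gap length, GC%), gap-run
manipulation, and the contaminant-cleanup rules (purge short hit-bearing
contigs, mask supported contaminant intervals, split or trim unsupported
ones, standardise unknown-size gaps to a fixed length).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# DNA alphabet accepted in assembly FASTA: canonical bases, N, and the
# IUPAC ambiguity codes (U tolerated and kept verbatim).
DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
_INVALID_RE = re.compile(r"[^ACGTUNRYSWKMBDHV]")

#: Contig break threshold: an N-run of at least this many bases splits a
#: scaffold into contigs. Ten is also the cap applied to gaps when building
#: redundancy-search copies of pseudodiploid scaffolds, so the two views of
#: "a real gap" agree by default.
DEFAULT_CONTIG_GAP_MIN = 10

#: Scaffolds shorter than this carrying any contaminant match are removed
#: outright during cleanup.
DEFAULT_MIN_PURGE_LEN = 5000

#: Unknown-size gaps are rewritten to exactly this many Ns.
DEFAULT_GAP_STD_LEN = 100


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One assembly scaffold (or contig): an id and its residues.

    Residues are stored upper-case. ``length`` is derived.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"invalid sequence id {self.id!r}")
        m = _INVALID_RE.search(self.residues)
        if m:
            raise FastaError(
                f"record {self.id!r}: residue {m.group()!r} at position "
                f"{m.start()} outside DNA alphabet"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AssemblyStats:
    """The standard assembly contiguity/composition panel.

    ``gap_length`` counts N residues; ``gc_percent`` is (G+C)/(A+C+G+T)x100
    with Ns and ambiguity codes excluded from both numerator and
    denominator, so gap standardisation cannot shift GC.
    """

    total_length: int
    num_scaffolds: int
    scaffold_n50: int
    scaffold_l50: int
    largest_scaffold: int
    mean_scaffold: float
    median_scaffold: float
    num_contigs: int
    contig_n50: int
    contig_l50: int
    gap_length: int
    gap_percent: float
    gc_percent: float

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "num_scaffolds": self.num_scaffolds,
            "scaffold_n50": self.scaffold_n50,
            "scaffold_l50": self.scaffold_l50,
            "largest_scaffold": self.largest_scaffold,
            "mean_scaffold": round(self.mean_scaffold, 1),
            "median_scaffold": round(self.median_scaffold),
            "num_contigs": self.num_contigs,
            "contig_n50": self.contig_n50,
            "contig_l50": self.contig_l50,
            "gap_length": self.gap_length,
            "gap_percent": round(self.gap_percent, 2),
            "gc_percent": round(self.gc_percent, 2),
        }


@dataclass(frozen=True)
class ContaminantAction:
    """A contaminant interval on a scaffold and the evidence available.

    ``has_spanning_support`` records whether long reads span the interval;
    supported intervals are masked in place, unsupported ones break the
    scaffold.
    """

    scaffold_id: str
    start: int
    end: int
    has_spanning_support: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.scaffold_id}"
            )


@dataclass(frozen=True)
class CleanupEvent:
    """One resolved cleanup action: what was done, to what, producing what."""

    scaffold_id: str
    action: str  # purge | mask | split | trim
    start: int | None
    end: int | None
    result_ids: tuple[str, ...]
    result_lengths: tuple[int, ...]


# ---------------------------------------------------------------------------
# FASTA I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    # fall back on magic bytes so .fa files that are secretly gzipped work
    if "r" in mode and path.exists():
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file into ``SequenceRecord`` objects.

    Residues are upper-cased; record order is preserved. Raises
    ``FastaError`` on an empty file, a duplicate id, or a residue outside
    the DNA alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA (gzipped when the path ends in .gz)."""
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gap runs and contigs


def n_runs(residues: str, min_run: int = 1) -> list[tuple[int, int]]:
    """0-based half-open intervals of N-runs of length >= min_run."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        (m.start(), m.end())
        for m in re.finditer(f"N{{{min_run},}}", residues)
    ]


def split_at_gaps(record: SequenceRecord, min_run: int = DEFAULT_CONTIG_GAP_MIN) -> list[int]:
    """Contig lengths of a scaffold, breaking at N-runs of >= min_run bases.

    Shorter N-runs stay inside a contig (and count toward its length);
    leading/trailing long runs yield no empty contigs.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    parts = re.split(f"N{{{min_run},}}", record.residues)
    return [len(p) for p in parts if p]


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """N50 and L50 of a length multiset.

    N50 is the length of the shortest sequence in the minimal set of longest
    sequences whose summed length reaches at least half the total; L50 is
    the size of that set. A prefix landing exactly on half qualifies.
    """
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for i, n in enumerate(ordered):
        acc += n
        if acc >= half:
            return n, i + 1
    raise AssertionError("unreachable")


def assembly_stats(
    records: Sequence[SequenceRecord],
    contig_gap_min: int = DEFAULT_CONTIG_GAP_MIN,
) -> AssemblyStats:
    """Compute the full contiguity/composition panel for an assembly.

    Contigs are obtained by :func:`split_at_gaps` with ``contig_gap_min``;
    ``gap_length`` counts every N residue regardless of run length.
    """
    if not records:
        raise ValueError("assembly_stats requires at least one record")
    if contig_gap_min < 1:
        raise ValueError("contig_gap_min must be >= 1")

    scaf_lengths = [r.length for r in records]
    total = sum(scaf_lengths)
    s_n50, s_l50 = n50_l50(scaf_lengths)

    contig_lengths: list[int] = []
    gap = 0
    gc = 0
    atgc = 0
    for r in records:
        contig_lengths.extend(split_at_gaps(r, contig_gap_min))
        seq = r.residues
        gap += seq.count("N")
        g = seq.count("G")
        c = seq.count("C")
        gc += g + c
        atgc += g + c + seq.count("A") + seq.count("T")
    if contig_lengths:
        c_n50, c_l50 = n50_l50(contig_lengths)
    else:  # all-N assembly
        c_n50, c_l50 = 0, 0

    return AssemblyStats(
        total_length=total,
        num_scaffolds=len(records),
        scaffold_n50=s_n50,
        scaffold_l50=s_l50,
        largest_scaffold=max(scaf_lengths),
        mean_scaffold=total / len(records),
        median_scaffold=statistics.median(scaf_lengths),
        num_contigs=len(contig_lengths),
        contig_n50=c_n50,
        contig_l50=c_l50,
        gap_length=gap,
        gap_percent=100.0 * gap / total if total else 0.0,
        gc_percent=100.0 * gc / atgc if atgc else 0.0,
    )


def standardize_gaps(
    record: SequenceRecord,
    unknown_runs: Sequence[tuple[int, int]],
    std_len: int = DEFAULT_GAP_STD_LEN,
) -> SequenceRecord:
    """Rewrite the listed unknown-size N-runs to exactly ``std_len`` Ns.

    Which gaps are "of unknown size" is evidence the assembly itself does
    not carry, so the caller must list them; every other residue is
    untouched. Raises if a listed interval is not entirely N.
    """
    if std_len < 1:
        raise ValueError("std_len must be >= 1")
    runs = sorted(unknown_runs)
    for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
        if e0 > s1:
            raise ValueError(f"overlapping gap intervals [{s0},{e0}) and [{s1},{e1})")
    seq = record.residues
    out: list[str] = []
    prev = 0
    for s, e in runs:
        if not 0 <= s < e <= len(seq):
            raise ValueError(f"interval [{s},{e}) outside record {record.id!r}")
        if set(seq[s:e]) != {"N"}:
            raise ValueError(
                f"interval [{s},{e}) on {record.id!r} is not entirely N"
            )
        out.append(seq[prev:s])
        out.append("N" * std_len)
        prev = e
    out.append(seq[prev:])
    return SequenceRecord(id=record.id, residues="".join(out))


# ---------------------------------------------------------------------------
# Contaminant cleanup


def purge_contaminants(
    records: Sequence[SequenceRecord],
    actions: Sequence[ContaminantAction],
    min_purge_len: int = DEFAULT_MIN_PURGE_LEN,
) -> tuple[list[SequenceRecord], list[CleanupEvent]]:
    """Apply contaminant-cleanup rules and report every action taken.

    Rules, per scaffold carrying at least one contaminant interval:

    * shorter than ``min_purge_len`` -> the whole scaffold is purged;
    * otherwise each supported interval (spanning long reads) is masked to
      Ns in place, and each unsupported interval breaks the scaffold —
      split into two pieces when interior, trimmed when it touches an end.

    Split pieces are renamed ``<id>.1``, ``<id>.2``, ... left to right.
    Returns the cleaned records (input order preserved) and the event log.
    """
    by_id = {r.id: r for r in records}
    per_scaffold: dict[str, list[ContaminantAction]] = {}
    for a in actions:
        if a.scaffold_id not in by_id:
            raise KeyError(f"contaminant action references unknown scaffold {a.scaffold_id!r}")
        if a.end > by_id[a.scaffold_id].length:
            raise ValueError(
                f"interval [{a.start},{a.end}) exceeds scaffold {a.scaffold_id!r} "
                f"length {by_id[a.scaffold_id].length}"
            )
        per_scaffold.setdefault(a.scaffold_id, []).append(a)

    cleaned: list[SequenceRecord] = []
    events: list[CleanupEvent] = []
    for rec in records:
        acts = per_scaffold.get(rec.id)
        if not acts:
            cleaned.append(rec)
            continue
        if rec.length < min_purge_len:
            events.append(CleanupEvent(rec.id, "purge", None, None, (), ()))
            continue

        # masking first, then breaks: both operate on the same original
        # coordinates, so order between the two phases does not matter
        seq = list(rec.residues)
        for a in acts:
            if a.has_spanning_support:
                seq[a.start : a.end] = "N" * (a.end - a.start)
                events.append(
                    CleanupEvent(rec.id, "mask", a.start, a.end, (rec.id,), (rec.length,))
                )
        breaks = sorted((a for a in acts if not a.has_spanning_support), key=lambda a: a.start)
        if not breaks:
            cleaned.append(SequenceRecord(id=rec.id, residues="".join(seq)))
            continue

        pieces: list[tuple[int, int]] = []
        prev = 0
        for a in breaks:
            if a.start > prev:
                pieces.append((prev, a.start))
            prev = max(prev, a.end)
        if prev < rec.length:
            pieces.append((prev, rec.length))
        touches_end = breaks[0].start == 0 or breaks[-1].end == rec.length
        if len(pieces) == 1:
            new = SequenceRecord(id=rec.id, residues="".join(seq[pieces[0][0] : pieces[0][1]]))
            cleaned.append(new)
            a = breaks[0]
            events.append(CleanupEvent(rec.id, "trim", a.start, a.end, (new.id,), (new.length,)))
        else:
            new_recs = [
                SequenceRecord(id=f"{rec.id}.{i + 1}", residues="".join(seq[s:e]))
                for i, (s, e) in enumerate(pieces)
            ]
            cleaned.extend(new_recs)
            action = "trim" if touches_end and len(breaks) == 1 else "split"
            for a in breaks:
                events.append(
                    CleanupEvent(
                        rec.id,
                        "split" if 0 < a.start and a.end < rec.length else "trim",
                        a.start,
                        a.end,
                        tuple(r.id for r in new_recs),
                        tuple(r.length for r in new_recs),
                    )
                )
    return cleaned, events
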