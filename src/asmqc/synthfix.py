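"""Deterministic synthetic fixtures with known ground truth.

Every consumer module in this package can be exercised offline: this
module fabricates assemblies with genes planted at known coordinates and
intended completeness ratings, pseudodiploid haplotig pairs with a chosen
divergence, exact alignment hits for the planted material, and paired
annotation/reference proteomes with hit tables constructed to realise a
chosen truncation and duplication structure — together with expected
results computed by definition-level brute force, independent of the
modules under test.

All randomness flows from a single integer seed, split into one named
stream per output kind, so adding a new output kind never perturbs
existing fixtures. Residues are drawn i.i.d. at the target GC (about 42%,
typical of avian genomes); no repeat structure is simulated, so these
fixtures say nothing about repeat-driven misassembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .paf import AlignmentHit
from .saaga import ProteinRecord, SearchHit
from .seqstats import SequenceRecord

_STREAMS = {
    "assembly": 1,
    "genes": 2,
    "placement": 3,
    "pseudodiploid": 4,
    "proteome": 5,
}

RATINGS = ("Complete", "Duplicated", "Fragmented", "Partial", "Ghost", "Missing")

#: Planted coverage fractions by intended rating. Fragmented plants two
#: overlapping 55% pieces on different scaffolds (union = 100%, no single
#: scaffold >= 95%); Partial plants 60%, Ghost 30%.
_FRAG_PIECE = 0.55
_PARTIAL_FRAC = 0.60
_GHOST_FRAC = 0.30


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of a synthetic study; all randomness flows from ``seed``."""

    seed: int = 0
    n_scaffolds: int = 6
    scaffold_length_range: tuple[int, int] = (20_000, 40_000)
    gaps_per_scaffold: int = 2
    gap_run_range: tuple[int, int] = (10, 120)
    gc_target: float = 0.42
    #: (gene_id, length, intended rating); empty -> a default plan of
    #: ``n_genes`` genes cycling through all six ratings.
    gene_plan: tuple[tuple[str, int, str], ...] = ()
    n_genes: int = 18
    snp_rate: float = 0.01
    hap2_shorten_frac: float = 0.05
    truncation_q: float = 1.0
    duplication_factor: int = 1
    unhit_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if not 0 <= self.snp_rate < 1:
            raise ValueError("snp_rate must be in [0,1)")
        if not 0 < self.truncation_q <= 1:
            raise ValueError("truncation_q must be in (0,1]")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")


@dataclass(frozen=True)
class PlantedSegment:
    """One placed piece of a planted gene."""

    gene_id: str
    scaffold_id: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int


@dataclass
class AssemblyTruth:
    """Ground truth accompanying a synthetic assembly."""

    gene_lengths: dict[str, int]
    gene_sequences: dict[str, str]
    intended_ratings: dict[str, str]
    segments: list[PlantedSegment]
    scaffold_lengths: dict[str, int]
    expected_stats: dict


def _rng(spec: TruthSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), _STREAMS[stream]])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def default_gene_plan(n_genes: int) -> tuple[tuple[str, int, str], ...]:
    """Cycle the six intended ratings across ``n_genes`` genes of varied
    length (first gene Complete, second Duplicated, and so on)."""
    plan = []
    for i in range(n_genes):
        rating = RATINGS[i % len(RATINGS)]
        length = 900 + 137 * (i % 7)
        plan.append((f"gene{i:04d}", length, rating))
    return tuple(plan)


# ---------------------------------------------------------------------------
# Assemblies with planted genes


def make_assembly(spec: TruthSpec) -> tuple[list[SequenceRecord], AssemblyTruth]:
    """Build an assembly with genes planted per the spec's plan.

    Each scaffold is background sequence at the target GC with the planted
    pieces inserted at recorded coordinates and N-run gaps dropped into the
    background between them. The truth carries the expected rating of every
    gene and an expected statistics panel computed here by brute force.
    """
    plan = spec.gene_plan or default_gene_plan(spec.n_genes)
    rng_bg = _rng(spec, "assembly")
    rng_genes = _rng(spec, "genes")
    rng_place = _rng(spec, "placement")

    gene_seqs = {g: _random_bases(rng_genes, length, spec.gc_target) for g, length, _ in plan}
    gene_lengths = {g: length for g, length, _ in plan}
    intended = {g: r for g, _, r in plan}

    # assign planting events to scaffolds round-robin
    events: list[list[tuple[str, int, int]]] = [[] for _ in range(spec.n_scaffolds)]
    cursor = 0

    def next_scaffold(exclude: int | None = None) -> int:
        nonlocal cursor
        while True:
            idx = cursor % spec.n_scaffolds
            cursor += 1
            if idx != exclude:
                return idx

    for g, length, rating in plan:
        if rating == "Missing":
            continue
        if rating in ("Duplicated", "Fragmented") and spec.n_scaffolds < 2:
            raise ValueError(f"{rating} planting needs >= 2 scaffolds")
        if rating == "Complete":
            events[next_scaffold()].append((g, 0, length))
        elif rating == "Duplicated":
            a = next_scaffold()
            b = next_scaffold(exclude=a)
            events[a].append((g, 0, length))
            events[b].append((g, 0, length))
        elif rating == "Fragmented":
            if spec.n_scaffolds < 2:
                raise ValueError("Fragmented planting needs >= 2 scaffolds")
            piece = int(np.ceil(_FRAG_PIECE * length))
            a = next_scaffold()
            b = next_scaffold(exclude=a)
            events[a].append((g, 0, piece))
            events[b].append((g, length - piece, length))
        elif rating == "Partial":
            events[next_scaffold()].append((g, 0, int(round(_PARTIAL_FRAC * length))))
        elif rating == "Ghost":
            events[next_scaffold()].append((g, 0, int(round(_GHOST_FRAC * length))))
        else:
            raise ValueError(f"unknown intended rating {rating!r}")

    lo, hi = spec.scaffold_length_range
    targets = rng_bg.integers(lo, hi + 1, size=spec.n_scaffolds)
    records: list[SequenceRecord] = []
    segments: list[PlantedSegment] = []
    for i in range(spec.n_scaffolds):
        sid = f"scaffold{i:03d}"
        parts: list[str] = []
        pos = 0
        for g, qs, qe in events[i]:
            spacer = int(rng_place.integers(300, 1200))
            parts.append(_random_bases(rng_bg, spacer, spec.gc_target))
            pos += spacer
            piece = gene_seqs[g][qs:qe]
            segments.append(PlantedSegment(g, sid, pos, pos + len(piece), qs, qe))
            parts.append(piece)
            pos += len(piece)
        pad = max(int(targets[i]) - pos, 600)
        tail = _random_bases(rng_bg, pad, spec.gc_target)
        # drop N-run gaps into the tail padding only, never into genes
        tail_list = list(tail)
        for _ in range(spec.gaps_per_scaffold):
            run = int(rng_place.integers(*spec.gap_run_range))
            if run + 2 >= len(tail_list):
                break
            at = int(rng_place.integers(1, len(tail_list) - run - 1))
            tail_list[at : at + run] = "N" * run
        parts.append("".join(tail_list))
        records.append(SequenceRecord(id=sid, residues="".join(parts)))

    truth = AssemblyTruth(
        gene_lengths=gene_lengths,
        gene_sequences=gene_seqs,
        intended_ratings=intended,
        segments=segments,
        scaffold_lengths={r.id: r.length for r in records},
        expected_stats=_bruteforce_stats(records),
    )
    return records, truth


def _bruteforce_stats(records: Sequence[SequenceRecord]) -> dict:
    """Plain-loop statistics used as the generator-side expectation."""
    lengths = sorted((r.length for r in records), reverse=True)
    total = sum(lengths)
    acc, n50, l50 = 0, 0, 0
    for i, n in enumerate(lengths):
        acc += n
        if acc * 2 >= total:
            n50, l50 = n, i + 1
            break
    gap = sum(r.residues.count("N") for r in records)
    gc = sum(r.residues.count("G") + r.residues.count("C") for r in records)
    atgc = gc + sum(r.residues.count("A") + r.residues.count("T") for r in records)
    return {
        "total_length": total,
        "num_scaffolds": len(records),
        "scaffold_n50": n50,
        "scaffold_l50": l50,
        "largest_scaffold": lengths[0],
        "gap_length": gap,
        "gc_percent": 100.0 * gc / atgc if atgc else 0.0,
    }


def make_alignments(truth: AssemblyTruth) -> list[AlignmentHit]:
    """Exact PAF-semantics hits for every planted segment (identity 1,
    mapq 60)."""
    hits = []
    for seg in truth.segments:
        span = seg.query_end - seg.query_start
        hits.append(
            AlignmentHit(
                query_id=seg.gene_id,
                query_length=truth.gene_lengths[seg.gene_id],
                query_start=seg.query_start,
                query_end=seg.query_end,
                strand="+",
                target_id=seg.scaffold_id,
                target_length=truth.scaffold_lengths[seg.scaffold_id],
                target_start=seg.target_start,
                target_end=seg.target_end,
                n_matches=span,
                block_length=span,
                mapq=60,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Pseudodiploid fixtures


@dataclass
class PseudodiploidTruth:
    expected_primary: dict[str, str]  # base name -> scaffold id
    identical_pairs: set[str]  # base names whose haplotigs are byte-identical


def make_pseudodiploid(
    spec: TruthSpec,
    include_allN: bool = False,
) -> tuple[list[SequenceRecord], list[AlignmentHit], PseudodiploidTruth]:
    """Paired ``<base>.1``/``<base>.2`` haplotigs plus containment evidence.

    Haplotig 2 is haplotig 1 with substitutions at ``snp_rate`` and its
    tail truncated by ``hap2_shorten_frac``. With both at zero the pairs
    are byte-identical and full mutual containment hits are emitted, so the
    redundancy step collapses each pair; otherwise no containment evidence
    exists and the pair survives to be split longer/shorter.
    """
    if spec.n_scaffolds < 1:
        raise ValueError("need at least one scaffold pair")
    rng = _rng(spec, "pseudodiploid")
    records: list[SequenceRecord] = []
    hits: list[AlignmentHit] = []
    expected_primary: dict[str, str] = {}
    identical: set[str] = set()
    bases = "ACGT"
    for i in range(spec.n_scaffolds):
        base = f"hap{i:03d}"
        length = int(rng.integers(*spec.scaffold_length_range))
        hap1 = _random_bases(rng, length, spec.gc_target)
        hap2_list = list(hap1)
        if spec.snp_rate > 0:
            n_mut = rng.binomial(length, spec.snp_rate)
            for at in rng.choice(length, size=n_mut, replace=False):
                cur = hap2_list[at]
                hap2_list[at] = bases[(bases.index(cur) + 1 + int(rng.integers(0, 3))) % 4]
        hap2 = "".join(hap2_list)
        if spec.hap2_shorten_frac > 0:
            hap2 = hap2[: int(round(length * (1 - spec.hap2_shorten_frac)))]
        id1, id2 = f"{base}.1", f"{base}.2"
        records.append(SequenceRecord(id=id1, residues=hap1))
        records.append(SequenceRecord(id=id2, residues=hap2))
        if hap1 == hap2:
            identical.add(base)
            for q, t in ((id1, id2), (id2, id1)):
                hits.append(
                    AlignmentHit(
                        query_id=q, query_length=length, query_start=0, query_end=length,
                        strand="+", target_id=t, target_length=length,
                        target_start=0, target_end=length,
                        n_matches=length, block_length=length, mapq=60,
                    )
                )
            expected_primary[base] = id1  # lexicographically smaller survives
        else:
            expected_primary[base] = id1 if len(hap1) >= len(hap2) else id2
    if include_allN:
        records.append(SequenceRecord(id="junk.1", residues="N" * 500))
    return records, hits, PseudodiploidTruth(expected_primary, identical)


# ---------------------------------------------------------------------------
# Proteome pairs for the annotation-metric panel


@dataclass
class ProteomePair:
    annotation: list[ProteinRecord]
    reference: list[ProteinRecord]
    fwd_hits: list[SearchHit]
    rev_hits: list[SearchHit]
    expected: dict[str, float]


def make_proteome_pair(spec: TruthSpec) -> ProteomePair:
    """Annotation/reference proteomes with hit tables realising a known
    truncation (``truncation_q``) and duplication (``duplication_factor``)
    structure.

    Each reference gene yields ``duplication_factor`` annotated genes whose
    protein is the first ``truncation_q`` of the reference; a leading
    ``unhit_frac`` share of annotated genes is withheld from both hit
    tables. Expected metrics are recomputed here from the constructed
    tables by definition-level brute force, independent of the metric
    module.
    """
    rng = _rng(spec, "proteome")
    n = spec.n_genes
    # lengths are multiples of 4 so quarter-fraction truncations are exact
    reference = [
        ProteinRecord(f"ref{i:04d}", f"ref{i:04d}", 4 * int(rng.integers(30, 150)))
        for i in range(n)
    ]
    annotation: list[ProteinRecord] = []
    fwd: list[SearchHit] = []
    rev: list[SearchHit] = []
    n_unhit = int(round(spec.unhit_frac * n))
    for i, ref in enumerate(reference):
        plen = max(int(round(spec.truncation_q * ref.length)), 1)
        for c in range(spec.duplication_factor):
            gid = f"gene{i:04d}c{c}"
            pid = f"{gid}.p1"
            annotation.append(ProteinRecord(pid, gid, plen))
            if i < n_unhit:
                continue
            fwd.append(
                SearchHit(pid, ref.protein_id, 0, plen, 0, plen, 2.0 * plen, 1e-100)
            )
            rev.append(
                SearchHit(ref.protein_id, pid, 0, plen, 0, plen, 2.0 * plen, 1e-100)
            )
    expected = _expected_metrics(annotation, reference, fwd, rev)
    return ProteomePair(annotation, reference, fwd, rev, expected)


def _expected_metrics(
    annotation: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    fwd: Sequence[SearchHit],
    rev: Sequence[SearchHit],
) -> dict[str, float]:
    """Brute-force evaluation of the metric definitions on explicit hit
    tables: naive loops, no shared code with the metric module."""
    ref_len = {p.protein_id: p.length for p in reference}

    def naive_best(hits: Sequence[SearchHit], query: str) -> SearchHit | None:
        mine = [h for h in hits if h.query_id == query]
        best = None
        for h in mine:
            if (
                best is None
                or h.bitscore > best.bitscore
                or (h.bitscore == best.bitscore and h.evalue < best.evalue)
                or (
                    h.bitscore == best.bitscore
                    and h.evalue == best.evalue
                    and h.target_id < best.target_id
                )
            ):
                best = h
        return best

    def naive_union(ivs: list[tuple[int, int]], length: int) -> float:
        mask = [False] * length
        for s, e in ivs:
            for k in range(s, min(e, length)):
                mask[k] = True
        return sum(mask) / length

    fwd_best = {p.protein_id: naive_best(fwd, p.protein_id) for p in annotation}
    fwd_best = {q: h for q, h in fwd_best.items() if h is not None}
    rev_best = {p.protein_id: naive_best(rev, p.protein_id) for p in reference}
    rev_best = {q: h for q, h in rev_best.items() if h is not None}

    n_genes = len(annotation)
    ratios, f1s, protcovs = [], [], []
    rbh = 0
    for p in annotation:
        bh = fwd_best.get(p.protein_id)
        if bh is None:
            protcovs.append(0.0)
            continue
        pair = [h for h in fwd if h.query_id == p.protein_id and h.target_id == bh.target_id]
        protcov = naive_union([(h.query_start, h.query_end) for h in pair], p.length)
        refcov = naive_union(
            [(h.target_start, h.target_end) for h in pair], ref_len[bh.target_id]
        )
        protcovs.append(protcov)
        ratios.append(p.length / ref_len[bh.target_id])
        f1s.append(2 * protcov * refcov / (protcov + refcov) if protcov + refcov else 0.0)
        back = rev_best.get(bh.target_id)
        if back is not None and back.target_id == p.protein_id:
            rbh += 1

    ref_covs = []
    for r in reference:
        bh = rev_best.get(r.protein_id)
        if bh is None:
            ref_covs.append(0.0)
            continue
        pair = [h for h in rev if h.query_id == r.protein_id and h.target_id == bh.target_id]
        ref_covs.append(naive_union([(h.query_start, h.query_end) for h in pair], r.length))

    mean = lambda xs: sum(xs) / len(xs) if xs else 0.0
    distinct_refs = {h.target_id for h in fwd_best.values()}
    top_rev = {h.target_id for h in rev_best.values()}
    return {
        "mean_protein_length_ratio": mean(ratios),
        "mean_f1": mean(f1s),
        "completeness": 100.0 * mean(ref_covs),
        "purity": 100.0 * mean(protcovs),
        "homology": 100.0 * len(fwd_best) / n_genes,
        "orthology": 100.0 * rbh / n_genes,
        "duplicity": len(fwd_best) / len(distinct_refs) if distinct_refs else 0.0,
        "compression": len(top_rev) / len(rev_best) if rev_best else 0.0,
        "multiplicity": n_genes / len(reference),
    }
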