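"""Annotation assessment from reciprocal homology searches.

Given a predicted proteome, a trusted reference proteome, and tabular
homology hits in both directions (annotation->reference "forward" and
reference->annotation "reverse"), this module computes a panel of nine
summary scores describing how faithful the annotation is:

* **mean protein length ratio** — annotated length / best-reference length,
  averaged over annotated genes with a hit; < 1 indicates truncation.
* **mean F1** — harmonic mean of PROTCOV (fraction of the annotated
  protein covered by its best reference hit) and REFCOV (fraction of that
  reference covered), averaged over genes with a hit.
* **completeness** — mean covered fraction of reference proteins (0 for
  unhit ones), x100.
* **purity** — mean PROTCOV over all annotated genes (0 when unhit), x100.
* **homology** — % of annotated genes with any forward hit.
* **orthology** — % of annotated genes in a reciprocal best-hit pair.
* **duplicity** — mean number of annotated genes sharing the same best
  reference hit.
* **compression** — unique annotated genes that are the top reverse hit of
  some reference protein / reference proteins with any reverse hit.
* **multiplicity** — annotated genes / reference proteins.

Gene-level scoring collapses the annotation to one representative protein
per gene, the longest isoform, so the homology/orthology denominators
count genes rather than transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its parent gene and length in amino acids."""

    protein_id: str
    gene_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"protein {self.protein_id!r}: length must be positive")


@dataclass(frozen=True)
class SearchHit:
    """One homology-search hit (coordinates 0-based half-open, aa)."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end or self.target_start >= self.target_end:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: empty or inverted interval"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class SaagaMetrics:
    mean_protein_length_ratio: float
    mean_f1: float
    completeness: float
    purity: float
    homology: float
    orthology: float
    duplicity: float
    compression: float
    multiplicity: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mean_protein_length_ratio": self.mean_protein_length_ratio,
            "mean_f1": self.mean_f1,
            "completeness": self.completeness,
            "purity": self.purity,
            "homology": self.homology,
            "orthology": self.orthology,
            "duplicity": self.duplicity,
            "compression": self.compression,
            "multiplicity": self.multiplicity,
        }


# ---------------------------------------------------------------------------
# Input parsing


def parse_hit_table(path: str | Path) -> list[SearchHit]:
    """Parse a 12-column tabular homology hit file (BLAST outfmt-6 / m8).

    Columns: query, target, pident, alnlen, mismatch, gapopen, qstart,
    qend, tstart, tend, evalue, bitscore. Coordinates are 1-based inclusive
    on disk and converted to 0-based half-open.
    """
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                hits.append(
                    SearchHit(
                        query_id=cols[0],
                        target_id=cols[1],
                        query_start=int(cols[6]) - 1,
                        query_end=int(cols[7]),
                        target_start=int(cols[8]) - 1,
                        target_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_membership_tsv(path: str | Path) -> dict[str, str]:
    """protein_id -> gene_id from a 2-column TSV."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if cols[0] in mapping:
                raise ValueError(f"{path}:{lineno}: protein {cols[0]!r} listed twice")
            mapping[cols[0]] = cols[1]
    return mapping


def read_membership_gff3(path: str | Path) -> dict[str, str]:
    """protein_id -> gene_id from a GFF3, using mRNA Parent relations.

    Protein ids are taken to equal mRNA ids, the common convention when a
    proteome FASTA is extracted from an annotation.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    mapping: dict[str, str] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = [p.id for p in db.parents(mrna, featuretype="gene")]
        mapping[mrna.id] = parents[0] if parents else mrna.id
    return mapping


# ---------------------------------------------------------------------------
# Best-hit bookkeeping


def best_hit(hits: Sequence[SearchHit]) -> SearchHit:
    """Best hit for one query: max bitscore, ties broken by minimum evalue,
    then lexicographically smallest target id — fully deterministic."""
    if not hits:
        raise ValueError("best_hit requires at least one hit")
    return sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.target_id))[0]


def best_hits_by_query(hits: Iterable[SearchHit]) -> dict[str, SearchHit]:
    grouped: dict[str, list[SearchHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return {q: best_hit(hs) for q, hs in grouped.items()}


def reciprocal_best(
    fwd_best: Mapping[str, SearchHit],
    rev_best: Mapping[str, SearchHit],
) -> set[tuple[str, str]]:
    """Reciprocal best-hit pairs: (g, r) iff best(g) = r and best(r) = g."""
    pairs = set()
    for g, hit in fwd_best.items():
        r = hit.target_id
        back = rev_best.get(r)
        if back is not None and back.target_id == g:
            pairs.add((g, r))
    return pairs


def f1(protcov: float, refcov: float) -> float:
    """Harmonic mean of the two coverage fractions; 0 when both are 0."""
    for v in (protcov, refcov):
        if not 0 <= v <= 1:
            raise ValueError(f"coverage fraction {v} outside [0,1]")
    s = protcov + refcov
    return 2 * protcov * refcov / s if s else 0.0


def _union(intervals: list[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total, cur_s, cur_e = 0, None, 0
    for s, e in ivs:
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def coverage_fractions(
    protein: ProteinRecord,
    reference: ProteinRecord,
    pair_hits: Sequence[SearchHit],
) -> tuple[float, float]:
    """(PROTCOV, REFCOV) between a protein and its best reference.

    All HSPs between the pair contribute — split-domain alignments are
    common, and the best HSP alone understates coverage.
    """
    q_ivs: list[tuple[int, int]] = []
    t_ivs: list[tuple[int, int]] = []
    for h in pair_hits:
        if h.query_id != protein.protein_id or h.target_id != reference.protein_id:
            raise ValueError(
                f"hit {h.query_id}->{h.target_id} does not belong to pair "
                f"({protein.protein_id}, {reference.protein_id})"
            )
        if h.query_end > protein.length:
            raise ValueError(
                f"query interval end {h.query_end} exceeds protein length {protein.length}"
            )
        if h.target_end > reference.length:
            raise ValueError(
                f"target interval end {h.target_end} exceeds reference length {reference.length}"
            )
        q_ivs.append((h.query_start, h.query_end))
        t_ivs.append((h.target_start, h.target_end))
    return _union(q_ivs) / protein.length, _union(t_ivs) / reference.length


def longest_isoform(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One representative protein per gene: the longest isoform, ties broken
    by lexicographically smallest protein id (so 'p10' beats 'p2')."""
    by_gene: dict[str, ProteinRecord] = {}
    for p in proteins:
        cur = by_gene.get(p.gene_id)
        if (
            cur is None
            or p.length > cur.length
            or (p.length == cur.length and p.protein_id < cur.protein_id)
        ):
            by_gene[p.gene_id] = p
    return [by_gene[g] for g in sorted(by_gene)]


# ---------------------------------------------------------------------------
# The metric panel


def saaga_metrics(
    annotation: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    fwd_hits: Sequence[SearchHit],
    rev_hits: Sequence[SearchHit],
    gene_level: bool = True,
) -> tuple[SaagaMetrics, pd.DataFrame]:
    """Compute the nine-score panel plus a per-gene detail table.

    Forward hits run annotation -> reference, reverse hits the other way.
    With ``gene_level`` the annotation is first collapsed to its longest
    isoform per gene. Returns (metrics, per-gene table with columns gene,
    protein, best_ref, protcov, refcov, f1, length_ratio, status).
    """
    if not annotation or not reference:
        raise ValueError("annotation and reference must both be non-empty")

    reps = longest_isoform(annotation) if gene_level else list(annotation)
    rep_ids = {p.protein_id for p in reps}
    ann_by_pid = {p.protein_id: p for p in reps}
    ref_by_pid = {p.protein_id: p for p in reference}

    fwd = [h for h in fwd_hits if h.query_id in rep_ids]
    for h in fwd:
        if h.target_id not in ref_by_pid:
            raise KeyError(f"forward hit targets unknown reference {h.target_id!r}")
    rev = [h for h in rev_hits if h.target_id in rep_ids or not gene_level]
    for h in rev_hits:
        if h.query_id not in ref_by_pid:
            raise KeyError(f"reverse hit from unknown reference {h.query_id!r}")

    fwd_best = best_hits_by_query(fwd)
    rev_best = best_hits_by_query(rev)
    rbh = reciprocal_best(fwd_best, rev_best)
    rbh_genes = {g for g, _ in rbh}

    fwd_pairs: dict[tuple[str, str], list[SearchHit]] = {}
    for h in fwd:
        fwd_pairs.setdefault((h.query_id, h.target_id), []).append(h)
    rev_pairs: dict[tuple[str, str], list[SearchHit]] = {}
    for h in rev:
        rev_pairs.setdefault((h.query_id, h.target_id), []).append(h)

    n_genes = len(reps)
    n_ref = len(reference)
    rows = []
    length_ratios: list[float] = []
    f1s: list[float] = []
    protcovs_all: list[float] = []  # every gene, 0 when unhit

    for p in reps:
        bh = fwd_best.get(p.protein_id)
        if bh is None:
            protcovs_all.append(0.0)
            rows.append(
                {
                    "gene": p.gene_id,
                    "protein": p.protein_id,
                    "best_ref": None,
                    "protcov": 0.0,
                    "refcov": 0.0,
                    "f1": 0.0,
                    "length_ratio": float("nan"),
                    "status": "unknown",
                }
            )
            continue
        ref = ref_by_pid[bh.target_id]
        protcov, refcov = coverage_fractions(
            p, ref, fwd_pairs[(p.protein_id, bh.target_id)]
        )
        protcov = min(protcov, 1.0)
        refcov = min(refcov, 1.0)
        length_ratios.append(p.length / ref.length)
        f1s.append(f1(protcov, refcov))
        protcovs_all.append(protcov)
        rows.append(
            {
                "gene": p.gene_id,
                "protein": p.protein_id,
                "best_ref": ref.protein_id,
                "protcov": protcov,
                "refcov": refcov,
                "f1": f1s[-1],
                "length_ratio": length_ratios[-1],
                "status": "known",
            }
        )

    # completeness: per reference protein, covered fraction against its best
    # reverse-search hit (0 when it has no reverse hit)
    ref_cov_all: list[float] = []
    for ref in reference:
        bh = rev_best.get(ref.protein_id)
        if bh is None:
            ref_cov_all.append(0.0)
            continue
        q_ivs = [
            (h.query_start, h.query_end)
            for h in rev_pairs[(ref.protein_id, bh.target_id)]
        ]
        ref_cov_all.append(min(_union(q_ivs) / ref.length, 1.0))

    n_with_hit = len(fwd_best)
    distinct_best_refs = {h.target_id for h in fwd_best.values()}
    refs_with_rev_hit = len(rev_best)
    top_rev_genes = {h.target_id for h in rev_best.values() if h.target_id in rep_ids}

    metrics = SaagaMetrics(
        mean_protein_length_ratio=_mean(length_ratios),
        mean_f1=_mean(f1s),
        completeness=100.0 * _mean(ref_cov_all),
        purity=100.0 * _mean(protcovs_all),
        homology=100.0 * n_with_hit / n_genes,
        orthology=100.0 * len(rbh_genes) / n_genes,
        duplicity=n_with_hit / len(distinct_best_refs) if distinct_best_refs else 0.0,
        compression=len(top_rev_genes) / refs_with_rev_hit if refs_with_rev_hit else 0.0,
        multiplicity=n_genes / n_ref,
    )
    return metrics, pd.DataFrame(rows)


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs) if xs else 0.0
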