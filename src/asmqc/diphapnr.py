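"""Split a pseudodiploid assembly into primary and alternative haploids.

Linked-read assemblers in pseudohap2 mode emit two scaffolds per resolved
locus with systematically paired names (``<base>.1`` / ``<base>.2``). This
module reduces such an assembly to a non-redundant primary haploid plus an
alternative haplotig set:

1. scaffolds with no definitive base call (100% N) are removed;
2. scaffolds whose gap-capped sequence (every N-run reduced to at most 10
   Ns) is fully contained within another scaffold at the identity
   threshold are removed; where two scaffolds are mutually identical the
   lexicographically smaller id survives;
3. survivors are matched into haplotig pairs by base name: a singleton
   goes to the primary assembly (its partner was presumably removed as
   identical, or never assembled); of a pair the longer goes to primary
   and the shorter to alternative, an exact length tie resolved by id.

Containment evidence comes from an external all-by-all aligner run on the
gap-capped copies (PAF in); the output records keep their ORIGINAL gap
sizes — capping exists only to stop large gaps defeating the aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Pattern, Sequence

from .paf import AlignmentHit
from .buscomp import coverage_union
from .seqstats import SequenceRecord

#: N-runs are shortened to at most this many Ns in search copies.
DEFAULT_GAP_CAP = 10

#: pseudohap2 naming: trailing ".1"/".2" haplotype suffix.
DEFAULT_PAIR_PATTERN = re.compile(r"^(.*)\.([12])$")

#: Paired scaffolds whose length ratio falls below this are flagged in the
#: decision report: they pair by name but are unlikely true haplotigs.
LENGTH_RATIO_FLAG = 0.5

FATES = ("primary", "alternative", "removed_allN", "removed_contained", "removed_identical")


@dataclass(frozen=True)
class HaplotigDecision:
    """The fate assigned to one input scaffold, with its reasoning."""

    scaffold_id: str
    fate: str
    length: int
    partner_id: str | None = None
    reason: str = ""


def cap_gaps(record: SequenceRecord, max_run: int = DEFAULT_GAP_CAP) -> SequenceRecord:
    """Shorten every N-run longer than ``max_run`` to exactly ``max_run``
    Ns; shorter runs are untouched. Search-copy transform only — the
    emitted assemblies keep their original gaps."""
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    capped = re.sub(f"N{{{max_run},}}", "N" * max_run, record.residues)
    return SequenceRecord(id=record.id, residues=capped)


def _base_name(scaffold_id: str, pattern: Pattern[str]) -> str:
    m = pattern.match(scaffold_id)
    return m.group(1) if m else scaffold_id


def diphapnr(
    records: Sequence[SequenceRecord],
    containment_hits: Sequence[AlignmentHit] = (),
    pair_pattern: str | Pattern[str] = DEFAULT_PAIR_PATTERN,
    containment_frac: float = 1.0,
    identity_frac: float = 1.0,
    gap_cap: int = DEFAULT_GAP_CAP,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[HaplotigDecision]]:
    """Resolve a pseudodiploid assembly into (primary, alternative, decisions).

    ``containment_hits`` are alignments of gap-capped scaffolds against
    each other (query coordinates on the gap-capped sequence). A scaffold
    is contained when the union of its aligned intervals at >=
    ``identity_frac`` identity covers >= ``containment_frac`` of its
    gap-capped length. Both default to the literal 100% rule; real aligner
    output rarely achieves that, so they are tunable.

    Every input scaffold receives exactly one decision; primary and
    alternative records carry their original (uncapped) sequences.
    """
    if isinstance(pair_pattern, str):
        pair_pattern = re.compile(pair_pattern)
    if not 0 < containment_frac <= 1 or not 0 < identity_frac <= 1:
        raise ValueError("containment_frac and identity_frac must be in (0,1]")

    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate scaffold ids in input")
    for h in containment_hits:
        if h.query_id not in by_id or h.target_id not in by_id:
            missing = h.query_id if h.query_id not in by_id else h.target_id
            raise KeyError(f"containment hit references unknown scaffold {missing!r}")

    decisions: dict[str, HaplotigDecision] = {}

    # 1. drop all-N scaffolds
    live: list[SequenceRecord] = []
    for r in records:
        if set(r.residues) <= {"N"}:
            decisions[r.id] = HaplotigDecision(
                r.id, "removed_allN", r.length, reason="no definitive base calls"
            )
        else:
            live.append(r)

    # 2. containment on gap-capped copies: size-sorted descending (ties by
    # id), a scaffold is removed if contained in an already-kept one
    capped_len = {r.id: cap_gaps(r, gap_cap).length for r in live}
    cover: dict[tuple[str, str], int] = {}
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in containment_hits:
        if h.query_id == h.target_id or h.identity < identity_frac:
            continue
        per_pair.setdefault((h.query_id, h.target_id), []).append(
            (h.query_start, h.query_end)
        )
    for key, ivs in per_pair.items():
        cover[key] = coverage_union(ivs)

    def contained_in(q: str, t: str) -> bool:
        cov = cover.get((q, t))
        return cov is not None and cov >= containment_frac * capped_len[q]

    kept: list[SequenceRecord] = []
    for r in sorted(live, key=lambda r: (-r.length, r.id)):
        host = next((k for k in kept if contained_in(r.id, k.id)), None)
        if host is None:
            kept.append(r)
            continue
        mutual = contained_in(host.id, r.id)
        fate = "removed_identical" if mutual else "removed_contained"
        reason = (
            f"100% identical to {host.id}; lexicographically larger id removed"
            if mutual
            else f"contained within {host.id}"
        )
        decisions[r.id] = HaplotigDecision(r.id, fate, r.length, partner_id=host.id, reason=reason)

    # 3. pair survivors by base name
    groups: dict[str, list[SequenceRecord]] = {}
    for r in sorted(kept, key=lambda r: r.id):
        groups.setdefault(_base_name(r.id, pair_pattern), []).append(r)

    primary: list[SequenceRecord] = []
    alternative: list[SequenceRecord] = []
    for base, members in sorted(groups.items()):
        if len(members) > 2:
            raise ValueError(
                f"pair pattern groups {len(members)} scaffolds under base "
                f"{base!r}: {[m.id for m in members]}"
            )
        if len(members) == 1:
            r = members[0]
            primary.append(r)
            decisions[r.id] = HaplotigDecision(
                r.id, "primary", r.length, reason="single haplotig; assigned diploid"
            )
            continue
        a, b = members
        if a.length != b.length:
            p, alt = (a, b) if a.length > b.length else (b, a)
            reason = "longer haplotig of pair"
        else:
            p, alt = (a, b) if a.id < b.id else (b, a)
            reason = "length tie; lexicographically smaller id to primary"
        ratio = alt.length / p.length
        flag = f"; length ratio {ratio:.2f} < {LENGTH_RATIO_FLAG} — dubious haplotig pair" if ratio < LENGTH_RATIO_FLAG else ""
        primary.append(p)
        alternative.append(alt)
        decisions[p.id] = HaplotigDecision(
            p.id, "primary", p.length, partner_id=alt.id, reason=reason + flag
        )
        decisions[alt.id] = HaplotigDecision(
            alt.id, "alternative", alt.length, partner_id=p.id,
            reason="shorter haplotig of pair" + flag,
        )

    ordered = [decisions[r.id] for r in records]
    return primary, alternative, ordered
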