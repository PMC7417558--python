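"""Rule-based adjudication of homology (BLAST) hit tables into OTU taxonomy.

The cascade mirrors a conservative homology-based assignment protocol:

1. query the primary nucleotide database; OTUs with no primary hit fall
   back to a secondary (barcode) database;
2. discard low-confidence hits (alignment length < 200 nt, identity < 90%,
   query coverage != 100%, any gaps) and hits whose subject title carries
   an uninformative keyword (uncultured / unidentified / unclassified /
   environmental);
3. if the surviving hits agree on a single genus, assign the top hit;
4. if several genera survive, rank hits by identity, then e-value, then
   query coverage, then gap count; a winner that strictly beats every
   other-genus hit is accepted, otherwise the OTU is flagged dubious for
   manual curation.

At most five hits per query are considered, matching a
``-max_target_seqs 5`` search.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

__all__ = [
    "BlastHit",
    "FilterThresholds",
    "Assignment",
    "STATUSES",
    "parse_hit_table",
    "filter_hits",
    "rank_hits",
    "assign",
    "summarize_assignments",
    "extract_genus_species",
]

PRIMARY_COLUMNS = (
    "qseqid sseqid length pident gaps sstart send qcovs evalue bitscore "
    "staxids stitle"
).split()
FALLBACK_COLUMNS = PRIMARY_COLUMNS[:10]

STATUSES = (
    "assigned_top_hit",
    "assigned_tiebreak",
    "unassigned_no_hit",
    "unassigned_all_filtered",
    "removed_banned",
    "dubious",
)

MAX_HITS_CONSIDERED = 5


@dataclass(frozen=True)
class BlastHit:
    qseqid: str
    sseqid: str
    length: int
    pident: float
    gaps: int
    sstart: int
    send: int
    qcovs: float
    evalue: float
    bitscore: float
    staxids: str = ""
    stitle: str = ""


@dataclass(frozen=True)
class FilterThresholds:
    min_alignment_length: int = 200
    min_pident: float = 90.0
    required_qcovs: float = 100.0
    max_gaps: int = 0
    banned_title_keywords: frozenset = frozenset(
        {"uncultured", "unidentified", "unclassified", "environmental"}
    )


@dataclass
class Assignment:
    otu_id: str
    lineage: tuple = ()  # ordered rank names, possibly ending at genus
    species: Optional[str] = None
    status: str = "unassigned_no_hit"
    evidence: list = field(default_factory=list)  # surviving hits, ranked
    source_db: str = "primary"


class HitTableParseError(ValueError):
    pass


def parse_hit_table(
    stream: Union[str, TextIO], dialect: str = "primary"
) -> dict:
    """Parse a tabular hit file into ``{qseqid: [BlastHit, ...]}``.

    ``dialect="primary"`` expects the 12-column layout (with staxids and
    stitle); ``dialect="fallback"`` the 10-column layout, in which case
    staxids/stitle are left empty and genus is later recovered from sseqid.
    Input hit order per query is preserved.
    """
    if dialect not in ("primary", "fallback"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    ncols = 12 if dialect == "primary" else 10
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    out: dict = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncols:
            raise HitTableParseError(
                f"line {lineno}: expected {ncols} tab-separated columns for "
                f"the {dialect} dialect, found {len(fields)}"
            )
        try:
            hit = BlastHit(
                qseqid=fields[0],
                sseqid=fields[1],
                length=int(fields[2]),
                pident=float(fields[3]),
                gaps=int(fields[4]),
                sstart=int(fields[5]),
                send=int(fields[6]),
                qcovs=float(fields[7]),
                evalue=float(fields[8]),
                bitscore=float(fields[9]),
                staxids=fields[10] if ncols == 12 else "",
                stitle=fields[11] if ncols == 12 else "",
            )
        except ValueError as exc:
            raise HitTableParseError(f"line {lineno}: {exc}") from exc
        out.setdefault(hit.qseqid, []).append(hit)
    return out


def _violation(hit: BlastHit, t: FilterThresholds) -> Optional[str]:
    """First violated confidence rule, in the protocol's stated order."""
    if hit.length < t.min_alignment_length:
        return "alignment_length"
    if hit.pident < t.min_pident:
        return "identity"
    if hit.qcovs != t.required_qcovs:
        return "query_coverage"
    if hit.gaps > t.max_gaps:
        return "gaps"
    if _has_banned_keyword(hit.stitle, t.banned_title_keywords):
        return "banned_keyword"
    return None


def _has_banned_keyword(title: str, keywords) -> bool:
    words = re.findall(r"[A-Za-z]+", title.lower())
    return any(w in keywords for w in words)


def filter_hits(hits: Sequence[BlastHit], t: FilterThresholds = FilterThresholds()):
    """Split hits into (surviving, removals) under the confidence rules.

    ``removals`` maps each removed hit to the first rule it violated.
    """
    surviving, removals = [], {}
    for hit in hits:
        reason = _violation(hit, t)
        if reason is None:
            surviving.append(hit)
        else:
            removals[hit] = reason
    return surviving, removals


def _rank_key(hit: BlastHit):
    return (-hit.pident, hit.evalue, -hit.qcovs, hit.gaps, hit.sseqid)


def rank_hits(hits: Sequence[BlastHit]) -> list:
    """Total order: identity desc, e-value asc, coverage desc, gaps asc,
    then sseqid (deterministic final tie-break)."""
    return sorted(hits, key=_rank_key)


_BINOMIAL_RE = re.compile(r"([A-Z][a-z]+)\s+([a-z]{2,})")


def extract_genus_species(hit: BlastHit, source_db: str = "primary"):
    """Best-effort (genus, species-binomial-or-None) from a hit.

    Primary dialect: first capitalized alphabetic token of the subject
    title is the genus; if followed by a lowercase alphabetic token the
    pair forms the species binomial.  Fallback dialect: the subject id is
    split on ``|`` and ``_`` and scanned for the same pattern.
    """
    if source_db == "primary":
        tokens = re.findall(r"[A-Za-z]+", hit.stitle)
    else:
        tokens = [tok for part in hit.sseqid.split("|") for tok in part.split("_")]
        tokens = [t for t in tokens if t.isalpha()]
    for i, tok in enumerate(tokens):
        if tok[0].isupper() and tok[1:].islower() and len(tok) >= 3:
            genus = tok
            if i + 1 < len(tokens) and tokens[i + 1].islower() and len(tokens[i + 1]) >= 2:
                return genus, f"{genus} {tokens[i + 1]}"
            return genus, None
    return None, None


def _assign_from_survivors(
    otu_id: str,
    survivors: Sequence[BlastHit],
    source_db: str,
    lineage_map: Optional[Mapping[str, tuple]],
) -> Assignment:
    ranked = rank_hits(survivors)
    genera = []
    for h in ranked:
        g, _ = extract_genus_species(h, source_db)
        genera.append(g)
    distinct = {g for g in genera if g is not None}
    winner = ranked[0]
    w_genus, w_species = extract_genus_species(winner, source_db)

    if len(distinct) <= 1:
        status = "assigned_top_hit"
    else:
        # winner must strictly beat every other-genus hit on the first
        # differing ranked criterion; full four-way ties across genera are
        # left to manual curation.
        wkey = _rank_key(winner)[:4]
        for h, g in zip(ranked, genera):
            if g is not None and g != w_genus and _rank_key(h)[:4] == wkey:
                return Assignment(
                    otu_id=otu_id,
                    lineage=(),
                    species=None,
                    status="dubious",
                    evidence=ranked,
                    source_db=source_db,
                )
        status = "assigned_tiebreak"

    lineage: tuple = ()
    if lineage_map is not None and winner.staxids and winner.staxids in lineage_map:
        lineage = tuple(lineage_map[winner.staxids])
    elif w_genus is not None:
        lineage = (w_genus,)
    if w_species is not None:
        lineage = tuple(lineage) + (w_species,) if w_species not in lineage else lineage
    return Assignment(
        otu_id=otu_id,
        lineage=lineage,
        species=w_species,
        status=status,
        evidence=ranked,
        source_db=source_db,
    )


def assign(
    otu_id: str,
    primary_hits: Sequence[BlastHit] = (),
    fallback_hits: Sequence[BlastHit] = (),
    t: FilterThresholds = FilterThresholds(),
    lineage_map: Optional[Mapping[str, tuple]] = None,
) -> Assignment:
    """Adjudicate one OTU from its primary and fallback hit lists."""
    if primary_hits:
        hits, source_db = list(primary_hits), "primary"
    elif fallback_hits:
        hits, source_db = list(fallback_hits), "fallback"
    else:
        return Assignment(otu_id=otu_id, status="unassigned_no_hit", evidence=[])

    if len(hits) > MAX_HITS_CONSIDERED:
        warnings.warn(
            f"{otu_id}: {len(hits)} hits supplied, only the first "
            f"{MAX_HITS_CONSIDERED} are considered"
        )
        hits = hits[:MAX_HITS_CONSIDERED]

    survivors, removals = filter_hits(hits, t)
    if not survivors:
        all_banned = bool(removals) and all(
            r == "banned_keyword" for r in removals.values()
        )
        return Assignment(
            otu_id=otu_id,
            status="removed_banned" if all_banned else "unassigned_all_filtered",
            evidence=[],
            source_db=source_db,
        )
    return _assign_from_survivors(otu_id, survivors, source_db, lineage_map)


def summarize_assignments(assignments: Iterable[Assignment]) -> dict:
    """Counts per status, per deepest assigned rank, and per source db."""
    status = Counter()
    source = Counter()
    deepest = Counter()
    n = 0
    for a in assignments:
        n += 1
        status[a.status] += 1
        source[a.source_db] += 1
        if a.species is not None:
            deepest["species"] += 1
        elif a.lineage:
            deepest["genus"] += 1
        else:
            deepest["none"] += 1
    return {
        "n_otus": n,
        "by_status": {s: status.get(s, 0) for s in STATUSES},
        "by_deepest_rank": dict(deepest),
        "by_source_db": dict(source),
    }
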