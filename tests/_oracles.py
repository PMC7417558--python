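"""Independent brute-force oracles used by the test suite.

These re-state the adjudication rules directly (explicit predicates and
exhaustive pairwise comparisons instead of sorting) so they can disagree
with the library if the library is wrong.
"""

from __future__ import annotations

import re

BANNED = ("uncultured", "unidentified", "unclassified", "environmental")


def title_banned(title: str) -> bool:
    return any(w in re.findall(r"[a-z]+", title.lower()) for w in BANNED)


def hit_ok(h) -> bool:
    return (
        h.length >= 200
        and h.pident >= 90
        and h.qcovs == 100
        and h.gaps == 0
        and not title_banned(h.stitle)
    )


def genus_of(h, source_db="primary"):
    from foulscan.taxonomy import extract_genus_species

    return extract_genus_species(h, source_db)[0]


def beats(a, b) -> bool:
    """True iff hit a strictly precedes hit b on the ranked criteria."""
    if a.pident != b.pident:
        return a.pident > b.pident
    if a.evalue != b.evalue:
        return a.evalue < b.evalue
    if a.qcovs != b.qcovs:
        return a.qcovs > b.qcovs
    if a.gaps != b.gaps:
        return a.gaps < b.gaps
    return a.sseqid < b.sseqid


def four_way_tie(a, b) -> bool:
    return (
        a.pident == b.pident
        and a.evalue == b.evalue
        and a.qcovs == b.qcovs
        and a.gaps == b.gaps
    )


def brute_status(primary, fallback):
    """(status, winner_sseqid_or_None, source_db) by exhaustive evaluation."""
    if primary:
        hits, src = list(primary), "primary"
    elif fallback:
        hits, src = list(fallback), "fallback"
    else:
        return "unassigned_no_hit", None, "primary"
    hits = hits[:5]
    ok = [h for h in hits if hit_ok(h)]
    if not ok:
        removals_banned = all(
            (h.length >= 200 and h.pident >= 90 and h.qcovs == 100 and h.gaps == 0)
            and title_banned(h.stitle)
            for h in hits
        )
        return ("removed_banned" if removals_banned else "unassigned_all_filtered",
                None, src)
    # winner: the hit that beats every other
    winner = None
    for h in ok:
        if all(h is o or beats(h, o) for o in ok):
            winner = h
            break
    assert winner is not None, "total order must have a unique maximum"
    genera = {genus_of(h, src) for h in ok if genus_of(h, src) is not None}
    if len(genera) <= 1:
        return "assigned_top_hit", winner.sseqid, src
    wg = genus_of(winner, src)
    for o in ok:
        og = genus_of(o, src)
        if og is not None and og != wg and four_way_tie(winner, o):
            return "dubious", None, src
    return "assigned_tiebreak", winner.sseqid, src
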