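"""Read quality control and greedy OTU clustering.

Merged amplicon reads are filtered on a minimum length and a minimum mean
phred quality (defaults 100 bp / Q20), then clustered into operational
taxonomic units (OTUs) at a fixed identity threshold (default 97%).
Identity between two sequences is defined on a global (Needleman-Wunsch)
alignment with match +1, mismatch -1 and linear gap -2, as matching
columns over total alignment columns; among score-optimal alignments the
one with the most matches (and then the fewest columns) is used, which
makes the metric deterministic and symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "QCParams",
    "QCReport",
    "ClusterParams",
    "ClusterResult",
    "quality_filter",
    "pairwise_identity",
    "greedy_cluster",
    "apply_exclusion_list",
]


@dataclass(frozen=True)
class QCParams:
    """Length / quality thresholds for merged-read filtering."""

    min_length: int = 100
    min_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.min_quality <= 41:
            raise ValueError("min_quality must lie in [0, 41]")


@dataclass
class QCReport:
    n_in: int = 0
    n_short: int = 0
    n_low_q: int = 0
    n_out: int = 0


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.97
    mode: str = "de_novo"  # or "closed_reference"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must lie in (0, 1]")
        if self.mode not in ("de_novo", "closed_reference"):
            raise ValueError(f"unknown clustering mode: {self.mode!r}")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list = field(default_factory=list)
    member_identities: list = field(default_factory=list)


@dataclass
class ClusterResult:
    clusters: list  # list[Cluster]
    unassigned: list  # ids (closed-reference only)


class MalformedRecordError(ValueError):
    pass


def quality_filter(reads, params: QCParams = QCParams()):
    """Filter reads on length and mean phred quality.

    A read is kept iff ``len(seq) >= min_length`` and
    ``mean(quality) >= min_quality``.  A read failing both rules is
    counted once, as short.

    Returns ``(kept_reads, QCReport)``.
    """
    report = QCReport()
    kept = []
    for read in reads:
        if len(read.qualities) != len(read.sequence):
            raise MalformedRecordError(
                f"read {read.read_id!r}: quality string length "
                f"{len(read.qualities)} != sequence length {len(read.sequence)}"
            )
        report.n_in += 1
        if len(read.sequence) < params.min_length:
            report.n_short += 1
        elif float(np.mean(read.qualities)) < params.min_quality:
            report.n_low_q += 1
        else:
            report.n_out += 1
            kept.append(read)
    return kept, report


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

_BASE_CODE = {c: i for i, c in enumerate("ACGTRYSWKMBDHVN")}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc.args[0]!r}") from exc


@njit(cache=True)
def _nw_identity(a, b):  # pragma: no cover - numba kernel, tested via wrapper
    n = a.shape[0]
    m = b.shape[0]
    GAP = -2
    # S: best score; M: max matches among score-optimal alignments;
    # D: max diagonal moves among (score-opt, match-max) alignments.
    S = np.empty((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    for j in range(m + 1):
        S[0, j] = GAP * j
    for i in range(1, n + 1):
        S[i, 0] = GAP * i
        ai = a[i - 1]
        for j in range(1, m + 1):
            eq = 1 if ai == b[j - 1] else 0
            sub = 1 if eq else -1
            sd = S[i - 1, j - 1] + sub
            su = S[i - 1, j] + GAP
            sl = S[i, j - 1] + GAP
            best = sd
            if su > best:
                best = su
            if sl > best:
                best = sl
            bm = -1
            bd = -1
            if sd == best:
                bm = M[i - 1, j - 1] + eq
                bd = D[i - 1, j - 1] + 1
            if su == best:
                if M[i - 1, j] > bm or (M[i - 1, j] == bm and D[i - 1, j] > bd):
                    bm = M[i - 1, j]
                    bd = D[i - 1, j]
            if sl == best:
                if M[i, j - 1] > bm or (M[i, j - 1] == bm and D[i, j - 1] > bd):
                    bm = M[i, j - 1]
                    bd = D[i, j - 1]
            S[i, j] = best
            M[i, j] = bm
            D[i, j] = bd
    columns = n + m - D[n, m]
    return M[n, m], columns, S[n, m]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two DNA strings, in [0, 1]."""
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    matches, columns, _ = _nw_identity(_encode(a), _encode(b))
    return matches / columns


def alignment_score(a: str, b: str) -> int:
    """Optimal global alignment score (match +1 / mismatch -1 / gap -2)."""
    if not a or not b:
        raise ValueError("alignment_score requires two non-empty sequences")
    return int(_nw_identity(_encode(a), _encode(b))[2])


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------


def greedy_cluster(
    seqs: Mapping[str, str],
    params: ClusterParams = ClusterParams(),
    reference: Optional[Mapping[str, str]] = None,
) -> ClusterResult:
    """Greedy centroid clustering at ``identity_threshold``.

    de_novo: sequences are processed in decreasing length order (ties broken
    by id); each joins the first existing centroid it matches at or above
    the threshold, otherwise it founds a new centroid.

    closed_reference: each sequence joins the best-matching reference
    centroid at or above the threshold, else is reported unassigned.
    """
    if params.mode == "closed_reference" and reference is None:
        raise ValueError("closed_reference clustering requires a reference map")
    if params.mode == "de_novo" and reference is not None:
        raise ValueError("de_novo clustering does not accept a reference map")
    if not seqs:
        return ClusterResult(clusters=[], unassigned=[])

    thr = params.identity_threshold
    if params.mode == "de_novo":
        order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
        clusters: list[Cluster] = []
        for sid in order:
            s = seqs[sid]
            placed = False
            for cl in clusters:
                ident = pairwise_identity(s, seqs[cl.centroid_id])
                if ident >= thr:
                    cl.member_ids.append(sid)
                    cl.member_identities.append(ident)
                    placed = True
                    break
            if not placed:
                clusters.append(Cluster(sid, [sid], [1.0]))
        return ClusterResult(clusters=clusters, unassigned=[])

    # closed reference
    ref_ids = sorted(reference)
    clusters = {rid: Cluster(rid) for rid in ref_ids}
    unassigned = []
    for sid in sorted(seqs):
        best_id, best_ident = None, -1.0
        for rid in ref_ids:
            ident = pairwise_identity(seqs[sid], reference[rid])
            if ident > best_ident:
                best_id, best_ident = rid, ident
        if best_ident >= thr:
            clusters[best_id].member_ids.append(sid)
            clusters[best_id].member_identities.append(best_ident)
        else:
            unassigned.append(sid)
    kept = [cl for cl in clusters.values() if cl.member_ids]
    return ClusterResult(clusters=kept, unassigned=unassigned)


def apply_exclusion_list(
    seqs: Mapping[str, str], exclude: Sequence[str] = ()
) -> dict:
    """Drop sequences named on a precomputed exclusion list.

    Chimera detection itself is out of scope here; this pass-through stage
    keeps the pipeline position for an externally produced chimera list.
    """
    exclude = set(exclude)
    unknown = exclude - set(seqs)
    if unknown:
        warnings.warn(f"exclusion list names {len(unknown)} unknown sequence ids")
    return {k: v for k, v in seqs.items() if k not in exclude}
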