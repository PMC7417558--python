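"""Community diversity and multivariate statistics.

Implements the analyses applied to the sample-by-OTU tables: alpha
diversity (observed richness, bias-corrected Chao1, Shannon with natural
log, inverse Simpson), rarefaction, Bray-Curtis dissimilarity with a
constant dummy pseudo-OTU, one-way PERMANOVA with permutation p-values,
and the multivariate homogeneity-of-dispersions test (betadisper-style,
principal coordinates + distances to group centroids).

The PERMANOVA decomposition follows the distance-based sums of squares

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

with p-values from random relabelling (the +1 convention guarantees
p > 0); when the number of distinct relabellings does not exceed the
requested permutation count, they are enumerated exhaustively instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AbundanceMatrix",
    "AlphaDiversity",
    "DistanceMatrix",
    "PermanovaResult",
    "BetadisperResult",
    "aggregate_rank",
    "marker_exclusive_taxa",
    "alpha_diversity",
    "rarefaction",
    "expected_rarefied_richness",
    "bray_curtis",
    "permanova",
    "dispersion_test",
]

DEFAULT_DUMMY = 1e-4
DEFAULT_PERMUTATIONS = 9999

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AbundanceMatrix:
    sample_ids: list
    group_labels: list
    otu_ids: list
    counts: np.ndarray  # samples x otus, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        ns, no = self.counts.shape
        if len(self.sample_ids) != ns or len(self.group_labels) != ns:
            raise ValueError("sample_ids/group_labels length mismatch with counts")
        if len(self.otu_ids) != no:
            raise ValueError("otu_ids length mismatch with counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)
        df.insert(0, "group", self.group_labels)
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        if "group" not in df.columns:
            raise ValueError("abundance frame must carry a 'group' column")
        otus = [c for c in df.columns if c != "group"]
        return cls(
            sample_ids=list(df.index),
            group_labels=list(df["group"]),
            otu_ids=otus,
            counts=df[otus].to_numpy(),
        )


@dataclass(frozen=True)
class AlphaDiversity:
    observed: int
    chao1: float
    shannon: float
    inv_simpson: float


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray
    dummy_value: float = DEFAULT_DUMMY

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    df_between: int
    df_within: int
    SS_between: float
    SS_within: float
    SS_total: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool = False

    def as_table_row(self) -> dict:
        """One-factor results in an adonis-style layout."""
        return {
            "df": self.df_between,
            "SumsOfSqs": self.SS_between,
            "MeanSqs": self.SS_between / self.df_between,
            "F.Model": self.pseudo_F,
            "R2": self.R2,
            "Pr(>F)": self.p_value,
        }


@dataclass
class BetadisperResult:
    group_mean_distances: dict
    F_stat: float
    p_value: float
    eigenvalues: np.ndarray
    distances: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# taxonomy-aware aggregation
# ---------------------------------------------------------------------------


def aggregate_rank(matrix: AbundanceMatrix, assignments, rank: str) -> pd.DataFrame:
    """Relative abundance per sample at a taxonomic rank.

    ``assignments`` maps (or lists Assignment objects mapping) otu_id to a
    lineage; OTUs lacking an assignment at the rank are pooled under
    "Unassigned".  Rows sum to 1 except for all-zero samples, which stay
    all-zero and are flagged in ``df.attrs['all_zero_samples']``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if isinstance(assignments, Mapping):
        lineage_of = assignments
    else:
        lineage_of = {a.otu_id: a for a in assignments}

    ridx = RANKS.index(rank)

    def taxon_for(otu: str) -> str:
        a = lineage_of.get(otu)
        if a is None:
            return "Unassigned"
        lineage = a if isinstance(a, (tuple, list)) else getattr(a, "lineage", ())
        if len(lineage) == len(RANKS):
            name = lineage[ridx]
        elif rank == "genus" and lineage:
            name = lineage[0]
        elif rank == "species" and len(lineage) >= 2:
            name = lineage[-1]
        else:
            name = None
        return name if name else "Unassigned"

    taxa = [taxon_for(o) for o in matrix.otu_ids]
    df = pd.DataFrame(matrix.counts, index=matrix.sample_ids, columns=taxa)
    agg = df.T.groupby(level=0).sum().T
    totals = agg.sum(axis=1)
    zero = totals == 0
    rel = agg.div(totals.where(~zero, 1.0), axis=0)
    rel.loc[zero] = 0.0
    rel.attrs["all_zero_samples"] = list(rel.index[zero])
    return rel


def marker_exclusive_taxa(phylum_sets: Mapping[str, set]):
    """Exclusive and shared taxa across markers.

    Returns ``(exclusive, shared)``: ``exclusive[m]`` holds taxa seen only
    with marker ``m``; ``shared`` maps each frozenset of >= 2 markers to
    the taxa seen in exactly that combination.
    """
    if not phylum_sets:
        raise ValueError("at least one marker required")
    markers = list(phylum_sets)
    exclusive = {}
    for m in markers:
        others = set().union(*(phylum_sets[o] for o in markers if o != m)) if len(markers) > 1 else set()
        exclusive[m] = set(phylum_sets[m]) - others
    shared: dict = {}
    all_taxa = set().union(*phylum_sets.values())
    for taxon in all_taxa:
        where = frozenset(m for m in markers if taxon in phylum_sets[m])
        if len(where) >= 2:
            shared.setdefault(where, set()).add(taxon)
    return exclusive, shared


# ---------------------------------------------------------------------------
# alpha diversity and rarefaction
# ---------------------------------------------------------------------------


def alpha_diversity(counts: Sequence[float]) -> AlphaDiversity:
    """Observed richness, Chao1 (bias-corrected), Shannon (nats), inverse
    Simpson for one sample's count vector."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("alpha diversity is undefined for an all-zero sample")
    observed = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p**2).sum())
    return AlphaDiversity(observed, chao1, shannon, inv_simpson)


def rarefaction(
    counts: Sequence[int],
    depths: Sequence[int],
    n_iter: int = 100,
    seed: Optional[int] = None,
) -> dict:
    """Mean observed richness at each subsampling depth.

    Subsampling is without replacement (multivariate hypergeometric),
    averaged over ``n_iter`` draws.
    """
    x = np.asarray(counts, dtype=np.int64)
    total = int(x.sum())
    rng = np.random.default_rng(seed)
    out = {}
    for depth in depths:
        depth = int(depth)
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        if depth == total:
            out[depth] = float((x > 0).sum())
            continue
        richness = np.empty(n_iter)
        for i in range(n_iter):
            sub = rng.multivariate_hypergeometric(x, depth)
            richness[i] = (sub > 0).sum()
        out[depth] = float(richness.mean())
    return out


def expected_rarefied_richness(counts: Sequence[int], depth: int) -> float:
    """Closed-form hypergeometric expectation of rarefied richness:
    S - sum_i C(N - x_i, n) / C(N, n)."""
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    N = int(x.sum())
    if depth > N:
        raise ValueError("depth exceeds sample total")

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.where(N - x >= depth, np.exp(logC(N - x, depth) - logC(N, depth)), 0.0)
    return float(len(x) - miss.sum())


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(matrix: AbundanceMatrix, dummy: float = DEFAULT_DUMMY) -> DistanceMatrix:
    """Bray-Curtis dissimilarities on raw counts.

    A pseudo-OTU with constant value ``dummy`` is appended to every sample
    so that pairs of all-zero samples have a defined distance (0); pass
    ``dummy=0`` to disable.
    """
    X = matrix.counts.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if dummy:
        X = np.hstack([X, np.full((X.shape[0], 1), float(dummy))])
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        tot = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
    return DistanceMatrix(labels=list(matrix.sample_ids), d=d, dummy_value=dummy)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _ss_within(D2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    ssw = 0.0
    for g, n_g in enumerate(sizes):
        idx = np.flatnonzero(codes == g)
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ssw


def _distinct_relabellings(codes: np.ndarray):
    """All distinct assignments of the label multiset to positions."""
    n = len(codes)
    counts = np.bincount(codes)

    def rec(positions, counts):
        if not positions:
            yield ()
            return
        remaining = sum(counts)
        # place group for the first remaining position to avoid duplicates
        first, rest = positions[0], positions[1:]
        for g, c in enumerate(counts):
            if c == 0:
                continue
            counts2 = list(counts)
            counts2[g] -= 1
            for tail in rec(rest, counts2):
                yield (g,) + tail

    for lab in rec(tuple(range(n)), list(counts)):
        yield np.array(lab, dtype=int)


def _n_distinct_relabellings(codes: np.ndarray) -> int:
    counts = np.bincount(codes)
    n = math.factorial(int(counts.sum()))
    for c in counts:
        n //= math.factorial(int(c))
    return n


def _check_groups(labels) -> tuple:
    uniq = sorted(set(labels))
    codes = np.array([uniq.index(g) for g in labels])
    sizes = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members")
    return uniq, codes, sizes


def permanova(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix."""
    uniq, codes, sizes = _check_groups(groups)
    N = len(codes)
    a = len(uniq)
    D2 = d.d**2
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _ss_within(D2, codes, sizes)
    ss_between = ss_total - ss_within
    dfb, dfw = a - 1, N - a

    def f_of(ssw: float) -> float:
        ssb = ss_total - ssw
        if ssw <= 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / dfb) / (ssw / dfw)

    f_obs = f_of(ss_within)

    n_distinct = _n_distinct_relabellings(codes)
    if n_distinct <= n_perm:
        count = sum(
            f_of(_ss_within(D2, lab, sizes)) >= f_obs - 1e-12
            for lab in _distinct_relabellings(codes)
        )
        p = count / n_distinct
        exhaustive = True
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if f_of(_ss_within(D2, perm, sizes)) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        exhaustive = False
        n_used = n_perm

    return PermanovaResult(
        pseudo_F=f_obs,
        R2=ss_between / ss_total if ss_total > 0 else 0.0,
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        SS_between=ss_between,
        SS_within=ss_within,
        SS_total=ss_total,
        n_permutations=n_used,
        seed=seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# homogeneity of multivariate dispersions
# ---------------------------------------------------------------------------


def _pcoa(d: np.ndarray):
    n = d.shape[0]
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    return eigval[order], eigvec[:, order]


def _pcoa_coords(d: np.ndarray):
    eigval, eigvec = _pcoa(d)
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    Xp = eigvec[:, pos] * np.sqrt(eigval[pos])
    Xn = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return eigval, Xp, Xn


def _centroid_distances_from_coords(Xp, Xn, codes) -> np.ndarray:
    z = np.empty(len(codes))
    for g in np.unique(codes):
        idx = codes == g
        dp = ((Xp[idx] - Xp[idx].mean(axis=0)) ** 2).sum(axis=1) if Xp.size else 0.0
        dn = ((Xn[idx] - Xn[idx].mean(axis=0)) ** 2).sum(axis=1) if Xn.size else 0.0
        z[idx] = np.sqrt(np.maximum(0.0, dp - dn))
    return z


def centroid_distances(d: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in principal
    coordinates, correcting for negative eigenvalues (imaginary axes)."""
    _, Xp, Xn = _pcoa_coords(d)
    return _centroid_distances_from_coords(Xp, Xn, codes)


def _anova_f(z: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    grand = z.mean()
    ssb = sum(sizes[g] * (z[codes == g].mean() - grand) ** 2 for g in range(len(sizes)))
    ssw = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in range(len(sizes)))
    dfb = len(sizes) - 1
    dfw = len(z) - len(sizes)
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / dfb) / (ssw / dfw)


def dispersion_test(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
) -> BetadisperResult:
    """Multivariate homogeneity of group dispersions (betadisper-style).

    Samples are embedded by principal coordinates (all axes kept, negative
    eigenvalues subtracted in squared distance), each sample's distance to
    its group centroid is computed, and a one-way ANOVA F on those
    distances is referenced against a permutation distribution in which
    group labels are relabelled and the centroid distances recomputed in
    full, which keeps the test calibrated at small group sizes.
    """
    uniq, codes, sizes = _check_groups(groups)
    eigval, Xp, Xn = _pcoa_coords(d.d)
    z = _centroid_distances_from_coords(Xp, Xn, codes)
    f_obs = _anova_f(z, codes, sizes)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        pcodes = rng.permutation(codes)
        zp = _centroid_distances_from_coords(Xp, Xn, pcodes)
        if _anova_f(zp, pcodes, sizes) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)

    means = {uniq[g]: float(z[codes == g].mean()) for g in range(len(uniq))}
    return BetadisperResult(
        group_mean_distances=means,
        F_stat=f_obs,
        p_value=p,
        eigenvalues=eigval,
        distances=z,
    )


def sqrt_relative_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Square-root of relative abundances, an optional pre-transform for
    the Bray-Curtis / PERMANOVA route."""
    X = matrix.counts.astype(float)
    totals = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, X / np.where(totals > 0, totals, 1.0), 0.0)
    out = AbundanceMatrix(
        sample_ids=list(matrix.sample_ids),
        group_labels=list(matrix.group_labels),
        otu_ids=list(matrix.otu_ids),
        counts=np.sqrt(rel),
    )
    return out
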