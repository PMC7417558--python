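"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates reference taxa with pseudo-Latin names, merged reads with
planted length/quality failures, homology hit tables exercising each
adjudication branch, two-group abundance matrices with controllable
location and dispersion effects, grayscale panel image stacks with known
foreground fraction, invasive-species checklists, and the sampling-design
manifest bookkeeping of a year-long two-treatment panel survey.

All randomness flows from one explicit integer seed per call; identical
seeds give identical outputs.
"""

from __future__ import annotations

import zlib

import numpy as np
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy.ndimage import gaussian_filter

from .taxonomy import BlastHit

__all__ = [
    "TaxonRecord",
    "SimulatedRead",
    "SamplingDesign",
    "SyntheticHitTable",
    "GroupEffectSpec",
    "MARKERS",
    "CASES",
    "gen_reference_taxa",
    "gen_reads",
    "gen_hit_table",
    "gen_abundance",
    "gen_panel_stack",
    "build_sampling_manifest",
    "gen_checklist",
    "gen_pseudogene_decoy",
]

MARKERS = ("16S", "18S", "23S", "COI")
CASES = ("clean", "no_hit", "low_confidence", "ambiguous", "banned_keyword", "nis")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Tandem repeats of this unit contain a TAA/TAG stop at least every five
#: codons in all six reading frames, so pseudogene decoys built from it
#: fail translation validation under every common genetic code.
PSEUDOGENE_UNIT = "AATTAATTAGCT"

# pseudo-Latin name fragments; deliberately non-existent combinations to
# avoid collision with real taxon checklists
_GENUS_SYLLABLES = ("zyx", "quor", "vex", "plun", "dralt", "mox", "fyrn", "glib",
                    "crast", "ulv", "bryn", "twel", "sporn", "kelv", "ozz", "jarn")
_EPITHETS = ("fictus", "simulatus", "portuensis", "navalis", "ferrugineus",
             "atlanticus", "placidus", "incrustans", "velatus", "spurius",
             "obscurus", "litoreus", "praetextus", "adhaerens", "fucatus",
             "mendax")
_PHYLA = ("Pseudophyta", "Fabrichordata", "Mimomollusca", "Apatarthropoda",
          "Crypturozoa", "Fictobacteriota")
_KINGDOMS = {"16S": "Bacteria", "18S": "Eukaryota", "23S": "Bacteria",
             "COI": "Animalia"}


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    lineage: tuple  # (kingdom, phylum, class, order, family, genus, species)
    marker: str
    sequence: str

    @property
    def genus(self) -> str:
        return self.lineage[5]

    @property
    def species(self) -> str:
        return self.lineage[6]


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: tuple  # per-base phred integers, 0-41


@dataclass(frozen=True)
class SamplingDesign:
    """One-year, two-treatment panel survey bookkeeping.

    Defaults describe 12 monthly samplings of 2 painted and 4 (of 8) bare
    panels at 3 grids each, plus 2 whole-panel scrapes in the final month,
    with panel scrapes pooled into 2 DNA pools per month.
    """

    months: int = 12
    painted_panels: int = 2
    bare_panels_sampled_per_month: int = 4
    grids_per_panel_per_month: int = 3
    extra_whole_panel_scrapes: int = 2
    pools_per_month: int = 2

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticHitTable:
    rows: list  # BlastHit, grouped by query in emission order
    truth: dict  # query_id -> {"true_lineage": tuple|None, "planted_case": str}

    def by_query(self) -> dict:
        out: dict = {}
        for hit in self.rows:
            out.setdefault(hit.qseqid, []).append(hit)
        return out


@dataclass(frozen=True)
class GroupEffectSpec:
    n_per_group: int
    n_otus: int
    location_shift: float = 0.0
    dispersion_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2 or self.n_otus < 2:
            raise ValueError("need n_per_group >= 2 and n_otus >= 2")
        if self.location_shift < 0:
            raise ValueError("location_shift must be non-negative")
        if self.dispersion_ratio <= 0:
            raise ValueError("dispersion_ratio must be positive")


# ---------------------------------------------------------------------------
# reference taxa
# ---------------------------------------------------------------------------


def _genus_name(rng: np.random.Generator, used: set) -> str:
    while True:
        n = rng.integers(2, 4)
        syls = rng.choice(len(_GENUS_SYLLABLES), size=n, replace=True)
        name = "".join(_GENUS_SYLLABLES[i] for i in syls) + "us"
        name = name.capitalize()
        if name not in used:
            used.add(name)
            return name


def _clean_coi_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Frame +1 ORF with no TAA/TAG codon: translates without stops under
    the invertebrate mitochondrial code (and tables 4/9)."""
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in ("TAA", "TAG"):
            codons.append(c)
    return "".join(codons)


def gen_reference_taxa(
    n_taxa: int, markers: Sequence[str] = MARKERS, seed: int = 0
) -> list:
    """``n_taxa`` reference records per marker, with shared lineages.

    Each taxon gets its own genus and a pseudo-Latin species binomial;
    sequences are at least 200 bases, COI sequences are clean open reading
    frames so that they pass translation validation.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    bad = set(markers) - set(MARKERS)
    if bad:
        raise ValueError(f"unknown markers: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    used_genera: set = set()
    lineages = []
    for i in range(n_taxa):
        genus = _genus_name(rng, used_genera)
        epithet = _EPITHETS[rng.integers(0, len(_EPITHETS))]
        phylum = _PHYLA[rng.integers(0, len(_PHYLA))]
        lineages.append(
            (
                phylum,  # kingdom placeholder, replaced per marker
                phylum,
                f"{phylum[:-1]}ea",
                f"{genus}iformes",
                f"{genus}idae",
                genus,
                f"{genus} {epithet}",
            )
        )
    records = []
    for marker in markers:
        for i, lin in enumerate(lineages):
            lineage = (_KINGDOMS[marker],) + lin[1:]
            if marker == "COI":
                seq = _clean_coi_orf(rng, 80)
            else:
                length = int(rng.integers(220, 321))
                seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
            records.append(
                TaxonRecord(
                    taxon_id=f"T{i:04d}:{marker}",
                    lineage=lineage,
                    marker=marker,
                    sequence=seq,
                )
            )
    return records


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _qualities(rng, n, mean, sd=3.0, below=None, at_least=None):
    q = np.clip(np.rint(rng.normal(mean, sd, size=n)), 0, 41).astype(int)
    # nudge the whole read if sampling noise crossed the planted boundary
    if below is not None:
        while q.mean() >= below:
            q = np.maximum(q - 1, 0)
    if at_least is not None:
        while q.mean() < at_least:
            q = np.minimum(q + 1, 41)
    return tuple(int(v) for v in q)


def gen_reads(
    taxa: Sequence[TaxonRecord],
    n_reads: int,
    frac_short: float = 0.0,
    frac_low_q: float = 0.0,
    seed: int = 0,
) -> list:
    """Simulated merged reads with planted QC failures.

    Exactly ``round(n_reads * frac_short)`` reads are shorter than 100
    bases, ``round(n_reads * frac_low_q)`` of the rest fail the mean-Q20
    rule, and all remaining reads pass both filters.  Quality regimes are
    centred near Q35 (pass) and Q15 (fail).
    """
    if not 0 <= frac_short <= 1 or not 0 <= frac_low_q <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if frac_short + frac_low_q > 1 + 1e-9:
        raise ValueError("frac_short + frac_low_q must not exceed 1")
    if n_reads == 0:
        return []
    if not taxa:
        raise ValueError("need at least one reference taxon")
    rng = np.random.default_rng(seed)
    n_short = round(n_reads * frac_short)
    n_low = min(round(n_reads * frac_low_q), n_reads - n_short)

    kinds = ["short"] * n_short + ["low_q"] * n_low
    kinds += ["pass"] * (n_reads - len(kinds))
    rng.shuffle(kinds)

    reads = []
    for i, kind in enumerate(kinds):
        t = taxa[rng.integers(0, len(taxa))]
        if kind == "short":
            length = int(rng.integers(60, 100))
        else:
            length = int(rng.integers(100, min(len(t.sequence), 200) + 1))
        start = int(rng.integers(0, max(len(t.sequence) - length, 0) + 1))
        seq = t.sequence[start : start + length]
        if kind == "low_q":
            quals = _qualities(rng, length, 15.0, below=20.0)
        else:
            quals = _qualities(rng, length, 35.0, at_least=20.0)
        reads.append(SimulatedRead(f"read{i:06d}", seq, quals))
    return reads


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


def _stitle(lineage, note="voucher"):
    return f"{lineage[6]} {note} cytochrome c oxidase subunit I (COI) gene, partial cds"


def _accession(rng) -> str:
    letters = "".join(chr(65 + c) for c in rng.integers(0, 26, size=2))
    return f"{letters}{rng.integers(100000, 999999)}.1"


def _mk_hit(rng, qseqid, lineage, pident, evalue, *, length=None, qcovs=100.0,
            gaps=0, banned=None, taxid=None):
    length = int(rng.integers(220, 420)) if length is None else length
    title = _stitle(lineage)
    if banned:
        title = f"{banned.capitalize()} organism clone {_accession(rng)}"
    sstart = int(rng.integers(1, 200))
    return BlastHit(
        qseqid=qseqid,
        sseqid=_accession(rng),
        length=length,
        pident=round(float(pident), 3),
        gaps=int(gaps),
        sstart=sstart,
        send=sstart + length - 1,
        qcovs=float(qcovs),
        evalue=float(evalue),
        bitscore=round(2.0 * length * pident / 100.0, 1),
        staxids=str(taxid) if taxid is not None else str(rng.integers(10000, 99999)),
        stitle=title,
    )


def _case_counts(n: int, case_fractions: Mapping[str, float]) -> dict:
    total = sum(case_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"case fractions sum to {total}, expected 1")
    bad = set(case_fractions) - set(CASES)
    if bad:
        raise ValueError(f"unknown planted cases: {sorted(bad)}")
    items = [(c, case_fractions[c]) for c in CASES if c in case_fractions]
    counts = {c: int(np.floor(f * n)) for c, f in items}
    remainders = sorted(
        items, key=lambda cf: (cf[1] * n) - np.floor(cf[1] * n), reverse=True
    )
    short = n - sum(counts.values())
    for c, _ in remainders[:short]:
        counts[c] += 1
    return counts


def gen_hit_table(
    queries: Sequence[str],
    taxa: Sequence[TaxonRecord],
    case_fractions: Mapping[str, float],
    seed: int = 0,
    nis_species: Optional[Sequence[str]] = None,
) -> SyntheticHitTable:
    """Hit table with one planted adjudication case per query.

    clean          all hits pass the confidence filters and share a genus
    no_hit         no rows
    low_confidence every hit violates at least one numeric threshold
    ambiguous      passing hits span >= 2 genera, unique ranked winner
    banned_keyword otherwise-passing hits flagged with banned title words
    nis            clean case whose species is drawn from ``nis_species``

    At most five hits are emitted per query.
    """
    rng = np.random.default_rng(seed)
    counts = _case_counts(len(queries), case_fractions)
    if counts.get("nis", 0) > 0 and not nis_species:
        raise ValueError("planting 'nis' cases requires nis_species")
    cases = [c for c in CASES for _ in range(counts.get(c, 0))]
    rng.shuffle(cases)

    species_to_taxon = {t.species: t for t in taxa}
    nis_set = set(nis_species or [])
    nis_pool = [species_to_taxon[s] for s in sorted(nis_set) if s in species_to_taxon]
    if counts.get("nis", 0) > 0 and not nis_pool:
        raise ValueError("no nis_species found among the supplied taxa")
    # non-NIS cases must not accidentally use checklist species, so that
    # planted 'nis' labels are the exact truth for downstream screening
    plain_pool = [t for t in taxa if t.species not in nis_set]
    if not plain_pool:
        raise ValueError("all supplied taxa are on the NIS checklist")

    def pick_plain():
        return plain_pool[rng.integers(0, len(plain_pool))]

    banned_words = ("uncultured", "unidentified", "unclassified", "environmental")
    rows: list = []
    truth: dict = {}

    for q, case in zip(queries, cases):
        if case == "nis":
            taxon = nis_pool[rng.integers(0, len(nis_pool))]
        else:
            taxon = pick_plain()
        truth[q] = {
            "true_lineage": None if case in ("no_hit",) else taxon.lineage,
            "planted_case": case,
        }
        if case == "no_hit":
            continue
        if case in ("clean", "nis"):
            k = int(rng.integers(1, 6))
            pidents = np.sort(rng.uniform(95.0, 100.0, size=k))[::-1]
            for j in range(k):
                rows.append(
                    _mk_hit(rng, q, taxon.lineage, pidents[j],
                            10.0 ** -float(rng.integers(80, 160)),
                            taxid=10000 + zlib.crc32(taxon.species.encode()) % 80000)
                )
        elif case == "low_confidence":
            k = int(rng.integers(1, 6))
            for _ in range(k):
                violation = rng.integers(0, 4)
                rows.append(
                    _mk_hit(
                        rng, q, taxon.lineage,
                        pident=rng.uniform(70.0, 89.9) if violation == 1 else rng.uniform(95, 100),
                        evalue=1e-20,
                        length=int(rng.integers(60, 200)) if violation == 0 else None,
                        qcovs=float(rng.integers(40, 100)) if violation == 2 else 100.0,
                        gaps=int(rng.integers(1, 9)) if violation == 3 else 0,
                    )
                )
        elif case == "ambiguous":
            other = pick_plain()
            while other.genus == taxon.genus:
                other = pick_plain()
            rows.append(_mk_hit(rng, q, taxon.lineage, 99.8, 1e-150))
            k = int(rng.integers(1, 5))
            pidents = rng.uniform(95.0, 99.0, size=k)
            for j in range(k):
                src = other if j % 2 == 0 else taxon
                rows.append(_mk_hit(rng, q, src.lineage, pidents[j], 1e-100))
        elif case == "banned_keyword":
            k = int(rng.integers(1, 4))
            for _ in range(k):
                word = banned_words[rng.integers(0, len(banned_words))]
                rows.append(
                    _mk_hit(rng, q, taxon.lineage, rng.uniform(95, 100), 1e-50,
                            banned=word)
                )
    return SyntheticHitTable(rows=rows, truth=truth)


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

_BASE_SIGMA = 0.4  # per-sample log-scale dispersion of the reference group


def gen_abundance(spec: GroupEffectSpec):
    """Two-group ("painted"/"bare") OTU count matrix.

    Counts are Poisson draws around lognormal per-OTU baseline means with
    per-sample multiplicative noise.  ``location_shift`` scales the means
    of half the OTUs in the bare group by exp(shift); ``dispersion_ratio``
    scales the bare group's per-sample log-noise standard deviation.  With
    shift 0 and ratio 1 the two groups are exchangeable.
    """
    from .stats import AbundanceMatrix

    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_per_group, spec.n_otus
    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=m)
    affected = np.arange(m) < m // 2

    sigma = np.full(2 * n, _BASE_SIGMA)
    sigma[n:] = _BASE_SIGMA * spec.dispersion_ratio
    eps = rng.normal(0.0, 1.0, size=(2 * n, m)) * sigma[:, None]
    lam = base[None, :] * np.exp(eps)
    lam[n:, affected] *= np.exp(spec.location_shift)
    counts = rng.poisson(lam)

    sample_ids = [f"painted_{i + 1:02d}" for i in range(n)] + [
        f"bare_{i + 1:02d}" for i in range(n)
    ]
    return AbundanceMatrix(
        sample_ids=sample_ids,
        group_labels=["painted"] * n + ["bare"] * n,
        otu_ids=[f"OTU{j + 1:04d}" for j in range(m)],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# panel images
# ---------------------------------------------------------------------------


def gen_panel_stack(
    width: int,
    height: int,
    depth: int = 1,
    coverage_frac: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Grayscale stack with exactly ``round(frac * W * H)`` foreground pixels.

    Foreground (fouling, intensity 200) forms smooth blobs from a
    thresholded Gaussian random field over background (bare panel,
    intensity 50); each foreground pixel is bright in one random slice so
    that the maximum intensity projection recovers the planted mask.
    ``true_coverage`` stores the exact planted fraction before noise.
    """
    from .imaging import PanelImageStack

    if width < 1 or height < 1 or depth < 1:
        raise ValueError("width, height, and depth must be positive")
    if not 0 <= coverage_frac <= 1:
        raise ValueError("coverage_frac must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    npix = width * height
    k = round(coverage_frac * npix)

    field_ = gaussian_filter(rng.normal(size=(height, width)), sigma=max(min(height, width) / 10.0, 1.0))
    flat = field_.ravel()
    mask = np.zeros(npix, dtype=bool)
    if k > 0:
        mask[np.argpartition(flat, -k)[-k:]] = True
    mask = mask.reshape(height, width)

    slice_of = rng.integers(0, depth, size=(height, width))
    stack = np.full((depth, height, width), 50.0)
    for z in range(depth):
        stack[z][mask & (slice_of == z)] = 200.0
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return PanelImageStack(pixels=stack, true_coverage=k / npix)


# ---------------------------------------------------------------------------
# sampling manifest and checklists
# ---------------------------------------------------------------------------


def build_sampling_manifest(design: SamplingDesign = SamplingDesign()) -> dict:
    """Design bookkeeping: grids scraped, samples, and DNA pools.

    With the default design this reproduces a survey of 216 grids, 218
    scraped samples, and 26 DNA extract pools over 12 months.
    """
    panels = design.painted_panels + design.bare_panels_sampled_per_month
    grids_total = design.months * panels * design.grids_per_panel_per_month
    scraped_samples_total = grids_total + design.extra_whole_panel_scrapes
    dna_pools_total = (
        design.months * design.pools_per_month + design.extra_whole_panel_scrapes
    )
    per_month = [
        {
            "month": m + 1,
            "grids": panels * design.grids_per_panel_per_month,
            "painted_grids": design.painted_panels * design.grids_per_panel_per_month,
            "bare_grids": design.bare_panels_sampled_per_month
            * design.grids_per_panel_per_month,
            "pools": design.pools_per_month,
            "extra_whole_panel_scrapes": design.extra_whole_panel_scrapes
            if m == design.months - 1
            else 0,
        }
        for m in range(design.months)
    ]
    return {
        "grids_total": grids_total,
        "scraped_samples_total": scraped_samples_total,
        "dna_pools_total": dna_pools_total,
        "per_month": per_month,
    }


def gen_checklist(
    taxa: Sequence[TaxonRecord], nis_fraction: float, seed: int = 0
) -> list:
    """Reproducible invasive-species checklist rows (species, source_tag).

    A ``round(nis_fraction * n_species)`` subset of the input species is
    listed, each under one or more stand-in database tags.
    """
    from .nis import ChecklistEntry

    if not 0 <= nis_fraction <= 1:
        raise ValueError("nis_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    species = sorted({t.species for t in taxa})
    k = round(nis_fraction * len(species))
    chosen = sorted(rng.choice(len(species), size=k, replace=False))
    tags = ("GISD-like", "CABI-like", "AquaNIS-like", "NEMESIS-like")
    rows = []
    for idx in chosen:
        n_tags = int(rng.integers(1, 3))
        for t in rng.choice(len(tags), size=n_tags, replace=False):
            rows.append(ChecklistEntry(species=species[idx], source_tag=tags[t]))
    return rows


def gen_pseudogene_decoy(length: int = 240, seed: int = 0) -> str:
    """DNA that fails translation validation in every frame and code.

    Built from tandem repeats of a unit carrying stop codons in all six
    frames; the seed only rotates the starting phase.
    """
    if length < 3 * len(PSEUDOGENE_UNIT):
        raise ValueError("decoy length too short to guarantee stops in all frames")
    rng = np.random.default_rng(seed)
    phase = int(rng.integers(0, len(PSEUDOGENE_UNIT)))
    reps = PSEUDOGENE_UNIT * (length // len(PSEUDOGENE_UNIT) + 2)
    return reps[phase : phase + length]
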