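# Methods

This note documents the models and procedures implemented in `foulscan`,
the parameters that matter, the design choices made where reasonable
alternatives existed, and what the synthetic-data generators do and do
not emulate.

## Read quality control

Merged amplicon reads are kept iff `length >= min_length` (default 100
bases) **and** `mean(phred) >= min_quality` (default Q20). "Quality below
Q20" is interpreted as the *mean* read quality; per-base truncation and
sliding-window variants are common alternatives, but the mean rule is the
simplest reproducible reading and is the only one implemented. A read
failing both rules is counted once, as short, so the QC report partitions
the input (`n_in = n_short + n_low_q + n_out`). Chimera detection is out
of scope; `apply_exclusion_list` preserves the pipeline position for an
externally produced chimera list.

## Pairwise identity and OTU clustering

Identity between two sequences is defined on a global Needleman–Wunsch
alignment with match +1, mismatch −1 and linear gap −2, as matching
columns divided by total alignment columns. Among score-optimal
alignments the one with the most matches is used, and among those the one
with the fewest columns; this makes the metric deterministic and
symmetric without depending on traceback order. The dynamic program is a
numba kernel tracking (score, max matches, max diagonal moves) per cell;
the score component is cross-checked against Biopython's
`PairwiseAligner` in the tests.

Greedy clustering follows the UCLUST convention: de novo input is
processed in decreasing length order (ties broken by id, which makes the
partition independent of input order), and a sequence joins the *first*
centroid with identity at or above the threshold (default 0.97), else
founds a new centroid. Closed-reference mode instead assigns each
sequence to its *best* reference centroid, or to the unassigned bin. The
k-mer screening and bit-packed alignment heuristics of UCLUST/USEARCH are
deliberately not reproduced — at the package's problem sizes exact
alignment is affordable and keeps the identity guarantee checkable.

## Taxonomy adjudication cascade

Hits arrive as BLAST tabular rows: a 12-column primary dialect
(`qseqid sseqid length pident gaps sstart send qcovs evalue bitscore
staxids stitle`) and a 10-column fallback dialect without
staxids/stitle. Adjudication of one OTU:

1. use primary hits if any, else fallback hits (`source_db` records
   which); both empty → `unassigned_no_hit`;
2. keep at most the first five hits (mirroring `-max_target_seqs 5`);
3. confidence filter: a hit survives iff alignment length ≥ 200 nt,
   identity ≥ 90%, query coverage exactly 100%, zero gaps, and its title
   contains none of *uncultured / unidentified / unclassified /
   environmental* (case-insensitive whole words). The per-hit removal
   reason is the first violated rule in that order. No survivors →
   `unassigned_all_filtered`, or `removed_banned` when every removal was
   the keyword rule;
4. surviving hits sharing a single genus → `assigned_top_hit` with the
   ranked winner's lineage;
5. two or more genera: hits are ranked by identity desc, e-value asc,
   coverage desc, gaps asc, then subject id (a deterministic total
   order). A winner that strictly beats every other-genus hit on the
   first differing criterion gives `assigned_tiebreak`; a four-way tie
   across genera is flagged `dubious` with no lineage, i.e. deferred to
   manual curation rather than auto-resolved.

The query-coverage rule is enforced literally (`qcovs == 100`); it is
strict but unambiguous. Genus and species are parsed from the subject
title in the primary dialect (first capitalized alphabetic token plus
following lowercase token) and from the subject id (split on `|`/`_`) in
the fallback dialect; a user-supplied `staxids → lineage` map takes
precedence when available. Naive-Bayes classification of rRNA markers
against curated databases is out of scope; those markers can be run
through the same cascade on user-supplied hit tables.

## NIS screening

Screening is restricted to protein-coding COI assignments. A candidate
OTU is reported iff (i) its status is `assigned_*` with a species-level
binomial, (ii) the species matches a checklist entry exactly after
case/whitespace normalization (an optional synonym map is applied first),
and (iii) its sequence passes translation validation: some frame
(+1,+2,+3,−1,−2,−3) under some genetic code yields a translation whose
longest stop-free codon run covers ≥ 90% of codons. The 90% span rule —
rather than demanding a completely stop-free full-length translation —
tolerates amplicons that start mid-codon; sequences riddled with stops in
every frame (NUMT-like pseudogenes) still fail under every code. The
default code set {1, 2, 4, 5, 9} covers the standard code and the
mitochondrial tables most relevant to marine metazoan barcodes; ambiguity
codes translate to X and never count as stops. `source_tags` aggregates
every checklist naming the species. Live queries to invasive-species web
databases are out of scope: checklists are local CSV files.

## Community statistics

* **Alpha diversity** per sample: observed richness; bias-corrected Chao1
  `S_obs + F1(F1−1)/(2(F2+1))` (defined even when no doubletons exist);
  Shannon entropy in nats; inverse Simpson `1/Σ p_i²`. The chain
  `1 ≤ invSimpson ≤ exp(H) ≤ S_obs ≤ Chao1` is enforced as a property
  test on random vectors.
* **Rarefaction** subsamples without replacement (multivariate
  hypergeometric) and averages observed richness over iterations;
  `expected_rarefied_richness` provides the closed form
  `S − Σ_i C(N−x_i, n)/C(N, n)` used as the oracle.
* **Bray–Curtis** on raw counts, `d_ij = Σ|x_i−x_j| / Σ(x_i+x_j)`, after
  appending one pseudo-OTU of constant 0.0001 to every sample so pairs of
  all-zero samples have a defined distance (0). The dummy is a column,
  not an epsilon added everywhere; pass `dummy=0` to disable. An optional
  square-root-of-relative-abundance pre-transform is provided
  (`sqrt_relative_transform`) because both raw-count and transformed
  conventions are in common use; the default is raw counts.
* **PERMANOVA** (one-way): `SS_total = (1/N) Σ_{i<j} d_ij²`,
  `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²`,
  `pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a))`. P-values use
  random relabelling with the +1 numerator/denominator convention
  (guaranteeing p > 0), with a fixed seed; when the number of distinct
  relabellings does not exceed the requested permutation count the
  distribution is enumerated exhaustively and p is the exact tail
  fraction. Only single-factor designs are supported. The F and R²
  values are verified against vegan's `adonis2` on a frozen example.
* **Dispersion homogeneity** (betadisper-style): principal-coordinates
  embedding of the distance matrix (double-centered Gower matrix, full
  eigendecomposition, all axes kept), per-sample distance to its group
  *centroid* computed as `sqrt(max(0, d²_pos − d²_neg))` across
  positive/negative-eigenvalue axes, then a one-way ANOVA F on those
  distances. The permutation scheme relabels groups and **recomputes the
  centroid distances in full** for each permutation: permuting the fixed
  distances (or their residuals) is anticonservative at small group
  sizes because each sample's distance is measured from its own group's
  estimated centroid, while full recomputation restores nominal type-I
  error (measured 0.04–0.05 at α = 0.05 in the calibration suite).
  Centroids, not spatial medians, are used. The observed F is verified
  against vegan's `betadisper`/`anova` on the same frozen example.

## Image-based coverage and biomass

The image chain mirrors an ImageJ workflow: maximum intensity projection
across the stack (a single photograph passes through unchanged);
conversion to 8-bit grayscale (channel mean, then linear rescaling from
the source bit range with round-half-up); binarization by exact Otsu
threshold on the 256-bin histogram (foreground `> t` for bright fouling,
`≤ t` for dark; a constant image falls back to a fixed 128 threshold
with a warning); removal of 8-connected components smaller than
`min_particle_px` (default 5) as the noise filter; percent cover as
foreground pixels over ROI pixels, with 0-based half-open ROIs. Polarity
defaults to bright-is-fouling and must be chosen per image set. Biomass
per area is `(wet − clean)/area` with negative differences clipped to
zero; the default effective area of 336 cm² is a 20 × 20 cm panel minus
four 16 cm² attachment areas.

## Synthetic data: what it emulates, and what it does not

Every generator draws from `numpy.random.default_rng(seed)` with an
explicit integer seed — no global state, byte-identical reruns.

* **Taxa** get pseudo-Latin names assembled from reserved syllable pools
  (deliberately non-existent binomials, so accidental collision with real
  checklists is effectively impossible), one genus per taxon, and
  sequences ≥ 200 nt; COI sequences are built codon-wise excluding
  TAA/TAG so they are genuine open reading frames in frame +1.
* **Reads** plant exact failure counts: `round(n·frac_short)` reads under
  100 bases, `round(n·frac_low_q)` of the rest with mean quality drawn
  from a low regime. The two quality regimes (means ≈ Q35 and ≈ Q15,
  s.d. 3) separate cleanly around the Q20 rule, and a read is nudged
  integer-wise if sampling noise crosses its planted side of the
  boundary. Real platform error profiles, PCR bias and chimeras are not
  emulated; length/quality distributions are stipulated, not fitted.
* **Hit tables** plant one adjudication case per query (clean / no-hit /
  low-confidence / ambiguous / banned-keyword / NIS), with e-values
  generated to co-vary with identity so the ranked tie-break's
  assumptions hold, at most five hits per query. Species on the NIS
  checklist are excluded from non-NIS cases so planted labels are the
  exact truth for downstream screening. Pseudogene decoys are tandem
  repeats of a 12-mer carrying TAA/TAG stops at least every five codons
  in all six frames, so they fail validation under every common code.
* **Abundance matrices** use lognormal per-OTU baselines (log-mean
  log 20, log-s.d. 1) with per-sample multiplicative lognormal noise
  (base log-s.d. 0.4) and Poisson counts. `location_shift` multiplies
  half the OTUs' means in the bare group by `exp(shift)`;
  `dispersion_ratio` scales the bare group's noise s.d. With shift 0 and
  ratio 1 the groups are exchangeable by construction, which is what the
  type-I-error calibration relies on.
* **Panel stacks** threshold a smoothed Gaussian random field at its
  k-th order statistic, so the planted foreground fraction is exact to
  the pixel; foreground pixels (intensity 200 over background 50) are
  bright in one randomly chosen slice each, making the maximum intensity
  projection recover the planted mask; Gaussian pixel noise is added on
  top. Real photographs' uneven illumination, color, shadows and
  three-dimensional structure are not emulated — passing recovery tests
  shows the image chain is correct, not that Otsu segmentation is
  adequate for arbitrary field photographs.
* **The sampling manifest** is pure bookkeeping: with the default design
  (12 months, 2 painted + 4 bare panels × 3 grids, 2 whole-panel scrapes,
  2 pools/month) it yields 216 grids, 218 scraped samples and 26 DNA
  pools.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: 500
replicates × 199 permutations for calibration (group sizes 5 + 5, 15
OTUs), 200 replicates for power (location shift 2.0 at n = 5/group;
dispersion ratio 4 at n = 10/group), 500 random hit tables against the
brute-force oracle, 200 sequences for the clustering identity guarantee,
100 images for the Otsu oracle and 50 noisy panels for coverage
recovery. Floating-point tolerances: the PERMANOVA sum-of-squares
decomposition is checked to 1e-9; permutation comparisons use a 1e-12
slack on F to make ≥ robust to round-off; eigenvalues within ±1e-10 of
zero are treated as null axes in the principal-coordinates embedding.

## Known limitations

* The adjudicator consumes precomputed hit tables; it does not run
  BLAST, resolve taxids against a live taxonomy, or compute
  lowest-common-ancestor consensus.
* Species matching in NIS screening is exact binomial equality (plus an
  optional synonym map); no fuzzy matching or genus-level screening.
* PERMANOVA/betadisper support a single factor with ≥ 2 members per
  group; no strata, blocking or multi-factor designs.
* The greedy clusterer is exact but quadratic; it is intended for
  thousands, not millions, of sequences.
* Morphology-based identifications (used alongside metabarcoding in real
  surveys) have no computational counterpart here beyond checklist
  metadata.
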