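# Methods

## Study model

The pipeline models a field campaign spanning three connected
compartments: the sea surface (foam, surface microlayer, subsurface
water), the atmospheric boundary layer (aerosol filters), and
precipitation (rain, snow). Reads from each sample are mapped against a
shared catalog of dereplicated viral scaffolds (>10 kb) and prokaryotic
MAGs; everything downstream — occupancy, exclusivity, enrichment,
variant sharing — is a function of the resulting presence calls and
normalized coverages. Handling/sequencing controls enter parsing but are
excluded from every statistic, and reads seen in control assemblies are
subtracted before coverage is computed.

## Presence contracts

- Viral scaffolds: present in a sample iff breadth ≥ 0.75 (fraction of
  positions with depth ≥ 1) after keeping alignments with identity
  ≥ 0.90. Identity is `(aligned_length − edit_distance)/aligned_length`
  over the aligned portion, soft clips excluded. The field typically
  enforces the 90 % cut through the mapper's score function; an explicit
  NM-based filter is equivalent only approximately (score functions
  weight gaps differently), which is why the filter is exposed rather
  than hidden in mapper settings.
- MAGs: breadth ≥ 0.90 under a ≤2 % error mapping contract
  (identity ≥ 0.98).
- All thresholds are inclusive (≥), matching the "at least" reading, and
  are pinned by generator decoys placed just beyond the boundaries
  (breadth 0.74 at identity 0.95; breadth 0.90 at identity 0.85).
- Sum normalization divides raw mean depth by library size at a
  per-million scale. The scale cancels in every downstream ratio because
  numerator and denominator samples share the convention; a test verifies
  ratio invariance under rescaling.

## Ecosystem synthesis

Occupancy per ecosystem is the OR over member samples. Venn regions are
exact membership patterns (verified against subset enumeration).
Enrichment ratios take the maximum normalized coverage across an
ecosystem as its highest plausible abundance and divide rain or aerosol
maxima by foam/SML maxima of a stated size fraction; a ratio is
undefined when either side lacks a detection. The shared-fraction
denominator defaults to the full catalog size (configurable), since
published percentages are quoted against the dereplicated catalog.

Group comparisons of %G/C use a tie-corrected Kruskal–Wallis H with
Dunn's rank-mean z post hoc; adjusted p-values are Bonferroni
(raw × number of comparisons, capped at 1). Shannon H′ uses natural
log on per-sample relative abundances. PERMANOVA computes the pseudo-F
from squared Bray–Curtis distances with label permutations and
p = (#{F_perm ≥ F_obs}+1)/(n_perm+1); it is implemented in-package with
an explicit RNG (scikit-bio's implementation serves as the independent
cross-check in tests, matching to machine precision).

## d2* host linkage

Profiles count k = 6 words on the sequence and its reverse complement;
expected counts come from an order-2 Markov chain fitted to the same
sequence (transition and context counts with a 0.5 pseudocount, which
keeps all expectations positive on short sequences). d2* maps the
background-centred correlation to [0, 1]; 0.5 is the independence point,
and assignment keeps hosts at d2* ≤ 0.3 with the minimum flagged
(lexicographic tie-break). k, order, strand convention, pseudocount and
threshold are parameters; the defaults follow common host-matching
practice.

## CRISPR linkage

Direct repeats whose sequence occurs verbatim in any viral scaffold are
discarded (likely viral repeats). Spacer extraction is Hamming-only
(≤3 mismatches, no indels) between consecutive non-overlapping DR hits
on both strands, keeping gaps ≤60 bp; cassettes truncated at read ends
are ignored. The homopolymer rule is made explicit: drop a spacer if one
base makes up ≥90 % of it or a single-base run reaches 15. Clustering is
greedy longest-first at 99 % identity (matches over the shorter length,
best ungapped offset, either strand). Protospacer matching is an
exhaustive ungapped scan of every offset on both strands with identity =
matches/spacer length at an inclusive 0.80 cut; this is exact and
reproducible at desk scale, whereas a seeded short-read BLAST heuristic
could admit borderline gapped hits — a deliberate, documented
simplification.

## Variants

Substitution-only calls from per-position A/C/G/T counts: depth ≥ 10,
alternate frequency ≥ 0.10, alternate count ≥ 4, reference base taken
from the scaffold FASTA. GUI variant callers used in practice do not
publish their defaults as a contract, so these explicit conservative
thresholds are the package's own and are configurable; equivalence with
any particular external tool is not claimed. Sites are shared between
samples iff position and alternate base coincide.

## Trajectories

A point is *sea* when the land mask says water, and *loading* when the
point is inside the mixing layer (altitude ≤ boundary-layer height from
a reanalysis-style field) and surface wind is strictly greater than
3 m s⁻¹. The literal two-criterion rule is the default; an option
additionally requires the point to be over sea, since marine-particle
loading over land is physically questionable but the published criteria
mention only the two conditions. Event summaries average per-trajectory
fractions over the first 96 of 120 hourly points (first four days);
the full-window option is retained. Nearest-grid annotation is Euclidean
in degrees with a lowest-index tie-break.

## INP estimation

With f(T) the cumulative frozen fraction of wells, Poisson statistics
give the expected INP per well as λ(T) = −ln(1 − f(T)); dividing by the
well volume yields the suspension concentration and dividing by the
source-water volume represented per punch — filtered volume × (punch
diameter / filter diameter)² — refers it back to the sampled water. The
geometry scaling is reconstructed from the described assay (1 mm punches
from 47 mm filters); the exact published formula is not printed anywhere,
so the area-fraction construction is this package's explicit choice.
Fully frozen trays are censored: a half-count continuity correction
((n−0.5)/n) gives a flagged lower bound instead of an infinite value.
The estimator's exact small-sample bias at 24 wells is ≤ ~8 % for
0.1 < f < 0.9 (Jensen's inequality on −ln(1−·)), which is why recovery
tests demand 10 % rather than exact unbiasedness.

## Interaction model and AIC convention

The wind×salinity model is OLS on [1, a, b, a·b], reported with adjusted
R², the overall F test, and AIC under the Gaussian-likelihood convention
that includes the 2π constant and counts the error variance as a
parameter — the convention of R's `stats::AIC`, which differs from
statsmodels' OLS `aic` by exactly +2. A frozen R-computed oracle pins
the convention in the tests.

## Synthetic data: what it emulates, and what it does not

Generators produce, with one RNG stream per stage derived from the
global seed (SHA-256 of `"<seed>:<stage>"`):

- **Genomes.** Hosts are sampled from per-host order-4 Markov chains.
  d2* subtracts the fitted order-2 background, so sequences generated by
  an order-2 chain would carry *no* residual 6-mer signal and all
  distances would sit at the 0.5 independence point; generating at order
  4 places the host signature exactly where d2* looks for it. Each
  transition row is rescaled to emit G/C with probability equal to the
  class target (marine 0.40, rain-only 0.60, matching the observed
  spread of marine scaffolds versus the elevated rain-only subset), so
  realized G/C lands within ±0.02 of target by construction. Viruses are
  resampled from their true host's chain with 5 % point mutations.
- **Coverage.** Alignment tables tile a prefix of each genome with
  150 bp reads whose edit distance realizes the requested identity;
  breadth is exact to within one read. Decoys pin the inclusive
  thresholds. No quality models, insert sizes or GC-coverage bias are
  simulated — coverage is generated at the depth-table level, so passing
  tests certify the calling logic, not robustness to mapper artifacts.
- **CRISPR.** Reads carry DR–spacer–DR cassettes; spacers are genome
  substrings with round(divergence × length) substitutions, so 20 %
  divergence sits exactly on the 0.80 identity boundary. The DR is
  rejected-sampled to occur in no scaffold.
- **Trajectories.** 120 hourly points; the first 96 realize the
  prescribed sea and loading fractions exactly after integer rounding
  (the dispersal set-points 72 %/35 % and 64 %/10 % are the two-event
  defaults in the pipeline). Loading points are a subset of sea points
  unless over-land loading is enabled.
- **Freezing assays.** 0.1 K steps mirror the imaging cadence; each
  still-liquid well freezes with probability 1 − exp(−Δλ) per step, the
  Poisson probability of at least one newly active INP.
- **Count tables.** Log-normal with exact latent-Gaussian inversion of
  the requested Pearson targets (all specimens share a coefficient of
  variation of 0.3, so a target of 1 yields exactly collinear columns);
  infeasible target matrices are rejected as not PSD.

Real sequencing data differ from all of this in ways the generators do
not model (strain mixtures, uneven coverage, chimeric assembly,
database incompleteness); synthetic truth recovery therefore
demonstrates the correctness of the computations, not field performance.

## Problem sizes and determinism

The default end-to-end study runs 20 viruses (10–15 kb) from 4 hosts
across 12 samples, 10 trajectories, one freezing assay and the bundled
16-row station table; it completes in well under a minute on one core.
Calibration checks use 10,000 Kruskal–Wallis null replicates, 1,000
PERMANOVA replicates at 999 permutations, and 500 simulated freezing
assays. All tabular output is written with '.' decimal separators at
fixed precision; identical config + seed reproduces byte-identical
files.

## Known limitations

- Real-data mode provides per-stage entry points (SAM/depth/pileup/CSV
  readers) but no end-to-end orchestration; assembling, binning, viral
  identification and trajectory computation are upstream tools whose
  outputs this package consumes.
- Protospacer and DR matching are ungapped; indel-divergent spacers are
  missed by design.
- The NM-identity filter approximates score-function mapping cut-offs.
- Spearman p-values use the large-sample t approximation, not the exact
  permutation distribution.
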