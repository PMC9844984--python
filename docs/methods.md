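# Methods

This note records the models implemented in meioscan, the assumptions they
make, the tunable parameters and their defaults, and the design choices
taken where more than one reasonable construction existed. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Setting and data model

The input is a table of sparse genotype observations for one chromosome of
one diploid donor: rows are SNP positions, columns are individual gametes
(sperm or oocytes), entries are 0 (reference allele), 1 (alternative) or
NA. Only sites heterozygous in the donor are informative, and a site can
only be *recognised* as heterozygous if both alleles are observed somewhere
in the gamete pool — hence the canonical input filter keeps rows with at
least one observed 0 and one observed 1. Two artifact filters for real data
precede it: exclusion of technically challenging regions given as BED
files, and removal of sites whose observation count exceeds the per-donor,
per-chromosome mean by more than one standard deviation (donor-specific
segmental duplications pile up reads from both copies at one reference
locus and can mimic transmission distortion). The pipeline applies filters
in a fixed order — BED → keep-list → excess-observation → informative —
because the excess filter's mean/sd must be computed before uninformative
rows are dropped.

Coordinates are 1-based inside the package. BED intervals are compared
directly against these positions as half-open `[start, end)` ranges, so a
site at position `end` is kept; this convention is pinned by tests.
Nucleotide-encoded tables (A/C/G/T with per-site ref/alt) are mapped to
0/1; a call matching neither allele becomes NA with a warning rather than
an error, since the downstream model explicitly absorbs genotyping error.

## Phasing: windowed clustering

Within a window of `window_length` SNPs (default 3000, overlap default
half a window), the Jaccard distance between two gametes is computed over
their pairwise-complete positions, treating allele 1 as presence:
d = (discordant positions with ≥ 1 one) / (positions with ≥ 1 one). A pair
with no such position is assigned distance 1 — the distance matrix must be
total for agglomeration, and mutually uninformative gametes are best kept
apart. Gametes are clustered by Ward agglomeration (the D2
variance-minimising Lance–Williams update, applied to the precomputed
non-Euclidean distances as-is) and the tree is cut into two clusters.

The method's core assumption is that recombinant gametes are a minority
within each window: each cluster then corresponds to one donor homolog.
Per-cluster, per-site majority votes decode the haplotype; exact ties vote
NA. The two cluster votes are reconciled site by site: complementary votes
are accepted, a one-sided NA is filled as the complement of the other
cluster's vote, and contradictory votes (both clusters voting the same
allele — typically a locally mis-split clustering) become NA. A window
whose tree cut yields a single non-empty cluster (all gametes effectively
identical) is returned as all-NA.

Windows are stitched left to right. At each junction the consensus is the
match fraction between the growing haplotype 1 and the new window over
overlap sites phased in both. Consensus above the threshold (default 0.9)
keeps the window's orientation; below 1 − threshold flips it. In stringent
mode (the default) anything in between — including an empty comparable
overlap — raises an error naming the junction; lenient mode takes the
higher-consensus orientation (an exact 0.5 tie keeps, logged). Overlap
sites keep the left window's call unless it is NA. Haplotype 2 is the
complement of haplotype 1 wherever phased, asserted as an invariant.

The default window length follows from the minority-recombinant
assumption: with r crossovers per chromosome expected, a window spanning a
fraction w of the chromosome sees ~rw crossovers per gamete, so windows of
a few thousand SNPs on chromosomes of tens of thousands keep recombinants
rare while pooling as many observations as possible. Chromosomes much
shorter than the default window are handled by the single-window path, but
users analysing short chromosomes at high recombination rates should
shrink the window (or use the automatic selector below).

## Automatic window size

An optional beta regression predicts the optimal window *proportion*
(window length / chromosome SNP count) from gamete count, coverage,
genotyping error rate and recombination rate. The model is fitted locally:
small datasets are simulated over a factorial grid (defaults: 20/60/150
gametes × 0.15/0.4/1.0× coverage × error 0.005/0.03 × r 0.5/1.5/4, at 600
underlying SNPs), each design is phased at six candidate proportions
(0.05–0.9, lenient stitching, since tiny windows on sparse data often
straddle the stitching band), the accuracy-maximising proportion is
recorded with ties resolved toward the larger window, and a beta
regression with a logit mean link is fitted on the grid. Because the mean
link is monotone, the fitted coefficient signs fully determine the
direction of each recommendation — more gametes and coverage push toward
larger windows, faster recombination toward smaller ones — and the tests
pin those signs. Predictions clamp inputs to the training hull (with a
warning): the regression is trusted as an interpolator only. Without a
fitted model the fixed default window is used, with a warning.

## Imputation: haplotype-of-origin HMM

Each gamete is decoded independently over its observed sites with known
phase. Hidden states are H1/H2 with initial probabilities (0.5, 0.5);
emissions are 1 − ε for an allele matching the state's haplotype and ε
otherwise; transitions between *consecutive observed sites* are
p = r / n_hetSNPs for a state change and 1 − p otherwise, independent of
the physical gap — the expected r crossovers are spread uniformly over the
hetSNPs. Defaults ε = 0.005 (typical short-read genotyping error) and
r = 1 crossover per chromosome. Constraints 0 < ε < 0.5 and 0 < p < 0.5
are enforced. All arithmetic is in log space; at these scales no further
normalisation is needed. Viterbi ties break toward no state change (fewer
inferred crossovers), and a tied final state resolves to H1 —
deterministic by construction. The test suite checks the decoder against
brute-force path enumeration on small instances.

After decoding, NA runs are filled: interior runs flanked by the same
state take that state; runs between discordant flanks are crossover
intervals and remain NA; terminal runs are filled from the nearest decoded
state unless `fill_ends` is disabled (chromosome ends recombine at high
rates in practice, so the conservative option exists). Sites of unknown
phase are excluded from the HMM, filled like unobserved sites at the path
level, but their *genotypes* stay NA — the allele cannot be named without
phase. Finally, original observations that conflict with the inferred
genotypes are superimposed back (flagged per cell), guarding against
HMM over-smoothing; the pre-superimposition ("smoothed") matrix is kept,
because crossover discovery must run on it — raw genotyping errors would
otherwise masquerade as crossovers, and discovery refuses superimposed
input outright.

## Crossover discovery

With NA runs squeezed out, every transition between consecutive assigned
states becomes one interval: last site of the outgoing haplotype to first
site of the incoming one, with direction and width (the breakpoint
resolution, in bp when positions are genomic). Per-gamete interval counts
equal the number of state sign changes by construction.

## Generative simulator

The simulator is the package's ground-truth source and defines the
conditions under which the benchmarks are run:

1. haplotype 1 is i.i.d. Bernoulli(0.5) per site; haplotype 2 its
   complement;
2. each gamete starts from a uniformly chosen homolog and switches at
   N ~ Poisson(r) breakpoints placed uniformly *without replacement* over
   the inter-SNP gaps (two breakpoints in one gap would annihilate and be
   untestable);
3. masking: the missing genotype rate is the Poisson zero-class
   probability MGR = exp(−coverage); exactly round(MGR × cells) entries
   are hidden, uniformly without replacement, so the realized missing
   fraction is exact by construction;
4. errors: exactly round(rate × observed cells) observed entries have
   their allele inverted;
5. rows left without both alleles are dropped (the observability filter),
   so observed hetSNP counts are ≤ the underlying count.

Positions default to site indices; a fixed inter-SNP spacing (e.g.
1000 bp, one hetSNP per kilobase of pairwise diversity) can be requested
for resolution studies. A single seeded generator drives all steps in a
documented order; equal seeds give byte-identical datasets.

The transmission-distortion variant plants a causal SNP (random or given)
and removes each gamete carrying the haplotype-2 allele there with
probability f = 2 − 1/k from an enlarged pool before down-sampling to the
target count; the favoured allele's expected transmission is then
0.5/(0.5 + 0.5(1 − f)) = 1/(2 − f) = k, an identity the tests verify
empirically.

What the simulator does *not* emulate: crossover interference (uniform
placement is conservative for close-pair misses), recombination-map and
hotspot heterogeneity, non-uniform or strand-biased error processes,
cell-quality variation, doublets, and aneuploidy. Passing benchmarks
therefore demonstrate correctness of the inference under the stated
generative assumptions, not robustness to every artifact of real
droplet-sequencing data — the artifact filters exist for those.

## Evaluation metrics

For sequences over {0, 1, NA}: accuracy is 1 − Hamming error rate, where a
position with NA in either sequence is not a mismatch but stays in the
denominator; completeness is the non-NA fraction; the switch error rate
counts NA-uninterrupted stretches of adjacent mismatches (one per stretch)
per position; the largest segment is the longest NA-free run of matches.
Haplotype-level scores take the better of the two truth orientations,
since the H1/H2 labelling is arbitrary.

Crossover calls are classified per gamete chromosome: a simulated
breakpoint whose gap midpoint lies strictly inside a predicted interval is
a TP, with greedy one-to-one matching in genomic order (two truths inside
one interval give one TP and one FN); unmatched predictions are FPs,
unmatched truths FNs, and a chromosome with neither is one TN. Counts are
pooled across gametes before ratios (TPR, FDR, precision, F1, FPR, TNR,
accuracy) are formed — pooling, not averaging of per-gamete ratios,
matches how a single figure per dataset is reported — and ratios with
empty denominators are NaN.

## Transmission-distortion statistics

The per-site test is the exact two-tailed binomial test (minimum-likelihood
rule: sum the probabilities of all outcomes no likelier than the observed
count, with a 1e-7 relative tolerance against floating-point ties). It is
implemented as a vectorised per-n table — a genome scan tests tens of
thousands of sites — and is validated against `scipy.stats.binomtest`
exactly in the tests.

The effective number of tests is estimated from SNP correlation: per block
of 1000 consecutive SNPs (configurable; agreement with the dense
eigendecomposition is tested), the smallest number of top eigenvalues
reaching 99.5% of the total mass, summed over blocks, chromosomes and
donors; the genome-wide threshold is 0.05 divided by that sum. Constant
rows are dropped, and the rare NAs in imputed matrices are mean-imputed
for the correlation only.

Global allele sharing: SNPs are pruned to approximate linkage equilibrium
by a sliding-window VIF rule (window 50 SNPs, step 5, VIF < 2; the SNP
with the largest VIF — diagonal of the inverted window correlation matrix,
ridge-regularised by 1e-8 for perfectly collinear windows — is removed
iteratively). Mean pairwise sharing over gamete pairs (fraction of equal
alleles at mutually non-NA pruned sites) is then compared against null
replicates of the generative model without masking or errors, matched on
gamete number, pruned SNP count and crossover counts; the one-tailed
p-value is the fraction of null means at or above the observed value.

Power calculators: `power_binomial` draws allele counts from
Binomial(n, k) — full knowledge of every gamete's genotype — and applies
the exact test at the given α; `power_tdt` simulates the pedigree McNemar
statistic (b − c)²/(b + c) against the χ²(1) upper tail;
`power_extreme_td` runs the whole pipeline (simulate with planted k,
phase, impute with superimposition, scan) and reports the fraction of
replicates whose lead SNP beats α, along with how often the causal SNP
itself was filtered as apparently homozygous and any pipeline failures.
The extreme-TD experiment stitches leniently by default: near the causal
site the haplotypes are carried at ~99:1, window junctions there can
straddle the stringent consensus band, and the distortion signal lives in
the imputed genotypes, which are invariant to local haplotype-label flips.

## Numerical and tie-breaking conventions

- Jaccard pairs without usable positions: distance 1 (logged).
- Cluster vote ties: NA; contradictory cluster votes: NA.
- Lenient stitch consensus tie (exactly 0.5): keep orientation, logged.
- Viterbi ties: stay in state; final-state tie: H1.
- Excess-observation filter: sample standard deviation (ddof = 1).
- Window-model responses are squeezed into (0, 1) by the standard
  (y(n−1) + 0.5)/n correction before the beta fit.
- All simulation sampling is count-exact (round, not Bernoulli), so
  realized rates match requested rates to rounding.

## Problem sizes used in the shipped checks

The test suite and acceptance script benchmark the pipeline at the
Sperm-seq-matched design — 1000 gametes, 30,000 underlying hetSNPs, 0.01×
coverage, r = 1, ε = 0.005, three independent trials — which runs in
roughly ten seconds per trial on one CPU. The end-to-end extreme-TD
experiment uses 20 replicates of that profile with k = 0.99. Power
estimates use 1000 Monte-Carlo trials per design point. These sizes are
the package's chosen benchmark conditions; all are plain parameters and
scale up directly.

## Known limitations

- Transition probabilities ignore physical inter-SNP distance; on very
  heterogeneous SNP densities a distance-scaled transition would localise
  crossovers better.
- Phasing assumes exactly two haplotypes throughout; aneuploid or doublet
  cells must be removed upstream (metadata-based, out of scope here).
- The simulator's uniform crossover placement and independent errors make
  the crossover benchmarks conservative for interference and optimistic
  for structured artifacts.
- Windows much larger than the chromosome's recombination scale (short
  chromosomes, high r) violate the minority-recombinant assumption; the
  automatic window selector exists precisely for those designs.
- The VIF pruner mirrors the classic sliding-window behaviour, including
  its property that correlated SNPs never sharing a window (step > 1) can
  both survive.
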