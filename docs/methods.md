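# Methods

## The problem

Public RNA-seq archives hold hundreds of chimpanzee samples whose
subspecies, donor identity, and mutual relatedness are unrecorded or
inconsistently recorded.  Genotypes called from the reads themselves carry
enough signal to reconstruct all three, provided the statistics tolerate the
peculiarities of RNA-seq genotyping: heavy, tissue-dependent missingness and
a nontrivial genotype-error rate.  `chimpcensus` implements that
reconstruction as a pipeline of small, individually testable estimators, and
pairs it with a simulator that generates cohorts with known truth so the
pipeline can be validated end to end.

## Simulator

**Population model.**  Subspecies are Balding–Nichols populations: ancestral
alternate-allele frequencies `p` are drawn uniformly on [0.05, 0.5] (the
lower bound avoids near-monomorphic sites), and each subspecies' per-site
frequency is `Beta(p(1−F)/F, (1−p)(1−F)/F)`.  Under this model the expected
pairwise Hudson F_ST between populations with drift `F_A` and `F_B` from a
shared ancestor is `(F_A + F_B)/2`, so the published divergences
(Western–Central 0.29, Western–Eastern 0.32, Central–Eastern 0.09)
parameterize the simulator directly: `F_W = 0.52`, `F_C = 0.06`,
`F_E = 0.12` solve the three printed values exactly.  The Western–
Nigeria-Cameroon divergence is not published; `F_N = 0.10` is a conventional
choice (same clade as Western, modest drift) and not a reconstruction.
Sites are unlinked: every downstream estimator here is a site-independent
method-of-moments or likelihood computation, so linkage would add realism
without exercising any additional code path.

**Individuals and pedigrees.**  An individual with ancestry proportions `q`
has genotype `Binomial(2, Σ_k q_k p_k)` per site.  Offspring are produced by
gamete dropping (one uniformly chosen allele per parent per site), which
makes Mendelian consistency exhaustively checkable; second-degree pairs are
realized as grandparent–grandchild via two rounds of dropping.

**Replicates and noise.**  A replicate sample is the donor's genotype vector
with independent per-genotype missingness (default 5%, the filtering regime
of interest) and uniform dosage resampling at 1% (a deliberately crude error
model — its job is to stress the relatedness threshold, not to model
base-calling chemistry).

**Contaminants.**  Contamination in the emulated setting is reads from a
different species, so the contaminant population draws its *own* ancestral
frequency spectrum (uniform on [0.05, 0.95], i.e. random allele orientation)
before applying drift `F = 0.9`.  A contaminant drifted from the shared
ancestral frequencies was considered and rejected: with one subspecies as
drifted as Western chimpanzees (F ≈ 0.5), such an outgroup's IBS distance to
the cohort saturates around 0.35 while in-group cross-subspecies distances
reach ≈ 0.34 — no robust separation exists in that model, and it is also the
wrong generative story for cross-species contamination.  With an independent
spectrum the contaminant sits near distance 0.5, far beyond any in-group
pair.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium, ascertainment of
sites through expressed transcripts (the simulated site-frequency spectrum
is far more common-variant-rich than RNA-seq reality), reference bias,
batch- or tissue-correlated missingness, and within-subspecies substructure.
The thresholds that are *scale-dependent* therefore transfer differently:
see "Outlier threshold" below.

## Estimators

**IBS distance.**  Allele-sharing fraction `(2·IBS2 + IBS1)/(2n)` over sites
non-missing in both samples, subtracted from 1.  All pairwise counts are
computed as 3×3 dosage-indicator matrix products (BLAS), and are verified in
tests against a per-site double loop.

**Relatedness coefficient.**  `(shared-hets − 2·IBS0)/min(hets_i, hets_j)`,
computed on sites with cohort MAF ≥ 0.25 (common sites carry nearly all of
the heterozygote signal this statistic uses; ~1,000 such sites suffice, and
the module warns rather than refuses below its site floor).  The raw value
is deliberately not truncated — strongly negative values are themselves
diagnostic of non-identity — and ≥ 0.5 marks same-donor pairs.

**IBD (Z0, Z1, Z2).**  Classical method-of-moments inversion: per site, the
expected probability of each IBS class given 0/1/2 alleles shared IBD is
computed from cohort allele frequencies with the standard small-sample
bias-correction factors (ratios of allele counts); summing over sites gives
a linear system that the observed IBS0/1/2 counts invert sequentially.  The
raw solutions are truncated to [0, 1] and renormalized to the simplex.
Frequencies default to the analysis cohort after filtering (a panel can be
supplied instead).  Degenerate sites (frequency 0/1, fewer than 4 alleles)
are skipped; fewer than 200 usable sites triggers a warning.

**UPGMA.**  Hand-rolled average-linkage agglomeration, O(n³), with
deterministic tie-breaking by the lexicographically smallest member ID.
Node heights are cophenetic half-distances, so a cherry's pendant edges
equal half the pair distance.  Tests require cophenetic equality with
scipy's average linkage to 1e-9; the separate implementation exists because
the duplicate-calling rule needs pendant edges and reproducible tie-breaks.

**Duplicate calling.**  Maximal clades with merge height < 0.006 become
clusters; for a pair this is exactly "terminal node edge length < 0.006".
Formulating the rule on clade height (rather than on every leaf's pendant
edge) prevents two distinct tight clusters that merge high up from being
absorbed into one.  Sibling clades failing the edge rule merge only on full
metadata agreement: identical sex and ages within ±1 year, all non-missing
(missing metadata never counts as agreement; the tolerance is configurable
because real usage judged such cases qualitatively).  Representatives: the
member with the highest mean within-cluster relatedness (ties by ID);
size-2 clusters use a seeded random draw.

**Outlier flagging.**  Group-wise rule: connected components of the
"distance ≤ threshold" graph; everything outside the largest component is
flagged, so a clade of mutually similar contaminants is flagged jointly,
not shielded by its own cohesion.  Component-size ties break toward the
component containing the smallest sample ID.  The conventional threshold
for RNA-seq-ascertained genotypes is 0.1; that value presumes the
rare-variant-dominated site spectrum of real RNA-seq calls, where in-group
baseline distances are small.  The simulator draws common variants, so its
in-group baseline is ≈ 0.2–0.35 and the demo census uses 0.42 — the midpoint
between the analytic in-group maximum and the contaminant expectation under
the configured drift values.  This is a property of the site ascertainment,
not a tuning knob: pick the threshold for the spectrum at hand.

**PCA.**  Panel genotypes are centered and scaled per site by
`sqrt(p̂(1−p̂))`, missing values imputed to the site mean, and decomposed by
full SVD; unknowns are standardized with the *panel's* statistics (missing →
0 after centering, so an all-missing sample projects to the origin) and
multiplied onto the loadings.  No projection-shrinkage correction is
applied: the panel is small, and downstream assignments are threshold-based
on admixture proportions, not distance-based in PC space.  This is a known
limitation — projected unknowns are biased slightly toward the origin.

**Supervised admixture.**  With per-subspecies frequencies fixed, each
sample's log-likelihood `Σ_s d_s log f_s + (2−d_s) log(1−f_s)` with
`f = Σ_k q_k p_k` is maximized over the simplex by EM on allele-level
responsibilities; the update is monotone in the likelihood (asserted
stepwise in tests).  Frequencies are clamped to [1e-6, 1−1e-6]; convergence
is a log-likelihood gain below 1e-6 (cap 2000 iterations, non-converged
samples flagged and their last iterate returned).  Missing sites are
skipped.  Two frequency sources exist: the simulator's exact per-subspecies
frequencies (the `ReferencePanel` contract, used in recovery validation) and
empirical frequencies from labeled panel genotypes with a 0.5-allele
pseudocount (the only option for a real VCF panel).  With empirical
frequencies from a 59-animal panel, estimates of the three closely related
low-drift subspecies leak into one another by a few percent — a real
supervised-analysis effect, visible in the demo output, driven by
frequency-estimation noise rather than by the optimizer.

**Ancestry assignment.**  A subspecies is assigned when `q_k ≥ 0.0625`
(inclusive; 1/2⁴ is the expected autosomal contribution of one unadmixed
great-great-grandparent) and a sample is exclusive when `max q > 0.9375`
(strict).  The boundary directions follow the published phrasing of each
rule.

**Kinship classification.**  Thresholds as in the README; precedence
identical > parent/offspring > sibling > second degree.  Only the
sibling/second-degree pair can genuinely overlap (Z1 ∈ [0.4, 0.7) with
Z2 ≥ 0.3, Z0 ≤ 0.4); the sibling rule wins there as the stricter
multi-condition rule.  A documented consequence of the conservative sibling
thresholds is that true full siblings (E[Z] = (0.25, 0.5, 0.25)) frequently
classify as second degree; the test suite asserts they are at least never
called unrelated.  The second-degree lower bound is read as 0.4 (the printed
"04" is taken as a typographical slip, consistent with the 0.7
parent/offspring bound); it is configurable.

**Unrelated set.**  Identical pairs are collapsed first (union over
transitive chains), then first/second-degree edges form a graph and a
maximum-degree node is removed repeatedly until no edge remains.  Degree
ties are broken by a seeded draw, so the surviving count over seed
replicates forms a min–max range, which the census reports (default 10
replicates).

## Pipeline order and problem sizes

`run_census` fixes the stage order: singleton and missingness filters →
outlier flagging (flagged samples leave *all* later stages) → UPGMA
duplicate clustering and replicate collapse → IBD/kinship among unique
individuals → PCA + supervised admixture of all retained samples.
Site-filter boundaries are inclusive keeps (a site at exactly the
missingness threshold survives; MAF ≥ 0.25 keeps the boundary).

The demo cohort uses 12,000 sites, a 59-animal panel, and 60 samples
(55 individuals, three multi-sample donors, one contaminant); after default
filters ≈ 7,700 sites remain, ≈ 2,500 of them at MAF ≥ 0.25.  Calibration
experiments use 50,000 sites for F_ST recovery and 20,000 for IBD/relatedness,
with 50 pairs or 100 trials per estimate.  These sizes put every Monte Carlo
standard error well inside the tolerance asserted for it while keeping the
whole validation suite runnable on a laptop in minutes.

## Degenerate inputs and numerical choices

Pairs with no jointly genotyped site get NaN distances (warned); relatedness
is NaN when either sample has no informative heterozygote; IBD returns NaN
on zero usable sites; PCA refuses panels with fewer polymorphic sites than
components; merging rejects duplicate sample IDs, flips ref/alt-swapped
sites (dosage 0↔2), and drops irreconcilable allele mismatches with a
logged count.  Half-calls in VCF input are treated as missing.  All
stochastic steps (simulation, size-2 representative choice, removal
tie-breaks) flow from explicit integer seeds, and rerunning a census with
the same config and seed reproduces every output byte for byte.

## Known limitations

Beyond the simulator gaps above: no LD pruning before IBD (harmless for
unlinked simulated sites, optimistic for real data); no KING-style
robust kinship (the method-of-moments estimator assumes homogeneous
frequencies and is biased under strong admixture — in practice kinship is
called within the post-ancestry cohort); the unsupervised-admixture
cross-check and local-ancestry inference are out of scope; X-linked and
mitochondrial inheritance are not modeled.
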