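# Methods

## Counting model

Occurrences of a recognition site are counted on the forward strand only,
overlapping, per replicon (windows never span replicon boundaries), and
summed over an organism's chromosomes and plasmids. A site and its reverse
complement are separate words; a palindrome therefore represents both
strands automatically, which is what the complementary-strand noise
estimator (below) exploits. IUPAC-degenerate site letters match their base
sets; a genome letter outside A/C/G/T (assembly gaps and ambiguity codes)
matches only the site letter N. This choice avoids inflating counts in
low-quality assemblies; real pipelines differ here, and on gap-free
synthetic data the rule is exercised only by the unit tests.

The counter encodes bases as bitmasks and site letters as bit unions, so a
length-L word costs at most L vectorised AND/compare passes; positions where
the site letter is N are skipped entirely. A pure-Python window-by-window
scan serves as the independent oracle in the tests.

## Expectations and the contrast ratios

`expected_karlin` implements the maximal-entropy expectation given all
masked subwords as the inclusion–exclusion product

E(W) = ∏ over non-empty S ⊆ {1..L} of N(mask(W,S))^((−1)^(|S|+1)),

where mask(W,S) replaces the positions in S by N and every masked word is
counted as a length-L window (the fully masked word counts the total
windows). Counting masked words at full length, without trimming leading or
trailing N, keeps the identity exact at sequence edges; the edge effect is
O(L / genome length). The exponents sum to 1, so E scales linearly in the
counts and Kr = N(W)/E(W) is exactly invariant under genome duplication —
both properties are asserted in the tests, along with agreement to 1e−12
with the hand closed forms for L = 2 and L = 3. The product is accumulated
in log space; a zero masked count makes the expectation undefined, and such
records are flagged and excluded downstream rather than aborting a run.

`expected_markov` is the maximal-order Markov expectation
N(prefix)·N(suffix)/N(core), each subword counted at its own length, with
the mononucleotide product as the L = 2 fallback. On null cohorts the
variance of Kr is smaller than that of Mr (checked softly on synthetic
controls, since the observation originates from real genomes), which is why
Kr is the primary measure. Expectations are computed on pooled counts
across replicons, not per replicon.

## Classification, reliability filter and noise model

Representation classes use inclusive boundaries: under if Kr ≤ 0.78, over
if Kr ≥ 1.23. The reliability filter requires E(W) ≥ 15, inclusive — the
boundary convention is exposed in `ThresholdConfig` because the prose
definitions around this cutoff are genuinely ambiguous ("more than 15"
versus "15 or more"); the inclusive reading is used throughout.

The filter's justification is recomputable: for each non-palindromic word w
present together with its reverse complement in the same genome, the two Kr
values estimate the same quantity, so each difference divided by √2
estimates the per-site noise. Pairs are binned by expected count (unit-wide
bins, 6.5–7.5, 7.5–8.5, …); a pair is placed by the mean of its two
expectations, since the two single-strand expectations differ slightly.
Sample SDs use ddof = 1; bins with fewer than two pairs are reported as
NaN. On unbiased synthetic genomes the per-bin SD falls as the expected
count grows, reproducing the rationale for the cutoff.

## Datasets and cohort statistics

The prokaryotic control is the full catalogue × genome cross product;
actual pairs are those whose genome encodes an REase (annotation flag
`encodes_rease`) recognising the word, matched by exact word equality after
canonical parsing; the experimentally proven subset requires a
gold-standard annotation or a methylation fraction strictly above 0.5; the
no-R-M subset keeps genomes with empty annotation lists. The subset chain
experimentally_proven ⊆ actual ⊆ control is a tested invariant. At the
reference fixture's scale the control is visibly contaminated by the
planted actual pairs (6 of 108); in genome-scale collections that
contamination is negligible, which is why the same construction is usable
as a null there.

Matched thresholds use the empirical quantile with a lower tie-break: the
largest t with fraction(control Kr ≤ t) ≤ f, so the realised control FPR
never exceeds f; when f < 1/n the threshold sits just below the control
minimum. Y(f) is the actual-stratum fraction below the matched threshold
minus f. Distribution comparisons use the two-sample Kolmogorov–Smirnov
test; fraction comparisons use the chi-square test on the 2×2 table with
Fisher's exact test whenever any expected cell is below 5 (the switching
rule is a convention; both tests are standard here). Kr histograms use 41
equal bins on [0, 2) with an explicit overflow bin, percentages relative to
all pairs.

## Lifespan proxies and traces

A pair is plasmid-encoded only when every REase copy for the word lies on a
plasmid; mixed cases count as chromosome-encoded (the conservative reading —
a chromosomal copy means the system is not purely mobile). Prevalence is
computed per (species, word): rare below 25 % of strains, widespread above
75 %, species with fewer than five strains unclassified; same-word matching
is the proxy for same specificity. Alien-fragment scores: each REase gene
takes the maximal score among fragments overlapping it by at least one base
(the strongest evidence of foreign origin for that locus; the choice
matters only when fragments overlap one gene, which predictors rarely emit)
and 0 when uncovered; a pair takes the minimum over its genes; the
score/threshold ratio is reported in bins NP / (0,1] / (1,2] / >2, with the
edges configurable because the binning is a reporting convention. Trace
labels partition the control: actual, species_trace (actual in another
strain of the species), genus_trace (actual only in another species of the
genus), background.

## The synthetic generator

`synthetic` generates what the analysis consumes: order-0/1/2 Markov
replicons (uniform composition by default), a species/genus strain layout,
chromosome- or plasmid-borne annotations, gold-standard and methylation
evidence, alien-fragment tables with a threshold, and planted site
avoidance. All seeds derive from one root seed via `SeedSequence` spawning,
and a spec regenerates byte-identical files.

Two depletion operations exist, and the distinction is deliberate.
`impose_site_depletion(d)` destroys a fraction d of the current matches by
re-drawing one position per selected window until the window no longer
matches — this controls the destroyed fraction directly and preserves the
background. But destroying an instance of W also removes instances of W's
subwords, so the Karlin expectation shrinks with the observed count: for a
4-mer at uniform composition each destroyed match multiplies E by roughly
exp(−148/n) (n the window count), i.e. destroying a fraction d of matches
realises Kr ≈ (1−d)·e^{0.58d}, not 1−d. Planted ground truth must live on
the scale the study measures, so `impose_avoidance(d)` — what the fixture
builder uses — destroys matches in calibrated batches until the sequence's
own Kr reaches 1−d. Incidental new matches are tolerated as realistic
noise.

The reference study conditions (`default_simulation_spec`): three species
of two genera, six strains each (so prevalence is classifiable), 200 kb
chromosomes and 40 kb plasmids of uniform composition — large enough that a
6 bp site depleted to Kr ≈ 0.4 still clears the E ≥ 15 filter, small enough
that a full fit takes about a second. One widespread chromosome-encoded
system (GGATCC, depth 0.6, depleted also in the annotation-free sixth
strain: the planted lost system), one rare plasmid-encoded recently
acquired system (GAATTC, undepleted, alien score 2.5× the threshold), and
four undepleted catalogue words as compositional controls.

What the generator does not emulate: real compositional heterogeneity
(codon bias, GC skew, repeats), phylogenetic correlation between strains
(strains are independent draws), isoschizomer families (same specificity is
same word), and methylation biochemistry. Passing tests therefore
demonstrate the statistical machinery — counting, expectations,
calibration, stratification — not the biological effect sizes of real
genome collections, whose headline percentages depend on genome-scale
inputs the package ingests but does not ship.

## Numerical and scale choices

Test and acceptance runs use deliberately modest problem sizes — null
calibration on 50 × 1 Mb genomes in the test suite and 30 × 300 kb in the
acceptance script, avoidance recovery on 100 kb replicons where a 4-mer's
expected count is ≈ 390 — chosen so every quantity has sampling noise well
inside its asserted band. `impose_avoidance` stops when the observed count
is within max(1, 0.5 % of E) of its target, or after 12 calibration
rounds. Tie-breaks and boundary conventions (inclusive thresholds,
inclusive E ≥ 15, lower-tie-break quantiles) are stated above and asserted
in tests.

## Known limitations

Degenerate-word palindromy is literal IUPAC-string equality with the
reverse complement (how catalogues write sites such as GANTC), not
set-symmetry of the matched word set. Type precedence beyond "orthodox II
wins; IIC/G beats III" is a fixed convention (orthodox II > IIC/G > III >
I > IIM > IV). P-values for individual word deviations are out of scope by
design — no distributional theory exists for the Karlin ratio — as are live
REBASE/GenBank retrieval and the horizontal-transfer predictor itself
(only its output table format is ingested).
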