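# rmavoid

Restriction–modification (R-M) systems pair a restriction endonuclease
(REase) with a methyltransferase sharing one recognition site. A genome that
hosts such a system pays a price for every copy of the site it carries: an
occasionally unmethylated site is cleaved, so selection slowly removes the
site from the genome. `rmavoid` quantifies this *site avoidance* in
prokaryotic genome collections and stratifies it by R-M system type,
palindromy, and proxies of how long a system has resided in its genome
(plasmid vs chromosome, prevalence among conspecific strains, compositional
evidence of recent horizontal transfer, and traces left by lost systems).

It is aimed at comparative genomicists who have genome sequences, a
recognition-site catalogue and per-genome R-M annotations (e.g. derived from
REBASE), and want reproducible under/over-representation statistics rather
than one-off scripts.

## The statistic

For a site word W of length L (possibly IUPAC-degenerate, e.g. `GANTC`),
occurrences are counted on the forward strand, overlapping, per replicon.
The deviation measure is the contrast ratio

    Kr = N(W) / E(W)

where E(W) is Karlin's maximal-entropy expectation given all masked
subwords of W, realised as an inclusion–exclusion over the positions:

    E(W) = ∏_{∅ ≠ S ⊆ {1..L}} N(mask(W,S))^((−1)^{|S|+1})

with `mask(W,S)` the word with the positions in S replaced by N, every
masked word counted as a length-L window. For L = 2 this is the familiar
N(w₁·)N(·w₂)/T; the exponents sum to 1, so Kr is invariant under genome
duplication. The maximal-order Markov analogue
Mr = N(W) / [N(W₁..L−1) N(W₂..L) / N(W₂..L−1)] is computed for comparison;
Kr scatters less on control cohorts and is the primary measure.

A pair (site, genome) is **underrepresented** when Kr ≤ 0.78 and
**overrepresented** when Kr ≥ 1.23 (boundaries inclusive), and is only
trusted when E(W) ≥ 15 — below that the ratio is too noisy, as the package's
complementary-strand SD procedure shows. Because palindromic and
non-palindromic sites have different null Kr distributions, strata are
compared at *matched thresholds*: fix a false-positive fraction f and give
each stratum the Kr cutoff at which exactly f of its control pairs fall
below; Y(f) = (actual fraction below the cutoff) − f then estimates the
avoidance attributable to R-M systems.

## Worked example

```python
from rmavoid import SiteAvoidance
from rmavoid.synthetic import build_fixture_collection, default_simulation_spec

fx = build_fixture_collection(default_simulation_spec(seed=1))
model = SiteAvoidance(
    genomes=fx.genomes, catalogue=fx.catalogue,
    methylation_calls=fx.methylation,
    alien_fragments=fx.alien_fragments, alien_threshold=fx.alien_threshold,
)
res = model.fit()
print(res.summary())
```

```
Site-avoidance analysis
============================================================
genomes: 18   catalogue sites: 6
thresholds: under Kr <= 0.78, over Kr >= 1.23, min expected 15.0

Pairs per dataset (passing the expected-count filter / total):
  actual                      6 /      6
  experimentally_proven       6 /      6
  prokaryotic_control       108 /    108
  no_rm_control              72 /     72

Representation fractions by R-M type and dataset:
              dataset     rm_type  n_pairs  fraction_under  fraction_over
               actual II_orthodox        6           0.833          0.000
experimentally_proven II_orthodox        6           0.833          0.000
  prokaryotic_control II_orthodox      108           0.056          0.000
        no_rm_control II_orthodox       72           0.014          0.000
```

The reference collection plants a widespread, chromosome-encoded system
whose site (`GGATCC`) is depleted in every carrier, and a rare,
plasmid-encoded, recently acquired system (`GAATTC`, undepleted, covered by
a high-scoring alien fragment). The fit recovers exactly that structure:
5/6 actual pairs underrepresented (the undepleted plasmid pair is the
exception), a 5.6 % control rate driven by the planted pairs themselves, and
`res.lifespan_summary()` / `res.trace_groups()` show 100 % avoidance for the
widespread and chromosomal strata, 0 % for rare and plasmid, and the
annotation-free sixth strain carrying the *lost system's* trace
(`species_trace`, Kr ≈ 0.41, underrepresented).

Fixture collections can also be written to FASTA/TSV and analysed from the
shell:

```sh
rmavoid simulate spec.yaml fixture/
rmavoid analyze run.yaml
```

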