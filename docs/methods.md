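# Methods

## The question the package addresses

Grab sampling — one bottle of water at one instant — is the default way to
collect eDNA, but eukaryotic eDNA travels as patchy, cell-sized particles, so
replicate grabs can disagree badly about taxon proportions.  Compositing many
small aliquots over a time interval should average over that patchiness.  The
package implements the full analysis needed to test this: taxonomic
assignment of OTUs, count-table hygiene, and the statistics that compare the
two schemes (dispersion of community profiles, rarefaction richness,
detection rates, and the precision of a two-taxon relative-abundance
estimate), together with a generative model of the deployment so every stage
can be validated against known truth.

## LCA assignment

An OTU's hit table is reduced to the best HSP per subject accession (one
reference sequence, one vote), floored at a per-locus minimum bit score, and
windowed: HSPs with `bit ≥ (1 − w)·best` participate, the boundary inclusive
so results do not depend on floating-point luck.  The assignment is the
deepest taxon ancestral to all participating hits.  Mean percent identity of
the participants then acts as a plausibility screen: a species call with mean
identity below 95 % is demoted to the nearest genus ancestor, a genus call
below 90 % to the nearest family ancestor.  Because reference taxonomies are
rank-sparse, "nearest ancestor" walks upward to the first node at or above
the target rank — but never above family: if no such node exists the OTU is
reported unassigned rather than at a rank the evidence cannot support.  The
12S locus, too short to separate many fish species, additionally gets a
watershed constraint: within the ray-finned fishes, hits to taxa not on an
expected-species list are removed and the LCA re-run (hits outside the clade
are untouched, so a bird assignment passes through unchanged).  Ordered
post-hoc adjustments (remove / rename / merge) handle known artifacts such as
feed-derived taxa; an adjustment that matches nothing is an error, not a
no-op.

## Filtering rules and their defaults

* **Run-wide minimum count, default 10.**  A deliberately conservative
  alternative to singleton removal: cross-talk between multiplexed samples
  and PCR artifacts inflate diversity, and that inflation is worse for the
  study's questions than the loss of genuinely rare OTUs.
* **Length windows** per locus: COI 312–379 nt, 16S ≥ 350 nt, 12S > 75 and
  ≤ 170 nt (inclusive integer bounds).
* **Cross-talk censor**: a taxon is kept only if its run total is ≥ 10 *and*
  it has ≥ 2 reads in at least one sample.  Taxa present only as scattered
  per-sample singletons are the signature of sequencer cross-talk from
  co-multiplexed libraries.
* **Rank collapsing** conserves per-sample totals exactly; lineages without
  the target rank get operational labels (genus + " incertae sedis" for
  family-less bacteria; "… genus BOLD:XXX" for barcode-database-only
  species).  **Top-N** restriction ranks by summed cpm with deterministic
  lexicographic tie-breaks.

## Comparison statistics

**Morisita dissimilarity** is computed from raw integer counts (the index is
count-based by construction; non-integer input is an error).  It was chosen
because sequencing effort differs systematically between methods — grab
events are pools of three separately sequenced replicates — and Morisita's
overlap is nearly independent of sample size.  At small counts the index can
exceed 1 (dissimilarity slightly negative); this is a property of the
unbiased λ estimator, not a bug, and the principal-coordinates machinery
downstream handles the resulting non-Euclidean structure.

**Rarefaction** uses the hypergeometric expectation computed via log-gamma
(stable for totals in the 10⁵ range) and the exact variance of rarefied
richness, including the pairwise covariance term; SE is exactly 0 at full
depth.  Pooled per-sampler richness parity-trims the larger method's
time-ordered sample list — floor(excess/2) from the start, the rest from the
end, which reproduces a 22→15 trim as drop-3-start/drop-4-end and 22→18 as
2/2 — then rarefies every sampler's pooled counts to the smallest total.

**Dispersion to centroid** double-centers the squared dissimilarities and
eigendecomposes; axes with negative eigenvalues contribute negatively to
squared centroid distances (clamped at zero).  Centroids are arithmetic means
in the embedding.  Two-group tests: a pooled-variance permutation *t* test
(group labels permuted over distances, 9 999 permutations by default, seeded,
`p = (hits + 1)/(B + 1)`) and a Mann–Whitney *U*.  Raw distances are
permuted, not residuals.

**Ratio analysis** computes S/(S+C) per sample per locus after pooling grab
replicates (the pooled fraction is algebraically the count-weighted mean of
replicate fractions); estimates with S+C < 20 are flagged and excluded from
inference because proportions from few reads carry high standard error.  The
two loci enter as independent estimates.  The variance *F* test doubles the
smaller tail of the F(n₁−1, n₂−1) distribution; the two-way ANOVA is fit by
OLS with Type II sums of squares by default (Type I available), the two being
identical on balanced data.

**Ordination** adds a single global pseudocount — half the smallest non-zero
proportion in the matrix — to every cell, takes natural logs without
renormalizing, and runs PCA on the taxon correlation matrix (so the result is
invariant to per-taxon affine rescaling).  A CLR variant is available.  Sign
convention: each axis's largest-magnitude loading is positive.

## The generative model

Particle capture is compound-Poisson: clusters arrive Poisson with rate
`flux·volume/m` and carry geometric sizes with mean `m = 1 + 1/k`, giving
variance/mean `= 1 + 2/k` within a collection; `k = ∞` is pure Poisson.
Clumping also acts across time: every collection instant carries a gamma
patch factor (mean 1, variance 1/k) multiplying the local intensity, and
collections at the same instant share it.  This is the decisive asymmetry
between the schemes: the three consecutive grab replicates of an event sample
one parcel of water (one patch draw), while the 12 aliquots of a composite
bottle, spread over 3 h, sample twelve independent parcels.  Without this
temporal structure a pooled grab event (1 500 mL) would always beat a 540-mL
composite, and the phenomenon the analysis is built to measure could not
exist in the simulation.

Defaults (units, value, why):

* **Schedules** — 22 composite bottles/site (12 × 45 mL at 15-min intervals,
  3 h per bottle); triplicate 500-mL grabs every 6 h downstream, 12 h
  upstream; a `paper_variant` reproduces the unbalanced 15 + 18 grab set of
  the original deployment (77 bottles total).
* **Fish classes** — *Salmo* and *Coregonus* at both 12S and COI, flux ratio
  3.854 (upstream fraction 0.794), retentions 0.39 vs 0.90 per 100 m so the
  downstream fraction falls to ≈ 0.627.  They share one patch group: the
  rearing-facility effluent is premixed, so their ratio is insensitive to
  patchiness even though their absolute counts are not.
* **Clumping** — k = 0.4 for the effluent classes, k = 4 for rare resident
  eukaryotes, Poisson for bacteria.  No field estimate of k exists; these
  values were chosen once to reproduce the qualitative regime the design
  presumes — strong patchiness in the concentrated effluent plume driving the
  dispersion contrast, moderate patchiness for diffusely shed resident taxa.
  With k < 1 for rare taxa, zero-inflation of grab bottles makes composite
  detection rates consistently higher, contrary to the detection-parity
  regime; k = 4 keeps detection method-neutral while the dispersion contrast
  (driven by the abundant classes) remains strong.
* **Rare taxa** — 20 COI invertebrate genera (chironomid-dominated), 6 rare
  12S vertebrates, 5 eukaryotic-16S phytoplankta, geometric flux tails.
* **Bacteria** — 150 families, power-law rank abundance (exponent −1.2),
  total 10⁴ cells/mL, Poisson capture.  Flavobacteriaceae blooms in cold
  storage: logistic growth factor `cap/(1 + (cap−1)e^{−rh})` with r = 0.12/h
  and cap = 200 over hours stored (bottles are recovered at run end, so the
  earliest-initiated bottles store longest).  Eukaryotic loci decay in
  storage at 0.035/h (COI, euk-16S) and 0.005/h (the much shorter 12S
  amplicon), rates set so the earliest COI count rates fall to roughly a
  tenth of the latest.
* **Reads** — multinomial at fixed per-locus library sizes (136 634 bacterial
  16S, 2 076 COI, 831 12S, 32 euk-16S per sample), deliberately decoupling
  input DNA mass from sequencing depth as library preparation does.
  Cross-talk moves each read to a random other sample with probability 10⁻³,
  and five "foreign" 12S taxa (abundant elsewhere on the shared flow cell)
  leak sparse Poisson singletons, giving the censor rule real work.
* **Seeding** — one `numpy` Generator drives everything; identical seeds give
  byte-identical count tables.

### What the generator does *not* emulate

No hydrodynamic transport (sites are independent draws, not advected copies),
no PCR amplification bias beyond the constant per-taxon factor implicit in
flux, no extraction or library-preparation variance, no within-taxon OTU
structure.  Consequences worth knowing: simulated fraction variance comes
only from particle and read sampling, so the composite-vs-grab variance *F*
can reach significance in either direction, whereas the field data's
method-neutral noise sources (amplification, extraction) dominated there; and
the bacterial PCA concentrates far more variance on axis 1 than real profiles
do, because the bloom is the only systematic bacterial gradient.  Passing
simulation tests therefore demonstrates the estimators and the qualitative
sampling-scheme physics, not field-data effect sizes.

## Numerical choices

Rarefaction via `gammaln` differences; window and length bounds closed;
Morisita requires totals ≥ 2; PCoA eigenvalue threshold 10⁻¹⁰ with negative
contributions clamped at zero; permutation p-values use the add-one rule;
top-N and adjustment processing are order-deterministic; zero-total samples
are dropped from cpm with a logged warning (the study's low-16S outliers
motivate tolerance here); an empty HSP list yields "unassigned", not an
exception, while structural taxonomy errors (cycles, missing parents,
multiple roots) raise.

## Estimator bias noted

The retention differential is recovered by inverting site-mean fractions into
an odds ratio.  Averaging per-sample fractions before transforming is mildly
non-linear (Jensen), biasing the recovered ratio upward by ~2 % at study
scale; the parameter-recovery check therefore compares against the
Monte-Carlo spread of whole-study estimates rather than the standard error of
their mean.  The bias is a property of the natural estimator, kept rather
than corrected.

## Known limitations

The LCA assigner consumes hit tables; it does not run alignments.  Bacterial
family labels are consumed as input (classifier training is out of scope).
The dispersion permutation test assumes exchangeability of distances under
the null, which ties in heavily structured designs could weaken.  Problem
sizes in tests and the acceptance script (150 bacterial families, 9 999
permutations, 20-seed recovery loops) were chosen to characterize the
estimators well at interactive runtimes.
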