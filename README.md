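# ednabench

Analysis toolkit for comparing **composite** and **grab** water sampling in
eDNA metabarcoding, built around a paired-autosampler study design: at each of
two stream sites, one autosampler composites 12 × 45 mL aliquots over 3 h into
each bottle while its twin takes triplicate 500-mL grab samples, and both are
profiled at three barcode loci (12S for vertebrates, COI for metazoans, 16S
for bacteria).  The package is aimed at molecular ecologists designing eDNA
sampling schemes and at anyone re-analyzing multi-locus amplicon count tables
from paired sampling designs.

## What it computes

**Taxonomic assignment.** A windowed lowest-common-ancestor (LCA) assigner for
BLAST-style hit tables: HSPs below a bit-score floor are dropped, only the
best HSP per subject accession is kept, and the OTU is assigned to the deepest
taxon ancestral to every hit scoring within a fractional window of the best
score, `bit ≥ (1 − w)·max`.  Percent identity acts as a secondary filter:
species-rank assignments require mean identity ≥ 95 %, genus ≥ 90 %, with
failing assignments demoted one rank (never above family).  Locus presets:
COI/eukaryotic-16S (floor 250, w = 0.05) and 12S (floor 200, w = 0.02, with a
watershed-constrained re-assignment inside the ray-finned fishes).

**Table filtering.** Run-wide minimum-count retention (≥ 10), per-locus
length windows, cross-talk censoring (a 12S taxon is kept only with total
≥ 10 *and* ≥ 2 reads in some sample), rank collapsing with operational
labels ("*genus* incertae sedis", BOLD operational genera), top-N restriction
by library-normalized abundance, and counts-per-million.

**Comparison statistics.** Morisita dissimilarity `1 − C` with
`C = 2Σxᵢyᵢ / ((λₓ+λᵧ)NₓNᵧ)`, chosen for its insensitivity to sample size;
individual-based rarefaction `E[Sₙ] = Σᵢ[1 − C(N−Nᵢ,n)/C(N,n)]` with the
exact Heck–van Belle–Simberloff variance; dispersion to the method centroid in
a principal-coordinates embedding (negative eigenvalues handled by the
imaginary-axis convention) tested by a seeded permutation *t* test and
Mann–Whitney *U*; parity-trimmed detection rates; the *S/(S+C)* fraction of
*Salmo* among *Salmo*+*Coregonus* reads with a two-sided variance *F* test,
two-way ANOVA (site × method) and time correlations; and log-ratio
correlation PCA of bacterial family profiles.

**Synthetic deployments.** A generator that simulates the whole study with
known ground truth: compound-Poisson particle capture with geometric clusters,
gamma patch factors shared by collections at the same instant (consecutive
grab replicates sample one water parcel; composite aliquots 15 min apart
sample independent parcels), per-taxon downstream retention (differential
settling), cold-storage decay plus a psychrophilic bacterial bloom, fixed
per-locus library sizes, and flow-cell cross-talk singletons.

## Worked example

Simulate the study-scale deployment and run the headline comparison:

```sh
python analysis/01_simulate_study.py
python analysis/04_community_metrics.py
python analysis/05_ratio_precision.py
```

prints (seed 11):

```
eukaryotes: composite dispersion 0.0311 vs grab 0.3744 (permutation p = 0.0001, Mann-Whitney p = 0.0011)
bacteria:   composite 0.0767 vs grab 0.0764 (p = 0.9742) - no method effect expected

site means of the Salmo fraction:
                mean       sem  size
downstream  0.628317  0.008009    54
upstream    0.789381  0.015271    54
```

Composite samples of clumped eukaryotic eDNA sit an order of magnitude closer
to their group centroid than pooled grab triplicates — compositing averages
over particle patchiness — while the evenly dispersed bacteria show no method
effect.  The *Salmo* fraction falls from ~0.79 upstream to ~0.63 downstream
because the *Salmo*-like eDNA class settles out faster (simulated retention
0.39 vs 0.90 per 100 m); both sampling methods recover the same means.

The same steps are available as a CLI (`ednabench simulate|assign|filter|
richness|dissim|dispersion|detect|ratio|pca|run`) and as library functions
under `ednabench.*`.

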