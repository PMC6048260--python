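# Methods

## Scope and data model

`halopond` implements the downstream statistics of a hypersaline-pond
microbiome survey: it starts from an OTU count table (OTUs × samples, with
per-sample pond, water/sediment fraction, and salinity metadata), a
taxonomy table with contaminant flags, and optionally CAZy-annotated
protein sequences. Upstream stages — OTU picking, taxonomy assignment,
assembly, binning, HMM annotation — are out of scope; their outputs are
this package's inputs.

## QC filters

Applied to raw counts, in order: (1) drop OTUs with total reads below
`min_total` (default 10); (2) drop contaminant-flagged OTUs (default flag
`chloroplast`), reporting the removed read fraction per sample; (3) drop
samples with fewer than `min_depth` (default 500) total reads. Relative
abundances are computed only after all QC, so filters never see
renormalised data. The chain is idempotent, and each table records its
filter provenance. An OTU absent from the taxonomy is an error rather than
silently retained: it cannot be judged clean.

## Diversity

Richness is the count of observed OTUs; Shannon entropy is in nats;
evenness is Pielou's H/ln S. For S ≤ 1 the ratio is 0/0 and is **defined
as 0** to keep the metric total and plot-safe. Diversity is computed on
raw (unrarefied) counts by default; the depth differences the simulator
produces are handled by the shallow-sample filter instead. Bray–Curtis
dissimilarity is computed between relative-abundance columns (scipy's
implementation; a brute-force double loop verifies it in the tests at
1e-12). The dendrogram uses average linkage (UPGMA) by default — the
linkage is configurable since the choice is not determined by the
procedure — and is cut at **dissimilarity** height 0.6; the cut is a
parameter because similarity-vs-dissimilarity conventions vary between
descriptions of such cutoffs. Cluster letters are assigned in order of
first sample appearance.

## Co-occurrence sub-networks

- Prevalence filter: strictly more than `min_reads` (10) reads in at least
  `min_samples` (5) samples, applied to the QC'd counts (i.e. after
  shallow samples are gone, so "5 of 16" refers to the retained samples).
- Correlation: Pearson r between OTU relative-abundance rows over **all**
  retained samples, zeros included — a single network on one common sample
  support, not pairwise-complete subsets. Two-sided p-values use the
  t-transform with n − 2 df. Zero-variance OTUs have undefined r; they
  remain nodes but can form no edge and end up unaffiliated.
- Multiple testing: Benjamini–Hochberg step-up over the full set of unique
  tested pairs, implemented directly as q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ min(1, p₍ⱼ₎·m/j)
  with a stable sort so ties share q. The implementation is cross-checked
  against statsmodels (1e-12) and against an independent step-up
  evaluation (exact) in the tests.
- Edge rule: r > `r_min` (0.98) **and** q < `q_max` (0.05), both strict, so
  r = 0.98 exactly is not an edge. The rule is monotone: loosening either
  threshold can only add edges. Only positive correlations can qualify.
- Sub-networks: connected components; those with **more than**
  `min_major_nodes` (10) nodes are major and lettered by descending node
  count with a deterministic tie-break (lexicographically smallest member
  OTU id). A size-10 component is unaffiliated. Since the conventional A–G
  letters in such studies encode pond association rather than size,
  `CooccurrenceResults.relabel_by_dominant_site()` re-letters majors by
  the site where each peaks.
- Attribution: per (label, sample) summed relative abundance, with a
  `filtered` row carrying the mass of OTUs that failed the prevalence
  filter, so columns total exactly 1; per-site means and standard
  deviations are taken over replicate samples.

Edges are read as shared habitat preference along the salinity gradient —
the seed-bank interpretation — never as ecological interactions. Pearson
on relative abundances ignores compositional coupling; a
compositionality-aware estimator (SparCC-like) is a documented
non-feature.

## Isoelectric points and CAZyme profiles

Net charge is the Henderson–Hasselbalch sum over ionizable side chains
(D, E, C, Y acidic; H, K, R basic) and both termini, with residue
multiplicities. Q(pH) is strictly decreasing and always brackets zero on
(0, 14), so bisection finds the unique pI; the interval tolerance is 1e-6
pH units, which keeps |Q(pI)| < 1e-3 even for large proteins where the
charge curve is steep (a 1e-4 interval would not). The shipped pKa set
(C-term 3.6, D 3.9, E 4.1, H 6.5, C 8.5, N-term 8.6, Y 10.1, K 10.8,
R 12.5) is the EMBOSS-style default and is an editable JSON config;
changing it shifts pI values by tenths of a unit but never breaks the
zero-charge property. Ambiguous residues (X, B, Z, …) contribute no
charge; a strict mode rejects them. Acidity is pI ≤ 5.0 **inclusive**.

Profiles use all annotated CAZymes in a sample as the denominator (not
per-class denominators); GH substrate fractions use GH records only. The
family → substrate map ships as an editable TSV covering the families a
pond survey typically reports (GH5/6/8/9/12/44/45/48 cellulose,
GH1/2/3/31 oligosaccharides, GH13/15/57/77/27 starch, GH32/68 fructans,
GH30/10/11 xylans, GH16/28 plant polysaccharides, GH18/19/20 chitin,
GH23/74 mixed); unmapped families are `other`. Salinity association is
Pearson by default (Spearman behind a flag, since the appropriate
statistic is not dictated by the data model), BH-corrected within each run
and computed separately for water and sediment samples; significance is
q ≤ 0.05 inclusive. Constant features are excluded from testing and
flagged.

## Synthetic data

The community generator is the validation substrate, not a sequencing
simulator. Per sample, each planted block k contributes mass
P[k, site]·g, where P is the block × site mean-abundance profile and
g ~ lognormal(0, σ²) is shared by all block members in that sample; member
OTUs keep fixed lognormal(0, 0.5²) relative weights with per-observation
lognormal jitter at σ/4. The shared factor plus the cross-site dynamic
range make within-block Pearson r exceed 0.98 at realistic noise
(σ = 0.1), while background OTUs — independent heavy-tailed base
abundances (lognormal σ = 1.5), smooth per-site affinities (lognormal
σ = 0.5), and independent per-sample noise — essentially never reach that
regime in 16 samples. Counts are multinomial at the configured depth, so
depth is conserved exactly and expected fractions sum to 1 by
construction. One `numpy` Generator seeded once drives every draw.

Default scale mirrors the survey design the package targets: 3 ponds at
2.5 / 7.5 / 33.2 % salinity × water/sediment × 3 replicates (18 samples),
two high-salinity sediment replicates shallow (300 / 250 reads, below the
500-read cutoff, leaving 16), ~2,500 OTUs of which 7 blocks
(40…12 members) carry ≈ 60 % of planted mass (≈ 69 % of retained reads
after contaminant removal), and 39 chloroplast OTUs injected at per-site
fractions of 19.7 / 1.7 % (water) and 1.1 / 0.24 % (sediment) of reads,
none at the high-salinity pond. Tests and the acceptance checks run a
reduced scale (4 blocks × 15 OTUs + 200 background OTUs) to keep the
suite fast at desk scale; the structure, not the size, is what the checks
exercise.

The protein generator draws sequences from a D/E-enriched (≈ 24.5 %
D+E, ≈ 2.4 % K+R) or K/R-enriched (≈ 5.8 % D+E, ≈ 17 % K+R) composition so
each record's intended acidity class is realized with > 95 % fidelity;
the realized pI ≤ 5 fraction therefore converges to the requested target
(binomial error ≈ ±0.011 at n = 2000). Survey-scale generation assigns
per-site targets of 27.0 / 42.0 / 81.4 % (water) and 36.0 / 38.2 / 46.3 %
(sediment), the acidic-proteome gradient such ponds exhibit.

What the simulator does **not** emulate: compositional closure effects
beyond the multinomial draw, phylogenetic correlation between OTUs,
sequencing error and chimeras, real CAZy family length/composition
signatures, and block overlap (each OTU belongs to at most one block).
Passing the planted-recovery checks therefore demonstrates the
procedure's correctness and its statistical behaviour under the stated
noise model — not performance on real amplicon data.

## Numerical and design choices

- BH is authored in-package (p·m/rank with a right-to-left running
  minimum) because the exact step-up arithmetic is part of the contract;
  library implementations that compute p/(rank/m) differ in the last ulp.
- fcluster's cophenetic-distance criterion implements the dendrogram cut;
  cut = 0 yields singletons among distinct samples, cut ≥ max height one
  cluster, and samples merged at height 0 (identical columns) are never
  split at any positive cut.
- Graph construction sorts nodes and edges, letters are assigned
  deterministically, and all writers emit sorted, timestamp-free output:
  a rerun with the same seed and config is byte-identical.
- Degenerate inputs fail loudly: zero-sum samples in normalisation, all
  samples below the depth cutoff, empty protein sets, p-values outside
  [0, 1], fewer than 3 samples for any correlation.

## Known limitations

Pearson-on-fractions compositionality (above); no rarefaction (exposed as
a deliberate non-default); single-linkage-free but otherwise standard
agglomerative clustering with no bootstrap support values; pI model
ignores cysteine disulfides, post-translational modification and local
electrostatic environment; the salinity correlation treats replicate
samples as independent observations, as the small per-fraction n
(typically ≤ 9) leaves no room for a mixed model.
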