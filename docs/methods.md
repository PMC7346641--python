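# Methods

`hgtnet` analyzes horizontal-gene-transfer (HGT) networks built from
breakpoint-pair event tables, as produced by an upstream split-read
breakpoint caller run on gut metagenomic sequencing data. This note records
the models, the parameter choices that matter, the numerical decisions, and
what the synthetic cohort does and does not emulate.

## The HGT network model

An HGT event links two segments of two different reference genomes through a
pair of breakpoints observed in one sample. The per-sample HGT network is
the weighted undirected graph whose nodes are the reference genomes linked
by at least one event and whose edge weight is the number of events between
the two genomes. Networks are undirected because the caller does not orient
donor versus recipient; nodes are genome assemblies (one accession per
taxon), not scaffolds.

Events are stored canonically with the lexicographically smaller accession
on side *a*. Cross-sample event identity is defined by binning breakpoint
coordinates into fixed windows: two events are "the same" iff they link the
same genome pair and both breakpoints fall in the same bin. The default bin
width is 100 bp (`bin_size`, configurable); split-read breakpoints jitter by
a few base pairs, and no exact tolerance is dictated by the upstream caller,
so this is an explicit design choice of the package. Binning uses
`floor((pos − 1)/bin_size)` so that position 1 (coordinates are 1-based
throughout, GFF3 convention) falls in bin 0. Venn-style group overlaps count
*distinct* event keys per group (deduplicated within group), so cells count
events, not occurrences.

## Scale-free structure

The degree distribution of a scale-free network follows P_k ∝ k^(−α); for
2 < α < 3 the network is an ultra-small world whose diameter grows like
ln ln N. Degrees are counts, so the package fits the *discrete* power law

    p(k) = k^(−α) / ζ(α, x_min),  k = x_min, x_min + 1, …

by maximum likelihood (Hurwitz-zeta normalization; α optimized by bounded
scalar search on (1.0001, 12)). The lower cutoff x_min is scanned over all
observed degree values and chosen to minimize the Kolmogorov–Smirnov
distance between empirical and fitted tail CDFs (Clauset-style selection).
The continuous closed form α̂ = 1 + n/Σ ln(x_i/x_min) is retained as an
analytic cross-check mode and as a test oracle only.

Three heavy-tailed alternatives are fitted on the *identical* tail
(k ≥ x_min): exponential, Weibull, and lognormal with non-negative location
μ. The μ ≥ 0 constraint follows from the data domain: degrees are ≥ 1, so
the fitted median e^μ must be ≥ 1. When the unconstrained optimum would be
negative the fit is returned at μ = 0 with an explicit `constraint_bound`
flag — never clipped silently. Alternatives use the standard discretization
of the continuous family, p(k) ∝ F(k+½) − F(k−½), renormalized over
k ≥ x_min; for the exponential this reduces exactly to the geometric
distribution, whose MLE is closed-form.

Model comparison uses the normalized (Vuong) log-likelihood ratio: with
pointwise differences d_i = ln p_PL(k_i) − ln p_ALT(k_i), the statistic is
Σd_i / (σ_d √n) and the two-sided p-value comes from the normal
approximation. A positive ratio prefers the power law. Tails shorter than
50 points return "undecided": below that the sign of the ratio is noise.
Group-level α comparisons use the classical pooled-variance two-sample
Student's t-test (two-sided) with t-based 95% confidence intervals.

The diameter–lnln N trend is an ordinary least-squares fit of the exact
diameter (computed on the largest connected component with an
extrema-bounding search) against ln ln N over networks with N ≥ 3.
Disconnected networks use their largest component; all-equal sizes raise a
degenerate-regression error.

## Network complexity and event rate

Complexity uses the simplified von Neumann entropy

    H_VN = 1 − 1/|V| − (1/|V|²) · Σ_{(u,v)∈E} 1/(d_u d_v),

with unweighted degrees (E is the edge *set*; event multiplicity does not
enter) and each undirected edge counted once. H_VN is 0 for a single node
and bounded above by 1 − 1/|V|.

The HGT event rate normalizes a sample's event count H for sequencing
effort: H̄ = ln(H / (Σr_i / Σl_i)), where r_i is the uniquely-mapped read
count and l_i the length of genome g_i, summed over the genomes linked by
events; Σr/Σl approximates average read depth in reads per base pair. The
rate is undefined for H = 0 or zero mapped reads, and these raise errors
rather than returning sentinels.

## Network similarity

Membership similarity is the Jaccard index of node sets. Topological
similarity is the Spearman rank correlation of a per-node property (degree,
PageRank with damping 0.85 and tolerance 1e-9, or unweighted local
clustering coefficient) computed per network and restricted to the shared
nodes; at least three shared nodes are required. The combined score is
Jaccard × degree correlation; when the correlation is undefined because
fewer than three nodes are shared, the combined score is defined as 0 with
an explicit flag so group sweeps never drop pairs silently — a nearly
node-disjoint pair *is* maximally dissimilar for this purpose. Weighted
degrees are not used anywhere in similarity; this is a documented choice,
not an inference. Within- versus between-group similarity is compared with
the two-sample Student's t-test (one-sided p for "within greater" is also
reported).

## Communities, HCCs, HECs, and labeling

Per-sample communities come from the Leiden algorithm (modularity-style RB
configuration quality, resolution 1.0 default, event multiplicities as edge
weights, explicit seed; two refinement iterations). The contract is
partition quality and determinism per seed, not a specific implementation.

Communities from all samples are clustered into HGT community clusters
(HCCs) by average-linkage hierarchical clustering of 1 − Jaccard distances
between member sets, cut at height 0.6 (exposed as a flag; the cut height
parallels the event-cluster setting), with clusters below 2 members moved
to an unclustered pool — a "cluster" of one community is noise. Input order
cannot affect the result: communities are sorted canonically before
distances are computed.

HGT event clusters (HECs) treat each distinct event key as its set of
samples (presence, not abundance — multiple occurrences in one sample count
once). Events present in fewer samples than the minimum prevalence are
filtered out (5 for the mother–child design, 4 for the IBD design,
available as presets); distances are 1 − presence-Jaccard; the average
linkage dendrogram is cut at height 0.6 with minimum class sizes 10 and 20
respectively. The tree cut is implemented as a fixed-height cut followed by
the minimum-size gate, which keeps the procedure deterministic; adaptive
per-branch splitting is deliberately not used.

Because groups contribute unequal numbers of samples, cluster labels use
the bias-corrected rule: label = argmax over groups of
COUNT(label)/num(label), where COUNT is the number of member communities
(for HCCs) or member-event sample occurrences (for HECs) carrying the
label, and num is the number of samples with that label in the dataset.
Ratios are compared exactly as rationals, so the rule is scale-invariant by
construction; exact ties return "ambiguous" rather than forcing a side.

Composition profiles preserve multiplicity: an HCC pools its member
communities' genome sets with repeats (G_i as a multiset); an HEC counts
both endpoint genomes of every member event, so each event contributes two
genus observations. Fractions always sum to 1. Per-taxon group differences
use the two-sample Student's t-test on per-cluster fractions, with absent
taxa counted as fraction 0.

## Fusion genes

A fusion gene is called when both breakpoints of an event fall inside
annotated genes on their respective genomes. Containment is inclusive on
both ends ([start, end], 1-based); strand is recorded but ignored — a
breakpoint is strandless. When several genes overlap a breakpoint, every
gene pair is reported, but event-level summaries count each event once, so
totals are not inflated. A genome without annotations is intergenic
everywhere. Function summaries count, per distinct product description, the
number of fusion events containing a gene with that product (an event whose
two genes share a product increments it once).

## Synthetic cohort generator

The generator emulates the structure of two longitudinal gut-metagenome
study designs at desk scale: a mother–child design (default 10 families;
children sampled at five time points with network sizes growing
40→65→100→145→200; mothers at three time points, flat at 350 nodes) and an
IBD design (CD/UC/Non-IBD patients sampled longitudinally, flat sizes).
These sizes are roughly an order of magnitude below the sequenced cohorts
they mimic, chosen so every pipeline stage runs in seconds while leaving
enough tail for the degree-distribution machinery; they are the package's
standing test conditions and are not tuned per test.

Scale-free backbones use preferential attachment with initial
attractiveness a = m(α_target − 3), which tunes the asymptotic degree
exponent to α_target (defaults: mothers 2.8, children 2.4, inside the
ultra-small-world band). Exact finite-size exponent matching is not
promised; the recovery tolerance (median fitted α within ±0.3 of target at
2000 nodes) is asserted instead. Each backbone edge becomes
1 + geometric(0.6) event templates with fixed positions, so edge weights
vary across the network.

Planted structure, all recorded in truth tables: a fraction ρ (default 0.5)
of each child's event templates is replaced by draws from its mother's pool
(family sharing); per-group event pools injected into group samples at rate
0.5 (drives Venn overlap and HEC labels); co-occurrence blocks of events
injected jointly into designated sample subsets; community motifs (cliques
over genome sets, optionally biased toward a phylum) injected into group
samples; and fixed numbers of in-gene and intergenic events for fusion
calling. Genomes carry tiled non-overlapping gene annotations (40 genes of
900 bp with 300 bp gaps on 500 kb genomes), which makes intergenic
positions constructible by design. Read depths are drawn lognormally around
a mean of 0.05 reads/bp (CV 0.3).

Randomness flows from a single root seed through named substreams
(taxonomy, backbone, pools, blocks, motifs, fusion, depth), so components
are independently reproducible and emitted files are byte-identical per
seed.

What the generator does *not* emulate: read-level noise and
breakpoint-caller error profiles, intra-genome structural variation,
realistic taxon abundance distributions, or genome-length variation.
Passing tests therefore demonstrate that the statistical machinery recovers
the structures it targets under its stated assumptions — not that those
assumptions hold in any particular sequencing dataset.

## Numerical and degenerate-input decisions

- All-equal degree sequences, empty networks, empty presence sets, groups
  with fewer than two members, and zero-variance rankings raise typed
  errors instead of returning NaN.
- Networks with fewer than 100 nodes are refused by the power-law fitter
  (too little degree data) unless explicitly overridden.
- Zero-variance two-sample comparisons define t = 0, p = 1 when means are
  equal and p = 0 otherwise, so constructed fixtures behave predictably.
- The discrete power-law sampler truncates its support at k = 10⁶;
  discarded tail mass is O((kmax/xmin)^(1−α)), negligible for α > 2.
- Pipeline reports are written via write-then-rename, so a failed run never
  leaves a half-written `report.json`; stage failures abort with the stage
  name.
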