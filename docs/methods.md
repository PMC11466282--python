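# Methods

This note documents the models implemented in `dvomics`, the defaults of the
synthetic-data generator, the numerical conventions, and the places where the
design was genuinely open and a choice had to be made.

## Study design and data model

Five genotypes are analyzed: wild type (WT), dorsalized (D), lateralized (L)
and two ventralized mutants (Vtl, Vsp), each measured with nested biological ×
technical replicates (defaults: 2 × 3). The in-memory container is a pandas
DataFrame of log2 intensities with a `(genotype, bio_rep, tech_rep)` column
MultiIndex; `NaN` marks undetected measurements. MaxQuant-style tab-separated
tables are read with the usual conventions (zero intensity = undetected,
reverse-decoy and contaminant rows dropped when the flag columns exist, log2
applied to linear intensities).

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is exercised.

Each entity draws a baseline log2 intensity from N(25, 2) (the typical LFQ
range) and a regulation category. Defaults: 30% of entities split evenly
across the six regional classes (D, L, V, DL, DV, LV), 70% nominally
ubiquitous — matching the fraction of proteins that test significant across
genotypes in this kind of experiment. Regulated entities are elevated in
their "on" regions by an entity-specific effect drawn uniformly from
`effect_size · [1−jitter, 1+jitter]` (defaults 3.0 log2 ± 30%, i.e. roughly
4–15-fold, the span seen for zygotic fate determinants); 10% of regulated
entities are *restricted* — truly absent (zero linear abundance) outside
their domain, like the mesodermal markers. Every expressed region
additionally receives a mild per-entity modulation of sd 0.25 log2
(`regional_sd`): real maternal proteins are not perfectly flat along the
axis, and without this the deviation distribution of the proportion screen
would collapse onto a handful of atoms.

The wild-type value is computed *on the linear scale* as the
proportion-weighted mixture `a·D + b·L + c·V` of the modulated regional
values (defaults (0.4, 0.4, 0.2)), so the linear model holds exactly at zero
measurement noise by construction. Mutant genotypes carry the pure regional
value; both ventralized genotypes share the ventral value. Measurement noise
is Gaussian on the log2 scale with a biological component shared across
technical replicates (defaults: bio 0.25, tech 0.35 — chosen once so the
technical-replicate FC variability lands near the published Q3 scale of
~0.4–0.5; no noise magnitudes are stated for the original data).
Missingness is thresholded-at-random on the true intensity (default cutoff
log2 = 20): low-abundance measurements are recorded missing, which is the
missing-not-at-random behavior the pipeline assumes when it imputes
"undetected in a mutant" as decreased abundance.

Phosphosites reference host proteins drawn with a 3× bias toward ubiquitous
entities (differentially phosphorylated sites sit mostly on stably expressed
proteins); a configurable fraction (default 0.7) carries regional regulation
drawn independently of the host from the regulated categories, the rest
inherit the host's category. Site ids follow
`ProteinAccession_Residue_Position` with positions unique per host. Under
these defaults the no-correlation fraction among regulated-site pairs comes
out at ~67–75% per comparison.

The spatial atlas places genes on a ring of DV angles; the six canonical
patterns are smooth von-Mises-style bumps (ventral at angle 0, dorsal at π,
lateral on both flanks; two-domain patterns are sums). Designated reference
genes (dpp; sog and soxN; twist; crb; net; neur) carry their pattern exactly,
other genes add Gaussian noise (default sd 0.1). The annotated network is a
Barabási–Albert backbone plus near-clique planted modules whose members share
a dedicated high-information ontology term; the ontology is a random is_a
tree with a single root; edge weights are the Resnik similarity of the
endpoints, floored at 0.05 so that zero-similarity pairs do not disconnect
the graph before normalization; nodes carry a
tyrosine-kinase / other-kinase / other partition label.

What the generator does *not* emulate: peptide-level quantification and
protein inference, intensity-dependent variance, batch structure between
instruments, SILAC ratio compression, spatial reconstruction error in the
atlas, and the size/annotation depth of a real interactome (a few hundred
nodes and dozens of terms versus thousands). Passing recovery tests on these
simulations therefore validates the *implementation* of each method and its
behavior under the assumed generative structure — not the biological claims
on real data.

## Significance testing

One-way ANOVA across genotypes uses a moderated statistic
`d = sqrt(MS_between) / (sqrt(MS_within) + s0)` with `s0 = 0.1` — the fudge
factor damps the significance of tiny absolute differences, and `d` is
monotone in F at `s0 = 0`. The FDR is estimated by permutation (default 500):
genotype labels are shuffled jointly across all samples; the q-value at
threshold `d_i` is the permutation-mean count of null statistics ≥ `d_i`
divided by the observed count ≥ `d_i`, capped at 1 and monotonized so q never
decreases as the statistic decreases. Entities need ≥ 2 genotypes with ≥ 2
values.

A caveat the implementation makes visible: with a shared biological-replicate
noise component the samples are not exchangeable under genotype-label
permutation, and the permutation test is anticonservative (technical
replicates of one biological replicate travel together in truth but not under
shuffling). The calibration check therefore uses a null with technical noise
only, and `average_tech_reps` is provided to collapse technical replicates
first — whether to do so is exposed as a user decision rather than hardwired.

Pairwise comparisons are two-sided unpaired t-tests with Benjamini–Hochberg
adjustment per pair; constant groups are reported as flagged non-significant
results instead of erroring mid-table. Replicate correlation matrices use
Pearson correlation over complete-case entities with average-linkage ordering
on correlation distance.

## Linear model and proportion screen

`twt = a·D + b·L + c·V` on linear-scale genotype means; deviation =
log2(twt/mwt), defined only for entities detected in WT and all three
contributing mutants (complete-case policy). The screen enumerates the full
grid over [0, 1]³ at step 0.05 (9261 combinations, no simplex constraint; an
optional flag restricts to a+b+c = 1) and sorts ascending by deviation IQR.
Two conventions the IQR ranking alone does not fix:

- At zero noise every scalar multiple k·(a, b, c) of the true combination on
  the grid also has IQR exactly 0 (its deviation is the constant log2 k).
  The secondary sort key is therefore |median deviation| (then grid order),
  which ranks the unscaled combination first; exact IQR ties are additionally
  flagged in the output.
- Percentiles/quartiles use linear interpolation everywhere (the convention
  of the numerical environments this kind of analysis is usually run in).

Extreme deviators are entities whose |deviation| strictly exceeds the 95th
percentile of the per-genotype |deviation| distribution in *both* ventralized
genotypes; phosphosites are collapsed to host proteins and counted once.

## Trichotomized clustering

The FC threshold is derived from technical variability: per (mutant genotype,
biological replicate) group, the log2 FC of each technical replicate against
the WT mean is computed per entity; the sample standard deviation across
those FCs summarizes the entity; the group's Q3 (75th percentile) captures
75% of its variability; the threshold is the mean of the group Q3 values.
Entities need ≥ 2 technical replicates with values (configurable). Applied to
the published per-replicate Q3 tables this gives 0.503 (proteome) and 0.352
(phosphoproteome).

FCs are trichotomized (+1 above, −1 below, 0 within the threshold band);
entities undetected in a mutant get −1 with an `imputed-undetected`
provenance flag; entities undetected in WT are excluded. All-zero and
uniformly ±1 profiles are filtered out. Rows are z-scored with the sample
(n−1) standard deviation — forced by the worked example (1,0,0) →
(1.1547, −0.5774, −0.5774) — and clustered with average linkage on Euclidean
distance; the tree is cut into a configurable k (default 14; the original
cut criterion is not stated). An `exact` mode groups identical sign profiles
directly, which is the idealized partition on the finite profile alphabet.
Rows are canonically sorted before linkage so the partition cannot depend on
input order. Each cluster's consensus pattern (sign of the component-wise
mean) maps to a regulation category: the set of regions attaining the strict
maximum sign, with the ventral axis counted if either ventralized genotype
attains it; the cluster is ventral-consistent iff the Vtl and Vsp components
agree. Patterns like (1, 1, 1, 0) yield a three-domain label ("DLV") rather
than an error.

## RNA-atlas matching

Reference profiles: dpp (D), positionwise mean of sog and soxN (L), twist
(V), crb (DL), net (DV), neur (LV). Genes are assigned the category of the
reference with the highest spatial Pearson correlation; argmax ties break by
the fixed order D, L, V, DL, DV, LV and are flagged; constant profiles are
skipped. Within each category only genes whose correlation strictly exceeds
the category's 95th percentile are kept — i.e. the top ~5% with the strongest
similarity form the DV RNA reference sets (the source description can be read
either as keeping or removing the top tail; keeping the most-similar genes is
the reading adopted). Protein-cluster vs RNA-category agreement is `perfect`
(equal region sets), `partial` (intersecting) or `mismatch` (disjoint).

## ED score

Each comparison's FC distribution is rescaled so 0 maps to 0.5 and the
dominant absolute extreme maps to 1 (when |max| ≥ |min|, including ties) or 0
(otherwise); entities undetected in a mutant are imputed with the lower limit
of that comparison's rescaled distribution and flagged. Reference vectors
collect the observed extremes per category — D: (max, min, min), L: (min,
max, min), V: (min, min, max), DL: (max, max, min), DV: (max, min, max), LV:
(min, max, max) — and the ED score is the Euclidean distance of an entity's
rescaled (D, L, V) vector to its category's reference, computed separately
for each ventralized genotype. Distributions are taken over all entities with
defined FCs (not only clustered ones).

## Phosphosite–protein linkage

Sites are paired with host-protein FCs (averaged over protein groups when a
site maps to several); thresholds 0.5 (protein) and 0.35 (site) log2.
Categories: correlation (both exceed, same sign), anti-correlation (both
exceed, opposite signs, labelled by the protein's direction), no correlation
(host within threshold, site beyond), unchanged (site within threshold — kept
as its own category so counts partition). Fractions are reported over both
denominators (all classified pairs, and regulated-site pairs only), since the
source description is ambiguous on this point.

## Network diffusion

Edge weights are Resnik similarities: IC(t) = −log2(n_t/N) over the
true-path-propagated annotation corpus (IC(root) = 0, base 2 throughout),
Resnik(g1, g2) = max IC over the intersection of the genes' ancestor-closed
term sets. Laplacian normalization w′_ij = w_ij/√(d_i d_j) corrects hub bias;
isolated nodes are removed first. The normalized matrix is not stochastic, so
the random walk with restart column-normalizes it at iteration time — making
every score vector a probability distribution, which the Jensen–Shannon
distance below requires. The walk iterates p ← r·s + (1−r)·W·p to an L1
residual < 1e−10 (cap 10 000 iterations, error on non-convergence); restart
r = 0.5 by default (the source states no value; all tests pin it explicitly).
A direct linear solve `p = r(I − (1−r)W)⁻¹s` serves as the independent oracle
in tests.

Seed weights are reciprocals of |ED score| or |deviation| (deviation mode
restricts to the interquartile range of the score distribution; phosphosite
scores collapse to host proteins by the median; zero scores cap at 1e6),
normalized within each kinase partition, and the walk runs per partition.
Null networks are degree-preserving double-edge-swap randomizations (10 swaps
per edge) with edge weights recomputed as the Resnik similarity of the new
endpoints (weight permutation is available as an option; graphs too small to
rewire come back as flagged copies). Empirical p = #{null score > real
score}/n_nulls — strict exceedance, so p can be 0; the (r+1)/(n+1) convention
is available behind a flag. Nodes with p < 0.05 in ≥ 1 partition form the
significant subnetwork.

Ego decomposition: for each seed node, candidate members within 2 steps are
kept when the z-score of Resnik(ego, j) against the ego's precomputed
mean/sd over the whole network exceeds 1.28; ego networks with < 5 nodes are
discarded. Edges are reweighted — edges touching the ego, and ring-1-to-ring-2
edges, get Resnik(ego, far endpoint) (for a cross-ring edge the non-ring-1
endpoint is taken as "far"); within-ring edges get the mean of the two Resnik
values — then Laplacian-renormalized. Per member, topological distance =
1000·log2(1 − JSD(RWR_node, RWR_ego)) with single-node seeds and the
Jensen–Shannon *distance* (square root of the base-2 divergence), and
functional distance = 1000·log2(Resnik(ego, node)); both log arguments are
floored at 2⁻⁵² so distances stay finite. Members are retained when their
Gaussian-KDE density (Silverman bandwidth, computed per axis and normalized
to a maximum of 1 — a raw density is not bounded by 1, so "within 0.7–1.0 of
the PDF" is read as max-normalized density) lies in [0.7, 1.0] on both axes;
a zero-variance axis retains everyone. The union of retained members is
tested for ontology-term over-representation (one-sided hypergeometric,
Benjamini–Hochberg across terms, optionally restricted to a namespace), and
consensus keeps terms significant in ≥ 2 of the 4 score/genotype networks,
reported as a −log10 p matrix.

## Problem sizes

Tests and the acceptance script run scaled-down instances chosen as
representative rather than exhaustive: proteome simulations of 400–5000
entities (the noisy proportion screen uses 5000, approximately the size of
the detected proteome), networks of 60–150 nodes with 100–200 nulls, and 10
seeds for calibration checks. The "log2-noise sd 0.2" recovery condition is
implemented as a total per-measurement sd of 0.2 split evenly in variance
between the biological and technical levels.

## Known limitations

- The permutation FDR inherits the exchangeability caveat above; on data with
  strong biological-replicate correlation it is anticonservative unless
  technical replicates are averaged first.
- Average-linkage flat cuts are not invariant to duplicating rows (cluster
  sizes enter the linkage averages); the `exact` mode is invariant and is the
  recommended reference on trichotomized profiles.
- Resnik similarities and the KDE filter depend on annotation depth; with the
  small synthetic ontologies the IC scale is coarse compared to a real gene
  ontology.
- The generator's dropout acts on the true intensity (sharp threshold), not
  on a probabilistic detection curve.
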