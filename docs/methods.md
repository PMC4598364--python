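# Methods

`floravision` models how floral reflectance spectra are perceived by two
pollinator visual systems, derives discrete colour categories from them,
audits hybrid taxa against their progenitors, and tests whether colour is
phylogenetically constrained. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Spectra and preprocessing

A spectrum is reflectance (fraction of incident light returned) on a
wavelength grid; the working grid is 300–700 nm at 1 nm (401 points),
covering the sensitivity range of bee and hummingbird photoreceptors.
Inputs on other grids are linearly interpolated; extrapolation is refused,
with a 2 nm tolerance at the ends (the edge value is held across gaps that
small). Replicate measurements of an accession are averaged pointwise;
accessions are never pooled implicitly (an explicit flag covers deliberate
pooling of similar accessions).

Smoothing is a centred rolling average of 9 nm applied three times (both
parameters exposed). At the boundaries the window shrinks symmetrically to
the available points, so output length equals input length and no padding
value leaks into the 300 nm end that drives the UV receptor. Three passes
of a box filter approximate a Gaussian closely while preserving affine
trends in the interior exactly.

Brightness is the trapezoidal area under the curve (reflectance·nm), a
proxy for pigment concentration. For spectral-shape clustering, curves are
scaled to a common integral (default 100 reflectance·nm) so that clustering
compares pigment *combinations* rather than concentration; the target is
arbitrary because Euclidean distances scale uniformly with it (asserted by
test).

Chlorophyll in petal tissue absorbs at 675 nm in vivo, producing a local
reflectance minimum. The detector searches a 660–690 nm window for the
deepest interior local minimum and measures its prominence against the
lower of the two window-shoulder values; the call is positive at
prominence ≥ 0.02 reflectance units. Window and threshold are configurable;
the defaults tolerate small calibration shifts while ignoring noise
wiggles. An optional artefact mask interpolates across a stated interval
(off by default) for instrument artefacts such as anomalous 475–500 nm
minima; narrow saturation spikes are assumed removed by smoothing.

## Receptor model and colour spaces

For receptor class *i* with sensitivity S_i(λ), stimulus R(λ), illuminant
I(λ):

- quantum catch Q_i = ∫ R·I·S_i dλ (trapezoidal, 300–700 nm);
- von Kries adaptation P_i = Q_i / Q_i(background), modelling colour
  constancy against the adapting background;
- excitation E_i = P_i / (P_i + 1) ∈ [0, 1), with E = 0.5 exactly at the
  adaptation point.

The illuminant defaults to the CIE D65 daylight distribution (bundled at
10 nm, interpolated); the background to the package's synthetic average
leaf spectrum. Both are file-overridable. Because measured receptor curves
are rarely distributed with a study, sensitivities default to the
Govardovskii A1 visual-pigment nomogram (alpha plus beta band,
peak-normalised) at the published peak wavelengths — bee UV/B/G at
350/440/530 nm, hummingbird UV/B/G/R at 370/440/508/560 nm — with a loader
for measured curves. For UV pigments the beta band overlaps the alpha band
and can shift the realised peak by ~2 nm; this is a property of the
template, not an error. Oil-droplet or ocular-media filtering of the avian
eye is not modelled.

Bee colour hexagon (excitations ordered UV, B, G):

    x = (√3/2)·(E_G − E_UV)        y = E_B − ½·(E_UV + E_G)

Hue is the angle about the origin, spectral purity the distance from it.
The √3/2 coefficient makes the six maximal-excitation states a regular
hexagon with vertices at unit distance; some printed sources carry 3/2,
presumably a typeset radical loss, and that variant is available via
`x_coeff=1.5`.

Hummingbird 3-D opponent space (excitations ordered UV, B, G, R):

    x = ¾·E_B − 1/12·(E_UV + E_G + E_R)
    y = ⅔·E_G − 1/6·(E_UV + E_R)
    z = ½·(E_UV − E_R)

implemented as a configurable 3×4 matrix, default exactly as published.
Note the x and y rows are not zero-sum, so equal excitations map to a
point off the origin (an achromatic offset); a `centre_on_background`
option subtracts the background locus for analyses where that matters. z
is antisymmetric under swapping UV and R, so stimuli with E_UV = E_R lie
in the z = 0 plane (exact, tested).

## Colour categories

Category inputs are the normalised 401-point curves (spectral), the (x, y)
hexagon loci (bee), or the (x, y, z) loci (hummingbird); distances are
Euclidean. Clustering is agglomerative with unweighted average linkage
(UPGMA): the height of a merge is the mean distance over all cross pairs
of the two groups, and the pair with the smallest mean merges first.
scipy's linkage provides the implementation; a literal brute-force
agglomeration serves as the test oracle (exact agreement on heights and
partitions for n ≤ 6). Average-linkage merge heights are non-decreasing.

The number of categories is chosen at an *elbow*: the statistic is the
first difference of consecutive merge heights, all candidate steps are
returned ranked (ties break to the later step, i.e. fewer clusters), and
the default cut sits halfway between the top candidate's height and its
predecessor's. Because the choice of elbow is ultimately a judgement
call, a fixed `k` can always be imposed to reproduce a published category
count. Known limitation: the first-difference statistic resolves the true
class count only when between-class merge heights are comparable (roughly
within a factor of two); with one pair of classes much closer than the
rest, the top candidate collapses them, and a lower-ranked candidate or an
explicit `k` is needed.

## Hybrid colour audit

For each hybrid and character (spectral, bee, hummingbird category;
chlorophyll): the expected set is the union of the progenitors' labels
(unions over colour morphs for polymorphic progenitors), and the verdict is
*expected* iff the observed label (any observed morph) is in that set.
Chlorophyll uses a dominance rule: if any progenitor carries chlorophyll
the expected state is presence; only when both lack it is absence
expected (the all-absent case does not arise in the published material;
the dominance model implies no source of the dominant character, which is
the package's choice). Verdicts are symmetric in the progenitors, and
enlarging the progenitor set can only turn unexpected into expected
(monotone, property-tested). Hybrids whose progenitors are known only to
section level are audited on spectral and chlorophyll characters only,
against state sets supplied from ancestral-state reconstruction.

The published audit of Nicotiana polyploids and homoploid hybrids
(observed and expected categories per character, with unexpected
phenotypes flagged) is bundled as a reference table; recomputing every
verdict from the raw labels reproduces the published flags exactly
(acceptance test).

## Phylogenetic analyses

Trees are dendropy objects, Newick in and out; tree samples are one
Newick per line. Taxa with several trait entries (colour morphs, multiple
accessions) are grafted as extra tips on zero-length branches — sisters of
the original tip at patristic distance zero, leaving all other distances
unchanged.

Ancestral states of categorical characters are reconstructed by
unordered-states parsimony. The implementation is unit-cost Sankoff
dynamic programming: a post-order pass computes per-node, per-state
subtree costs; a pre-order pass computes the cost of the rest of the tree;
the MPR set at a node is the states whose total attains the global
minimum. This is exact on multifurcating trees, scores missing tips as
the full alphabet, and reduces to Fitch–Hartigan on binary trees (verified
against exhaustive enumeration of all internal labelings for small trees).
Tracing over a tree sample: each consensus-tree node is matched to sample
trees by its tip-set clade (matching rooted clades rather than unrooted
bipartitions is deliberate — the two children of a root are one unrooted
split but distinct nodes with distinct MPR sets, and the trees in a sample
share a rooting). Within a tree, equally parsimonious states at a node
share its weight (1/|MPR set| each; a flag switches to full counting), and
frequencies are normalised over the trees containing the node, with the
containing fraction reported as coverage — so per-node frequencies sum to
one. Majority-rule consensus trees (threshold configurable, default 0.95)
come from dendropy.

Phylogenetic signal in a multidimensional trait is tested by a Mantel
permutation test: Pearson correlation r between the vectorised upper
triangles of the trait distance matrix and a phylogenetic distance matrix
(patristic; or uncorrected p-distance with pairwise deletion from an
alignment). The p-value is (1 + #{r_perm ≥ r_obs})/(n_perm + 1), one-tailed
for positive association — phylogenetic signal is a directional
hypothesis — with a two-sided option; default 10 000 permutations. Over a
tree sample the per-tree p-values are summarised as mean, standard
deviation and the percentage of trees significant at α = 0.05. A master
seed spawns one child seed per tree, so runs are reproducible and
parallelisable; an option reuses one permutation stream across trees
(useful to verify that identical trees give identical p-values).
Calibration is property-tested: null p-values are uniform (KS) and the
rejection rate at α = 0.05 matches the lattice-exact null rate.

## Synthetic data generator

The generator provides labelled inputs with the statistical structure the
analysis assumes. Flower spectra follow a Beer–Lambert-style shape model:
baseline reflectance attenuated by Gaussian absorption bands,
R(λ) = baseline·exp(−Σ depth·G(λ; centre, width)) + Gaussian noise
(default sd 0.003, clipped at zero; replicates share a profile and differ
only in noise). The band roster mimics real pigments — UV-absorbing
flavonoids (~330 nm), anthocyanins in the green (the pink/magenta
double-peak), carotenoids below 500 nm (the yellow step), chlorophyll at
430/675 nm — and the eight named default classes (white, UV-white, pink,
magenta, red, yellow, green, dark green) are calibrated so classes differ
in normalised *shape*, since integral normalisation deliberately discards
concentration. It is a shape model only: gloss, structural colour, petal
microstructure and radiative transfer are not modelled, so passing tests
demonstrate correct analysis mechanics, not instrument-level realism.

The leaf background is the same band model tuned to an average leaf: green
peak near 550 nm, dark UV/blue, chlorophyll minimum at 675 nm (depth
configurable; zero removes the minimum). The bundled D65 table and a flat
illuminant are available, mean-normalised to one.

Trees come from a pure-birth (Yule) simulator (exponential waiting times,
uniform lineage choice, default birth rate 1); posterior-like samples are
made by lognormal branch-length jitter of a true tree (topology fixed) —
a deliberately cheap stand-in for Bayesian uncertainty. Categorical
states evolve by a symmetric continuous-time Markov walk (default rate
0.3 per unit length) with true node states retained for recovery tests.
Whole-study bundles default to the motivating study's scale — four colour
classes × five taxa × three replicates (60 diploid spectra) plus six
hybrid accessions — with hybrids inheriting the maternal or paternal class,
or a class outside both (transgressive, default probability 0.25), and an
optional chlorophyll-loss event (default probability 0.3) that removes the
chlorophyll bands; a manifest records every truth label and the master
seed, and bundles are byte-reproducible from that seed.

## Problem sizes in tests and the acceptance script

Exact identities run at trivial size. Oracle-equivalence checks use
n ≤ 6 observations/tips with 50–100 seeded cases (exhaustive enumeration
grows factorially). Statistical calibration uses 400–1000 null Mantel
runs at n = 8 with 199 permutations (the p-value lattice then has step
1/200, fine enough for KS at the 1% level), and power runs at 30 tips
over 20-tree samples. Category recovery uses 3–8 classes × 5 accessions
× 20 seeded replicates. These sizes are the package's own verification
choices: large enough for the distributional statements being tested,
small enough to keep the whole suite interactive.

## Known limitations

- The elbow statistic's factor-of-two homogeneity requirement (above).
- Bird-space coordinates reproduce the published opponent matrix even
  though its rows are not zero-sum; analyses sensitive to the achromatic
  offset should use `centre_on_background`.
- The Yule + branch-jitter tree sample has no topological uncertainty;
  ASR-over-trees coverage bookkeeping is exercised by construction tests
  rather than by genuinely conflicting topologies.
- Parsimony reconstruction is unordered and unweighted; no
  model-based (ML/Bayesian) ancestral-state estimation is provided.
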