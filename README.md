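# floravision

Floral colour evolution through pollinator eyes: a Python library that takes
petal **reflectance spectra** (300–700 nm) to pollinator-perceived **colour
loci**, cluster-derived **colour categories**, **expected/unexpected hybrid
colour audits**, and **phylogenetic analyses** of colour traits — with a
fully seeded synthetic-study generator for validation.

It is aimed at pollination biologists and plant evolutionary biologists who
measure flower reflectance and want to ask: which colours does a bee or a
hummingbird actually distinguish here, did polyploid and homoploid hybrid
taxa inherit a progenitor's colour or shift to something transgressive, and
is floral colour constrained by phylogeny?

## The models at the core

**Receptor excitation.** For receptor class *i* with sensitivity S_i(λ)
(Govardovskii A1 nomogram at the published λmax values by default; bee
UV/B/G = 350/440/530 nm, hummingbird UV/B/G/R = 370/440/508/560 nm),
stimulus R(λ) and illuminant I(λ) (CIE D65):

    Q_i = ∫ R·I·S_i dλ,     P_i = Q_i / Q_i(leaf background),     E_i = P_i/(P_i+1)

von Kries adaptation against an average leaf makes the background
achromatic (E = 0.5, the colour-space origin).

**Colour spaces.** Bee colour hexagon:
x = (√3/2)(E_G − E_UV), y = E_B − ½(E_UV + E_G); hue is the angle about the
origin, spectral purity the distance from it. Hummingbird 3-D opponent
space: x = ¾E_B − 1/12(E_UV+E_G+E_R), y = ⅔E_G − 1/6(E_UV+E_R),
z = ½(E_UV−E_R).

**Categories.** UPGMA (unweighted average-linkage) clustering of
integral-normalised curves or colour loci, cut at an "elbow" — the merge
step with the steepest height increase — or at a fixed k.

**Hybrid audit.** A hybrid's category is *expected* if it matches at least
one progenitor, *unexpected* otherwise; petal chlorophyll (inferred from
the 675 nm reflectance minimum) follows a dominance rule.

**Phylogenetics.** Unordered parsimony ancestral states (exact MPR sets by
unit-cost Sankoff dynamic programming, traced over tree samples and
summarised on a consensus tree) and Mantel permutation tests of
phylogenetic signal (p = (1+exceedances)/(1+n_perm), one-tailed), with
zero-length tips grafted for polymorphic taxa.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import floravision as fv

leaf = fv.smooth(fv.make_leaf_background())           # adapting background
bee  = fv.bee_visual_system(leaf)                     # D65 + A1 nomograms
bird = fv.hummingbird_visual_system(leaf)

flowers = [fv.smooth(fv.simulate_flower_spectrum(fv.DEFAULT_CLASS_PROFILES[c], seed=0)[0])
           for c in ("pink", "green")]
print(fv.project_library([leaf] + flowers, bee).round(3))
```

Running `python examples/02_colour_spaces.py` prints:

```
bee colour hexagon (x, y; purity = distance from achromatic origin):
accession      x     y  purity  hue_angle
     leaf  0.000 0.000   0.000      0.000
     pink -0.053 0.208   0.215    104.374
    green  0.048 0.060   0.077     51.119

hummingbird colour space (x, y, z):
accession     x     y      z  purity
     pink 0.446 0.166  0.069   0.481
    green 0.361 0.233 -0.011   0.430
```

The leaf sits exactly at the hexagon origin (achromatic to an adapted
bee). The pink flower is the most saturated stimulus for the bee
(purity 0.215, hue in the bee-"blue" sector), while the green flower is
barely distinguishable from foliage (purity 0.077). In the hummingbird
space the pink flower's positive z reflects UV reflectance unmatched by
red.

`python examples/03_colour_categories.py` then clusters a 20-accession
library from four pigment classes and reports:

```
categories found: 4 (true classes: 4)
cut height:       0.882
top elbow candidates (merge step, height increase):
  step 17  +1.723
```

— the top elbow (the +1.723 jump at merge 17 of 19) cuts the dendrogram
into exactly the four generating classes, with every accession in the
right category.

Each script in `examples/` is a short narrative of one capability:
preprocessing and chlorophyll calls (01), colour spaces (02), categories
(03), the published hybrid audit (04), phylogenetic signal (05),
ancestral states (06), and the full pipeline on a generated study (07).
A thin CLI mirrors the stages (`floravision simulate | preprocess | loci |
cluster | classify-hybrids | mantel | asr | run-pipeline`).

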