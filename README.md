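# mimicolor

Bee-eye colour perception of floral mimicry: does a rewardless orchid's
colour fool its pollinator, and does the answer depend on the bee's
experience?

## The problem

The terrestrial orchid *Eulophia zeyheriana* offers no nectar yet is
pollinated by *Lipotriches* bees, apparently by resembling the rewarding
*Wahlenbergia cuspidata* flowering alongside it. Classical analyses reduce
this to a single colour-distance threshold. This package instead treats
colour as a *perception*: the probability that a bee discriminates two
colours is a continuous psychometric function of their distance in the
hexagon colour space of hymenopteran vision, and that function changes with
the bee's experience and viewing conditions. Combined with probability
density functions describing how variable each species' colour actually is,
this predicts how often real flower encounters are confusable.

The pipeline has four stages, each a module under `src/mimicolor/`:

1. **colorspace** — reflectance spectra (300–650 nm, 10 nm bins, PCHIP
   resampling) → receptor quantum catches with von Kries adaptation to a
   green-leaf background → excitations `E = P/(P+1)` → hexagon loci
   `x = (√3/2)(E_G − E_UV)`, `y = E_B − (E_UV + E_G)/2`; colour distance
   ΔC is Euclidean, in hexagon units (Hu).
2. **discrimination** — psychometric curves π(ΔC):
   3-parameter logistic `π = Mo·K / (Mo + (K−Mo)·e^(−r·ΔC))` for successive
   viewing (experienced bees), 4-parameter logistic
   `π = Mo + (K−Mo) / (1 + e^((xmid−ΔC)/scal))` for absolute conditioning
   (inexperienced bees); nonlinear least-squares and mixed-effects fitting,
   likelihood-ratio model selection, bootstrap equality-of-means testing.
3. **color_pdf / copulas** — intraspecific colour variability as a
   bivariate PDF `f(x,y) = f_x(x)·f_y(y)·c(F_x(x), F_y(y))`: normal, gamma
   (shape/rate) or Weibull (shape/scale) marginals joined by a Gumbel, Joe
   or Tawn type II copula with 0/90/180/270° rotations, all implemented
   here (densities, conditional-inversion sampling, ML fitting, AIC
   selection, Anderson–Darling GOF).
4. **mimicry** — Monte-Carlo confusion analysis: sample 100,000 locus pairs
   from two species' PDFs, push the distances through the discrimination
   functions, and report the fraction of encounters below the 75%-accuracy
   threshold (π75); classify within-species colours as typical / less
   frequent / rare by density quantiles.

`synthetic` generates spectra and choice data for end-to-end testing with
no measured data; `fixtures` ships the published model parameters
(discrimination coefficients and the four flower PDFs).

## Worked example

```python
import numpy as np
from mimicolor import fixtures, threshold_distance
from mimicolor.mimicry import cross_species_distances, discrimination_report

bundle = fixtures.load_all()
fns = {"abs": bundle["discrimination"]["absolute"],
       "succ": bundle["discrimination"]["successive_blue"]}
pdfs = bundle["pdfs"]

d = cross_species_distances(pdfs["ez_lateral_petal"], pdfs["wc_petal"],
                            n_pairs=100_000, seed=1)
rep = discrimination_report(d, fns, pair="lateral petal/petal")
print(round(rep.median_dc, 3))                 # 0.05   (median ΔC, Hu)
print(round(threshold_distance(fns["abs"], 0.75), 3))   # 0.092 (π75, Hu)
for cond, (pi_med, _, _, pct) in rep.conditions.items():
    print(cond, round(pi_med, 3), round(pct, 1))
# abs  0.5    88.9
# succ 0.936  8.2
```

Read: the typical colour difference between orchid and model petals
(~0.05 Hu) sits at chance (π = 0.5) for an inexperienced bee — 88.9% of
simulated encounters fall below its 75%-accuracy threshold of 0.092 Hu —
while an experienced bee viewing the flowers successively discriminates
the median pair with probability 0.936 and is confused by only 8.2% of
encounters. The mimicry exploits newcomers; experience largely defeats it.

The numbered scripts under `analysis/` run the four stages as a narrative
(synthetic spectra → loci; discrimination-function evaluation and refits;
PDF reconstruction and validation; the confusion analysis) and write their
tables to `results/`.

## Layout

```
src/mimicolor/     library (colorspace, discrimination, copulas, color_pdf,
                   mimicry, synthetic, fixtures, cli)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    modelling assumptions, conventions and limitations
```

A `mimicry-report` console command exposes the pipeline for shell use
(`mimicry-report --help`).
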