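# tpdiv

Trait probability density (TPD) functional diversity for species
assemblages: build probabilistic functional trait spaces, compare
biogeographic realms, simulate progressive Red List extinction scenarios
against randomization null models, and impute missing traits with
phylogenetically informed random forests.

## The problem

Counting threatened species does not say what an extinction wave would do
to the *functions* a fauna performs: species contribute to ecosystems
through their traits (body mass, fecundity, longevity, morphology), and
many species are functionally redundant while a few occupy unique corners
of trait space. `tpdiv` implements the probabilistic trait-space workflow
used in macroecology to answer, for a set of regional species pools:

* how much functional space does each region occupy, and is that more or
  less than expected for its species richness?
* which trait combinations would be lost if the species in the most
  threatened IUCN categories (CR, then EN, VU, NT, DD) go extinct, and is
  that loss larger than removing the same number of species at random?

## The model

Traits are log-transformed, standardized and reduced by PCA to a
D-dimensional functional space (D = 2 for most vertebrate groups, 4 for
morphologically richer ones). An assemblage with species coordinates
x₁…x_S is represented by its **trait probability density**

    TPD(x) = (1/S) Σᵢ φ(x; xᵢ, H),

an equal-weight mixture of Gaussian kernels with a common, unconstrained
bandwidth matrix H fitted once on the global species cloud. The density
is discretized on a fixed grid (200 cells per dimension in 2-D),
thresholded to its 99% highest-density region to strip outlier tails, and
renormalized. From there:

* **FRic** (functional richness) = occupied cells × cell volume;
* **FDiss** = 1 − Σ min(TPD_a, TPD_b), the overlap-based dissimilarity;
* **SES** = (observed FRic − null mean) / null SD against 999 random
  assemblages of equal size; rank p with the 0.975/0.025 rule;
* extinction scenarios −CR ⊂ −EN ⊂ −VU ⊂ −NT ⊂ −DD remove whole
  categories cumulatively from the IUCN-assessed pool; losses are
  compared with 999 randomized-identity removals, and per-cell quantile
  differences (before − after) map where trait combinations become
  rarer (negative), commoner (positive), or vanish (lost space, δF),
  with δT the share of species removed;
* missing traits are imputed with iterative random forests whose
  predictors include the first ten eigenvectors of the double-centred
  patristic distance matrix, and validated by masking complete species
  and measuring the normalized RMSE of their recovered positions.

## Worked example

Generate a synthetic world (300 species, 6 traits, 3 realms, trait-biased
threats, ~12% missing trait cells, a matching phylogeny) and run the full
pipeline:

```sh
tpdiv simulate --seed 3 --out demo/
tpdiv ingest --traits demo/traits.csv --memberships demo/memberships.csv \
             --status demo/status.csv
# 300 species x 6 traits (72 missing cells), 3 realms, 300 statuses
```

then, with a YAML config pointing at those files (see
`tpdiv.pipeline.RunConfig` for the schema):

```sh
tpdiv run-all --config config.yaml
```

The run directory contains `diversity.csv` (per realm: TRic, endemicity,
FRic and its fraction of the world value, null mean/SD, SES, p),
`scenarios.csv` (per realm and scenario: n_removed, δT, FRic before and
after, loss %, δF, null 95% interval, SES, p), pairwise Jaccard and
overlap dissimilarity matrices, a compact-letter-display table, coverage
QA and a `manifest.json` that records every parameter and seed needed to
reproduce the numbers. For the demo world above the `-NT` scenario
removes about 41% of assessed species per realm but only ~7% of
functional space on average — the generated threats sit in a densely
redundant region until the bias is turned up.

A library-level example of the core quantities:

```python
import numpy as np
from tpdiv import (KernelConfig, GridSpec, assemblage_tpd, threshold_tpd, fric)

kernel = KernelConfig(H=np.eye(2), selector="normal_reference")
grid = GridSpec((-5, -5), (5, 5), (300, 300))
tpd = assemblage_tpd(np.array([[0.0, 0.0]]), kernel, grid)
print(fric(threshold_tpd(tpd, 0.99)))   # 28.9378
```

— the 99% highest-density region of a standard bivariate normal, whose
exact area is π·9.2103 ≈ 28.935.

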