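# gmapsolve

Deconvolution of protein glycosylation from **on-chip glycan modification
and probing (gmap)** data: lectin-array profiles of microspotted
glycoproteins collected across rounds of exoglycosidase treatment.

Glycans are branched, so a single monosaccharide composition (one MS mass)
can hide many isomers differing in branching, linkage positions and
anomericity. On-chip gmap probes those isomeric features directly: spotted
proteins are digested with linkage-specific exoglycosidases (e.g. α2-3
vs broad sialidase, β1-3 vs β1-4 galactosidase) and probed with panels of
lectins of known motif specificity. `gmapsolve` turns the resulting
binding patterns into relative glycan abundances:

1. **Model response vectors.** For every candidate glycan structure the
   package simulates each enzyme treatment (recognition-motif → replace-motif
   substitution on the glycan tree) and predicts each lectin's binding from
   per-motif binding scores. Stacking all (treatment, lectin) channels gives
   the N × M model matrix **C**; data are normalized per lectin by the block
   maximum.
2. **Nonnegative least-squares deconvolution.** The observed response
   vector **d** is explained as a nonnegative mixture,
   min‖C·a − d‖₂² s.t. a ≥ 0, so the weights *a* read as relative
   abundances. Perfectly colinear candidate columns are collapsed to a
   single representative first.
3. **Alternative-fit sampling.** Because similar structures produce similar
   columns, the solver re-fits while recursively excluding initially
   predicted glycans; refits within 0.05 R² of the initial fit that use at
   most two additional glycans are accepted (up to 100 refits per initial
   glycan). The report keeps glycans included in ≥ 10 % of accepted fits,
   with inclusion frequencies, mean weights and contribution fractions.
4. **Summaries.** Weighted core-type fractions (bi/tri/tetra-antennary
   N-glycans, O-cores), terminal-feature proportions (Neu5Ac α2-3/α2-6,
   Gal β1-3/β1-4, exposed GlcNAc), per-mass (composition) fractions, and
   within-mass isomer breakdowns.

Candidate libraries can be restricted to compositions/masses observed by MS,
which is how the method assists the isomer-level interpretation of MS data.
A seeded synthetic module generates glycan libraries from an N-/O-glycan
grammar, bundled lectin/enzyme panels, and spot-level simulated observations,
so the whole pipeline is testable without any experimental download.

## Worked example

```python
import numpy as np
from gmapsolve import GlycanDeconvolver, build_model_matrix, normalize_per_lectin
from gmapsolve.synthetic import (SimulationSpec, clean_observation,
                                 default_panel, draw_mixture, generate_library)

spec = SimulationSpec(library_size=50, seed=1)
rng = np.random.default_rng(1)
library = generate_library(spec, rng)                 # 50 unique structures
panel = default_panel(extended=True)                  # 11 lectins x 8 rounds
C = normalize_per_lectin(build_model_matrix(library, panel))
a_true = draw_mixture(library, spec, rng, matrix=C)   # 4-component mixture
d = clean_observation(C, a_true)

model = GlycanDeconvolver().fit(C, d)
print(model.r2_)
print(model.report_.table.round(3))
```

prints

```
1.0
      inclusion_frequency  mean_weight  contribution
G005                  1.0        0.312         0.375
G044                  1.0        0.290         0.290
G013                  1.0        0.213         0.263
G021                  1.0        0.185         0.071
```

The initial fit is exact (R² = 1.0) and the report contains exactly the four
mixture components: each appears in 100 % of the accepted fits
(`inclusion_frequency`), `mean_weight` reproduces the true relative
abundances, and `contribution` is the share of the solution response vector
each glycan explains — a confidence proxy. With 5 % spot-level noise and
replicate averaging (6 spots × 3 arrays) the same pipeline recovers the
support with weight correlations around 0.99.

The same workflow is available from the shell:

```sh
gmapsolve simulate --out sim --seed 1          # library, panel, spot table
gmapsolve run --config config.yaml --out out   # full pipeline
gmapsolve design --glycans ... --panel ...     # pairwise isomer separability
```

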