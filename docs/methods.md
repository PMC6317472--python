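# Methods

## Glycan model

Glycans are rooted trees of monosaccharides over a fixed vocabulary
(Glc, Gal, Man, GlcNAc, GalNAc, Fuc, Neu5Ac, Neu5Gc, Xyl). The root is the
reducing-end residue; every other residue carries its linkage to its parent
as (anomericity a/b/?, child anomeric carbon 1–9/?, parent hydroxyl position
1–9/?). The text dialect is condensed IUPAC with the reducing end rightmost
and branches parenthesized immediately before their parent
(`Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3(...)Manb1-4GlcNAcb1-4GlcNAc`). Sibling
order is semantically void: equality, hashing and deduplication go through a
canonical serialization that sorts siblings by attachment position and then
subtree text. `?` wildcards are legal in stored structures (reference
structures often have unresolved linkages) but match only explicit pattern
wildcards during comparison — an unknown linkage never silently satisfies a
specific pattern.

Compositions collapse residues into the classes Hex/HexNAc/dHex/Neu5Ac/
Neu5Gc/Pent. Masses are computed from underivatized monoisotopic residue
masses (Hex 162.0528, HexNAc 203.0794, dHex 146.0579, Neu5Ac 291.0954,
Neu5Gc 307.0903, Pent 132.0423 Da) plus one water, giving e.g. 2222.78 Da
for Hex5HexNAc4Neu5Ac2. Printed masses in the glycomics literature usually
reflect derivatization or adduct conventions that are rarely stated, so
mass-informed candidate restriction matches either by composition or by a
user-supplied mass list within a tolerance (default ±0.5 Da), and the mass
table is fully overridable via YAML.

## Lectins, enzymes and motif matching

A motif is a small glycan-shaped pattern, optionally *terminal-required*
(every pattern leaf must map to a residue with no further non-reducing
extension). Matching maps the pattern root onto any residue and the pattern
children injectively onto that residue's children, recursively; a site is
the matched root residue. Lectins carry one binding score per motif; the
predicted binding level of a lectin to a glycan is the **maximum** score over
matching motifs. The maximum was chosen because per-motif scores already
summarize average binding levels to motif-bearing glycans; `sum` and
`site_weighted` (score × site count) aggregation modes are available for
sensitivity analysis.

Exoglycosidases are modeled as recognition → replace motif substitution:
the replace pattern must be the recognition pattern minus one or more
non-reducing-side residues, and wherever the recognition motif matches,
those residues are deleted, repeatedly, to exhaustion. Recognition motifs
are terminal-required by default (exoglycosidases act on exposed termini).
Sites are processed deepest-first in a deterministic order; because
substitution only deletes terminal-side residues the fixed point is unique,
digestion is idempotent, and the residue count never increases. A
substitution that would not remove a residue raises instead of looping.
Digestion is all-or-none; partial/kinetic digestion is out of scope.

## Response model and deconvolution

A panel is an ordered list of conditions (each an ordered enzyme sequence;
the empty sequence is "untreated") crossed with a lectin set. The model
matrix entry for channel (t, ℓ) and glycan g is the predicted binding of ℓ
to g after treatment t. Model and observed data are normalized per lectin
by the block maximum — for the model over all conditions *and* glycans
jointly, which keeps columns mutually comparable so that the fitted weights
read as relative abundances; for an observed vector over its conditions
(per protein, not per slide). All-zero blocks are left untouched and the
operation is idempotent. Negative background-subtracted signals are kept by
default (clamping available). Model columns are organized by complete-linkage
hierarchical clustering on Euclidean distance, flattened at a configurable
cutoff (default 10 % of the maximum pairwise distance — the clustering is
descriptive, so only the scale matters).

The weights solve min‖C·a − d‖₂², a ≥ 0 (Lawson–Hanson NNLS). R² is the
conventional coefficient of determination with mean-centered total sum of
squares (defined as 1 for an exactly fitted constant vector, else 0).
Before fitting, groups of pairwise-proportional columns (cosine within
1e-9 of 1, or both zero) are collapsed to the member whose residues are
most thoroughly evaluated by the panel — coverage is the number of distinct
residues (tracked by uid through digestion) inside any motif match in any
condition; ties break on residue count, then id. General linear dependence
is deliberately left to alternative-fit sampling.

Alternative fits are explored by deterministic depth-first search: each
node excludes one not-yet-excluded initially predicted glycan (descending
initial weight, ties on id) and refits over all remaining candidates. A
refit is accepted when its R² is within `r2_window` (0.05) of the initial
fit *and* it uses at most `max_additional_glycans` (2) glycans outside the
initial predicted set; accepted fits are recursed into, to a depth of the
initial support size, under a global budget of `samples_per_glycan` (100)
refits per initial glycan. A visited-set memo prevents duplicate refits of
the same exclusion set. Determinism replaces random sampling so results
reproduce without a seed. Refits may introduce candidates that had zero
initial weight — that is what "additional glycans" means — and the initial
fit does not count against the budget.

The report keeps glycans whose inclusion frequency (fraction of accepted
fits with weight > 1e-8) is at least `inclusion_threshold` (0.10). The
reported weight is the mean over **all** accepted fits, zero-filled where a
fit lacks the glycan, so weights stay comparable across fits (mean over
containing fits is available). The contribution of glycan i is
mean_weightᵢ·‖columnᵢ‖₁ normalized over reported glycans — the share of the
solution response vector it explains; the solution vector itself is
C·mean_weights and is compared with d by Pearson r and R² as the
goodness-of-fit readout.

`GlycanDeconvolver` packages filter → fit → sample → report as a
scikit-learn estimator (`fit(C, d)`, `get_params`/`set_params`, fitted
`weights_`, `report_`, `r2_`, `n_refits_`), composing with sklearn
pipelines and model selection; the module-level functions are the
primitives it wraps.

## Synthetic study conditions

The generator mirrors the structure space the method is designed to
discriminate: complex N-glycans with 2–4 antennae on the
trimannosyl-chitobiose core (antenna slots β1-2 on Man α1-3, β1-2 on
Man α1-6, β1-4 on Man α1-3, β1-6 on Man α1-6), per-arm galactose elongation
(90 %; β1-3 with probability 0.25, else β1-4), per-arm sialylation (70 %;
α2-3 vs α2-6 at 50/50), core fucose (30 %), bisecting GlcNAc (20 %), and
core-1 O-glycans (10 % of draws, optionally α2-3-sialylated). These rates
give sialylated, mostly β1-4-galactosylated complex glycans typical of
serum glycoproteins while exercising every discriminated feature. Libraries
are deduplicated by canonical form.

The bundled lectins are synthetic specificity models patterned on common
array lectins (α2-3 and α2-6 sialic-linkage binders, terminal Gal β1-4 and
β1-3 binders, internal LacNAc, terminal GlcNAc, core mannose, branch β1-6
GlcNAc, core fucose, bisecting GlcNAc); their binding scores are plausible
placeholders in [0.5, 0.9], **not** values derived from any glycan-array
dataset. The basic profiling design is 7 lectins × 3 conditions (untreated,
α2-3 sialidase, broad sialidase); the extended design is 11 lectins × 8
conditions, adding β1-3/β1-4 galactosidase rounds alone and after
desialylation, emulating a deeper second-round experiment. The basic design
deliberately carries no Gal β1-3-sensitive lectin, which is why a
triantennary isomer pair differing in one arm's Neu5Ac/Gal linkages is
exactly indistinguishable under it and separated (r ≈ 0.93) under the
extended design.

Observations are simulated at the spot level: each channel yields
`n_arrays` × `n_spots` replicates (default 3 × 6) whose median signal is a
constant background plus the clean channel value plus additive Gaussian
noise with sd = `noise_sd` × the maximum clean value (default 5 %). Spot
reduction (median − background, mean within array, mean across arrays)
recovers the clean vector exactly at zero noise. Simulated observations
live on the normalized-model scale, so they are fitted without re-applying
the per-lectin observed normalization that real fluorescence data needs.
The simulation has no spatial artifacts, no per-lectin gain variation, and
no specificity error — passing recovery benchmarks therefore demonstrates
the correctness and conditioning of the deconvolution machinery, not
robustness to mis-specified lectin models, which on real data is the
dominant error source.

**Resolvable mixtures.** Under max-aggregation the model matrix of a
50-glycan library has numerical rank far below 50, so an arbitrary mixture's
response vector admits many exact nonnegative representations and cannot be
recovered by any method. Recovery benchmarks therefore draw mixtures that
are resolvable in a method-independent sense: (a) the support is exactly
identifiable — its columns span a face of the candidate cone, verified by
linear programming; (b) every component weight is ≥ 0.1, since components
below the 10 %-inclusion reporting rule are not meaningful recovery targets;
and (c) every component is essential by ≥ 0.02 R² against single-substitute
sparse alternatives (refitting the clean vector without the component, alone
or with any one other candidate) — a margin several times the R²-scale
perturbation of replicate-averaged 5 % spot noise, below which noise can
legitimately favor the alternative explanation. Benchmarks use a 50-glycan
library, 4-component Dirichlet(2) mixtures, and the extended panel.

## Numerical choices and edge cases

- Normalization only divides blocks whose maximum is positive.
- Pearson correlation of a constant vector is reported as NaN with a
  warning, never silently.
- Empty candidate sets after mass restriction warn rather than raise;
  an empty *allowed* set raises.
- NNLS on a zero-column matrix returns zero weights with residual ‖d‖².
- Colinearity uses a 1e-9 cosine tolerance ("perfectly colinear" up to
  float arithmetic); cluster labels are dense integers in order of first
  appearance.
- All tie-breaks (sibling order, exclusion order, representative choice,
  report ordering) are deterministic, making the entire pipeline
  byte-reproducible for a fixed config.

## Known limitations

- Binding is all-or-none per motif with score-level output; no
  concentration dependence, avidity or partial digestion.
- The enzyme model cannot express residue-class wildcards, so one
  biological enzyme with cross-class specificity (e.g. a sialidase acting on
  both Gal- and GalNAc-linked Neu5Ac) must be encoded as several entries
  applied in sequence.
- Core typing covers complex N-glycans and O-cores 1–2; hybrid and
  high-mannose staging are not classified (they fall into N-other/other).
- No automated panel optimization: `design` scores user-specified panels
  only.
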