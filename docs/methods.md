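# Methods

`mtplus` compares the structural connectivity fingerprints of the three MT+
subregions — MST, MT and FST — between two primate species (a human-like and
a macaque-like condition), at the voxel level and at the ROI level. This
note documents the procedures, the conventions adopted where the published
descriptions of these analyses leave a choice open, what the synthetic data
generator does and does not emulate, and the numerical details that matter
for reproducing results.

## Voxel-level analysis

Each subject contributes one streamline visitation-count volume per seed
(MST, MT, FST). The stages are:

1. **Binarization.** A voxel is "connected" iff its count is positive.
   There is deliberately no threshold parameter: the presence/absence
   convention is part of the contract, and `binarize_profile` exposes none.
2. **Group maps.** The group probabilistic map of a seed is the per-voxel
   fraction of subjects connected (so `fraction × n_subjects` is always
   integral); the group-average profile is the per-voxel arithmetic mean of
   counts.
3. **Overlap statistics.** Pairwise Dice `2|A∩B|/(|A|+|B|)` and the
   third-order form `3|A∩B∩C|/(|A|+|B|+|C|)` are computed per subject
   within a tissue mask (gray matter for profiles, white matter for tract
   maps). The metric itself is tissue-agnostic; restriction is the
   caller's job. Dice of all-empty inputs is undefined and returns NaN with
   a warning rather than 0 — an empty profile is a data problem, not a
   zero-overlap observation.
4. **Maximum probability map (MPM).** White-matter voxels are classified
   from the three group-averaged strengths `S_MST, S_MT, S_FST`. Seed X
   dominates iff it is the unique maximum and, against every other seed Y,
   `|S_X − S_Y| > (S_X + S_Y)/2`. For nonnegative strengths with
   `S_X > S_Y` this margin condition is algebraically identical to
   `S_X > 3 S_Y`, and the test suite binds the implementation to both
   forms. Conventions chosen here (the rule is stated for one pair of
   regions; its extension is a design decision):
   - the pairwise margin is required against *each* other seed, applied to
     the unique maximum — the only reading consistent with a partition into
     "dominant" and "overlapped" voxels;
   - exact ties at the maximum are OVERLAP (no unique dominant seed);
   - voxels where all three strengths are zero are UNCLASSIFIED, a distinct
     label: "not connected" is not "connected to multiple seeds";
   - the overlap percentage uses classified voxels only in its denominator
     (seed-dominant + OVERLAP), excluding UNCLASSIFIED and background.
   The MPM is invariant to a common positive rescaling of the three
   strength volumes and equivariant under seed relabeling; both are tested.

## ROI-level analysis

1. **Node-size normalization.** Raw streamline counts between regions a and
   b are scaled by the inverse mean volume of the two nodes,
   `w_ab = c_ab · 2/(V_a + V_b)`. Only the "inverse node volume" idea is
   pinned by the field's tooling; the exact convention (inverse mean, as
   opposed to e.g. inverse sum) is a package choice isolated behind
   `normalize_by_node_size`. Any convention that decreases in volume
   preserves within-seed rank orderings, which is what the downstream
   Spearman statistics consume. When volumes are shared across subjects the
   normalization commutes with group averaging (tested).
2. **Group connectome and target union.** Subject matrices are averaged
   entrywise (identical label order enforced). For each seed, the non-seed
   regions are ranked by group strength and the top `ceil(fraction · m)`
   kept (ceiling: deterministic and inclusive at small m; ties broken by
   label for reproducibility); the three lists are unioned. The default
   fraction is 0.5 and a 0.5→0.2 sweep is a one-line configuration change;
   the union is monotone in the fraction (tested). Only the three MT+
   seeds are excluded from the candidate pool.
3. **Fingerprint correlations.** Seed-pair Spearman correlations over the
   union targets use average ranks for ties; p-values are Bonferroni
   multiplied (default n = 6: three pairs × two species) and capped at 1.
4. **Similarity sets.** For seeds A, B and n subjects,
   `Set_{A−A} = {ρ(v_i^A, v_j^A) : i<j}` and
   `Set_{A−B} = {(ρ(v_i^A, v_j^B) + ρ(v_i^B, v_j^A))/2 : i<j}`, each with
   n(n−1)/2 elements; the between-set is symmetric in A and B and the
   within-set is the between-set of a seed with itself (both tested).
   Elements are Fisher z-transformed (`arctanh`) with |ρ| clipped to
   1 − 1e−7, since degenerate synthetic data can produce ρ = 1 exactly.
   The pipeline emits the tidy per-element table; the repeated-measures
   ANOVAs that consume it are out of scope by design.

## Common space and tracer concordance

The group connectome of each species is projected onto 27 shared homologous
regions: the strength from a seed to a homolog is the **sum** over all atlas
labels mapped to that homolog. Summation is chosen because streamline
strengths are extensive quantities; the same rule aggregates tracer regions
onto the diffusion atlas. Joint ranks over all 3 × 27 values are computed
for presentation; Spearman comparisons are identical on strengths or ranks.
Cross-species per-seed correlations are Bonferroni-corrected for n = 3.

The packaged homolog table (`data/homology27.csv`) is an editable default
with 27 names drawn from the standard human–macaque visuomotor homology
literature, one-to-one for the human column and with conventional macaque
atlas equivalents (F5→PMv, F2→PMd, F6→pre-SMA, …). Real studies should
substitute their own atlas mapping; the synthetic pipeline uses a synthetic
stand-in table (`mtplus.pipeline.synthetic_homology`).

Tracer tables are directed (source, target, strength). Because diffusion
tractography is direction-blind, the two directed entries of a pair are
averaged when both exist (single entries pass through; a flag skips
symmetrization for strength indices measured in one direction only). After
mapping and aggregation, concordance is the Spearman correlation over the
shared regions (at least 3 required). The scale relationship between tracer
strength indices and streamline counts is never modeled; rank correlation
sidesteps it.

## Graph metrics of the tool-use network

The 10-node tool-use subnetwork (TE, AIP, LIP, VIP, PMv, PMd, pre-SMA, MST,
MT, FST) is analyzed per subject as a weighted undirected graph:

- total strength is normalized to 1 (sum over unique undirected edges) for
  cross-species comparability;
- the network is thresholded at sparsities 0.05–0.5 in steps of 0.05,
  keeping the `ceil(s · n(n−1)/2)` strongest edges *with their weights*
  (no binarization — the weighted analysis option is the contract). The
  tie-break at the cut is weight descending, then lexicographic on the
  label pair; the ceiling rule guarantees ≥ 1 edge at s = 0.05 on 10 nodes.

The four nodal metrics use the standard weighted forms:

- **Dc** — node strength, `Σ_j w_ij`. (The verbal description "number of
  direct connections" could also mean binary degree; strength is the
  default under a weighted analysis, and `nodal_degree_binary` provides the
  binary variant behind a switch.)
- **Cp** — geometric-mean triangle clustering,
  `Cp_i = Σ_{j≠h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1))` with
  `ŵ = w / max(w)` and `k_i` the binary degree; nodes with `k_i < 2` get 0.
  The max-weight rescaling makes Cp invariant to uniform weight scaling.
- **Eg** — nodal efficiency `(1/(n−1)) Σ_{j≠i} 1/d_ij`, shortest paths on
  edge lengths `1/w`; unreachable pairs contribute 0, keeping the metric
  finite on fragmented thresholded graphs.
- **Eloc** — global efficiency of the subgraph induced by the node's
  neighbors with the node removed; fewer than 2 neighbors gives 0.

These formulas are the contract: the test suite binds them to independent
brute-force oracles (explicit triangle enumeration; textbook
Floyd–Warshall) on random 8-node networks at every sparsity, at 1e−10.
Shortest paths in the implementation use Dijkstra from `scipy.sparse.csgraph`;
the weighted clustering and efficiency variants used here are not available
as weighted implementations in general-purpose graph libraries, so they are
implemented directly and oracle-tested. Each metric's sparsity curve is
summarized by its trapezoidal AUC over [0.05, 0.5] (a constant c gives
0.45·c); the trapezoid rule is a pinned convention — the rectangle rule
would differ only by a uniform factor on smooth curves.

## Synthetic data generator

The generator defines the study conditions for all tests; it emulates data
*structure*, not physics.

**ROI arm.** Each seed has a latent log-normal fingerprint over
`n_regions` targets. The three fingerprints are drawn through a Gaussian
copula whose latent Pearson correlation is calibrated as
`r = 2 sin(π ρ_s / 6)` so that the *Spearman* correlation matches the
requested target matrix (unit diagonal, PSD enforced; the sin transform can
push the matrix marginally off the PSD cone, in which case it is projected
back). Log-normal marginals (log-sd 1.0) keep strengths positive and
right-skewed, like streamline counts. Subject matrices multiply the latent
values by symmetric multiplicative log-normal noise (log-sd
`subject_noise_sd`, default 0.3). Node volumes are log-normal (log-sd 0.3)
and shared across subjects; raw counts carry the volume factor back in, so
the inverse-mean-volume normalization recovers latent × noise exactly, and
zero noise reproduces the latent fingerprints bit for bit.

Presets encode the two conditions: `human_like` sets all off-diagonal
targets to 0.9 (near-interchangeable fingerprints); `macaque_like` sets
them to 0.2 (divergent fingerprints). Cohort size defaults to 30 subjects
and 80 target regions — large enough for stable rank correlations over the
top-50% union, small enough that the full two-species experiment runs in
seconds.

**Voxel arm.** A shared smooth positive field (Gaussian-filtered noise,
mean 1, clipped at 0.05) plays the role of anatomy on a 12³ grid, split
into a gray-matter compartment (lower half of axis 0) and a white-matter
compartment (upper half); axis 2 is dorso-ventral (index 0 = ventral).
Each seed's Poisson rate is the base field times `mean_count` (default 20)
times a plateau bump along axis 2 — the product of two logistics of
steepness `gradient_strength` centered a sixth of the axis either side of
the seed's preferred position (MST dorsal at 5/6, MT middle at 1/2, FST
ventral at 1/6). At `gradient_strength = 0` both logistic factors are 1/2
everywhere, so all seeds share an identical expected profile (the
human-like condition); the `macaque_like` preset uses 30, which segregates
the seeds into dorso-ventral bands. Per-subject, per-seed log-normal
factors add between-subject variability; counts are Poisson, hence integer.

**Tracer.** Two directed entries per nonzero connection of the chosen seed
(default MT), each the true strength times independent log-normal noise;
zero noise reproduces the truth in both directions and yields concordance
ρ = 1 through the full symmetrize–map–correlate path.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no diffusion signal, tractography, or
distance-dependent false-positive structure; no anatomically realistic
cortical geometry, folding, or co-registration error; no relationship
between a region's volume and its connectivity; gray/white compartments are
geometric halves, not tissue classes; tracer noise is independent
log-normal, whereas real tracer–tractography disagreement is systematic.
The tests demonstrate that the statistical machinery recovers planted
structure under controlled noise, not that the biological conclusions
transfer.

**Determinism.** Every component draws from its own
`SeedSequence([rng_seed, stream])`, so regeneration is bit-identical and
independent of call order; pipeline reruns under the same configuration
reproduce every output file byte for byte (tested). Per-species seeds are
derived from the run seed as `seed·1000 + index` modulo 2³¹.

## Problem sizes

Default experiment sizes — 30 subjects per species, 80 target regions, 12³
voxel grids, 10-node graphs over 10 sparsities — were chosen so the full
two-species experiment, including the oracle-bound test suite, completes in
well under a minute while leaving all rank statistics stable; they are
package defaults, adjustable in the run configuration.

## Known limitations

- The homolog membership and atlas mapping shipped as the default table is
  a literature-conventional stand-in; quantitative cross-species claims
  require a study-specific mapping.
- The MPM tie and zero-strength conventions, the inverse-mean-volume
  normalization, the ceiling rules, and the trapezoidal AUC are package
  decisions where the field's verbal descriptions underdetermine the
  computation; all are recorded in every run manifest and isolated behind
  single functions.
- Group-level MPM and fingerprints are computed from group-averaged
  profiles/connectomes; subject-level MPMs are possible via the same API
  but are not what the pipeline reports.
- The pipeline emits ANOVA-ready tidy tables but deliberately contains no
  repeated-measures ANOVA machinery; only a plain two-sample t-test is used
  in the synthetic species-contrast experiment.
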