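# Methods

## The descriptor

A sequence of length *n* over {A,C,G,T} plus IUPAC ambiguity codes maps
to the 12-vector ⟨n_k, μ_k, D₂ᵏ⟩ for k ∈ {A,C,G,T}, with

D₂ᵏ = Σᵢ (s[k][i] − μ_k)² / (n_k · n),

where s[k][i] is the 0-based offset of the i-th occurrence of k and
μ_k = mean offset. Higher central moments converge to zero quickly and
are omitted; the 12 retained dimensions are what the downstream
Euclidean geometry uses. The divided natural vector cuts the sequence
into k contiguous segments (with n = q·k + r, the first r segments get
q+1 residues, the rest q, left to right) and concatenates segment NVs
computed with segment-local offsets.

Conventions, all fixed here and unit-tested:

- **Offsets are 0-based.** A global 1-based shift adds the same constant
  to every μ_k and cancels in all pairwise Euclidean distances, so the
  choice cannot affect any tree; we state and fix 0-based.
- **Ambiguity codes** (N, R, Y, …) belong to no base class but occupy
  positions and count toward *n*. Reconstructed genomes contain N runs;
  dropping them would shift every downstream offset. The moment
  denominator therefore uses the full length by default; a
  `skip_ambiguous_length` switch excludes ambiguous residues from *n*
  for users who prefer stripped-length normalization, since genome-scale
  practice varies.
- **Empty classes** get μ_k = D₂ᵏ = 0; short DNV segments make this case
  routine.

## Reconstruction from VCF

Haplotypes are rebuilt by replacing the reference substring
[POS, POS+len(REF)−1] with the genotype-selected allele, applied in
descending position order on a copy — equivalent to simultaneous
left-to-right splicing, so indel coordinate shifts never corrupt later
records (verified against a brute-force splice oracle on random cases).
Decisions:

- Symbolic ALTs (`<CN0>` etc.) or records with SVTYPE are structural and
  excluded: their leftmost-position placement in duplicated regions is
  ambiguous. Multi-base explicit alleles are small indels and applied.
- Missing allele calls (".") are treated as reference — conservative,
  and the only choice that keeps a fully uncalled sample equal to the
  reference.
- Overlapping applied records are a hard error rather than a silent
  precedence rule; overlap in the input is exactly the ambiguity that
  motivates excluding structural variation, so it should surface.
- REF-allele verification against the reference is on by default
  (catches wrong reference builds); a flag downgrades it to a warning.
- Phased `|` and unphased `/` separators are both accepted and treated
  alike: the "a"/"b" haplotype labels carry no parental meaning, and all
  downstream statistics average over the pair anyway.

## Averaging and distances

The two haplotype vectors of a diploid chromosome get equal weight
(parental origin is unknowable from the data), so the personal vector is
their midpoint; haploid input (Y chromosome) passes through unchanged.
A population is its members' centroid; matrices are aligned by label
name and summed across chromosomes. Scaling a distance matrix by a
positive constant preserves UPGMA/NJ/BIONJ topology (tested), which is
why sum versus mean across chromosomes is immaterial for trees.

## Tree building

UPGMA, NJ and BIONJ are implemented on one agglomeration core:

- UPGMA: merge the closest pair at height d/2, size-weighted average
  linkage; exact on ultrametric input.
- NJ: Saitou–Nei Q-criterion and branch-length formulas; exact on
  additive input (path-distance reconstruction tested to 1e-9).
- BIONJ: NJ's selection and branch lengths, with the reduced row a
  convex combination d_uk = λ(d_ik − b_i) + (1−λ)(d_jk − b_j) where λ
  minimizes the variance of the reduced matrix (variances initialized to
  the distances, updated as V_uk = λV_ik + (1−λ)V_jk − λ(1−λ)V_ij,
  λ clamped to [0,1]). On additive input BIONJ and NJ agree; under
  perturbation BIONJ recovers the generating 8-taxon topology in ≥90%
  of seeded replicates (tested), and it matches R's `ape::bionj`
  topology on a cross-checked matrix.

Numerical choices: negative branch estimates are clamped to zero with
the deficit moved to the sibling edge so the pair sum is preserved;
agglomeration ties are broken by the lexicographically smallest pair of
cluster representative labels, with ties detected at 1e-9 relative
tolerance — at the four-node stage of NJ the two complementary pairs
have analytically equal Q values that differ only by rounding, and
tolerance-based tie detection keeps output invariant under input
rescaling. BIONJ is the default method; trees are unrooted unless an
outgroup is given. Robinson–Foulds distances count nontrivial
bipartitions on unrooted copies (scikit-bio backend, cross-checked
against dendropy).

## Natural graph

Layer 1 gives every unit one outgoing edge to its nearest other unit;
weakly connected components form groups. Higher layers repeat the rule
on groups. Group-to-group distance defaults to single linkage (minimum
member pair), the closest-neighbor spirit of the construction; "mean"
linkage is selectable since average-based summaries are also of
interest. Nearest-neighbor ties resolve to the lexicographically
smallest label. The globally closest pair always produces a mutual
edge, so every layer strictly reduces or preserves group count and the
procedure terminates.

## Mitogenome filter

Keep sequences with length in [16,564, 16,574] (inclusive window around
the 16,569 bp reference mitogenome) and at most one literal N; other
IUPAC codes are not counted as N (configurable). Groups (countries)
with fewer than two survivors are then dropped. The group filter counts
sequence-filter survivors, so the stage order is part of the contract.

## Synthetic data

Two generators, both fully deterministic under a fixed seed (integer RNG
draws; no float-order dependence in emitted text):

- **VCF cohorts**: reference plus phased diploid genotypes.
  Population-private SNPs segregate at frequency 0.9 inside the owning
  population and 0 elsewhere — high enough that structure is
  recoverable at small sample sizes — shared SNPs at 0.5 everywhere;
  optional 1–3 bp indels and symbolic `<CN0>`/SVTYPE records exercise
  the exclusion path. Sites sit on a stride-5 position grid so REF
  spans can never overlap. With substitutions only, each haplotype's
  Hamming distance to the reference equals its planted non-reference
  allele count (tested).
- **Population sequence cohorts**: a common ancestor is mutated along a
  fixed two-level tree (superpopulation → population → individual) by
  random substitutions, counts proportional to branch lengths. Defaults
  are 10 kb sequences with 200/80/25 substitutions per
  superpopulation/population/individual branch (2%/0.8%/0.25% of
  sites): a clear within- < between-population divergence hierarchy
  while all sequences stay >97% identical, roughly the regime where
  centroid averaging over 20 samples (noise shrink ≈ √20) separates
  populations cleanly. The generating topology is returned for
  recovery scoring.

What the generators do **not** emulate: recombination, coalescent drift,
realistic human mutation spectra or allele-frequency distributions,
linkage structure, sequencing error, or reference bias. Passing
structure-recovery tests therefore shows the pipeline's statistics and
plumbing are correct under planted hierarchical divergence — not that
real cohorts of any particular size would be resolved.

## Problem sizes

The default verification runs use deliberately small instances: 10 kb
sequences, 4 populations × 20 samples, two simulated chromosomes, and
100 replicates for recovery rates; tree oracles use 3–8 taxa where
hand- or brute-force checks are exact. These sizes make every result
reproducible in seconds while exercising the same code paths as
genome-scale inputs.

## Known limitations

- The VCF reader covers the GT-only minimal dialect (no FORMAT fields
  beyond GT, no breakends, no BCF); half-calls beyond the
  missing-as-reference rule and phase sets are out of scope.
- No ME-criterion topology refinement (NNI/SPR) after BIONJ; for noisy
  matrices the agglomerative result is the final answer.
- CNV/SV-aware reconstruction is excluded by design, matching the
  structural-variant exclusion rule.
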