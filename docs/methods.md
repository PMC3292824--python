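# Methods

## The discrimination model

`barcodegap` operationalizes the "barcode gap" as a strict per-scope
threshold. A *scope* is a single locus or an ordered concatenation of
loci. For each scope:

- **Threshold.** τ is the maximum intra-specific K2P distance observed
  among accession-level sequences at that scope. Intra-specific
  statistics use the raw accessions, never the consensus
  representatives, and exclude species sampled only once. If no species
  has two accessions, τ = 0 with a warning. For a concatenation, τ is
  computed on concatenated accession-level sequences (only accessions
  sequenced at every member locus contribute), so it is a pooled —
  site-count-weighted — quantity, not a mean of per-locus values. The
  per-scope (rather than per-species) threshold matches the convention
  of reporting a single "maximum intra-specific variation recorded" per
  locus; with zero intra-specific variation it reduces exactly to
  zero-distance logic.
- **Rule.** A species pair is resolved iff its inter-specific distance
  is *strictly* greater than τ; a pair at exactly τ is unresolved.
  Inter-specific distances are computed between per-species consensus
  representatives.
- **Statistic.** percent resolution = (A − B) × 100 / A, where A is the
  number of species in the scope and B the size of the *union* of
  species over unresolved pairs. Note B counts species, not pairs: 140
  unresolved pairs can involve only 22 species. Percentages are rounded
  half-up to 2 decimals (29/36 → 80.56, 34/36 → 94.44); distances are
  reported at 4 decimals but carried at full precision internally.

## Distances

K2P: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P, Q the transition and
transversion proportions among compared sites. The log arguments are
formed from integer site counts ((n − 2·ts − tv)/n), so the saturation
boundary is detected exactly rather than through float dust. Saturated
pairs (argument ≤ 0) and empty-overlap pairs are NaN in the matrix,
flagged via `undefined_mask`, written as `NA`, and — for discrimination
only — treated as resolved with a warning, since saturation implies
divergence far beyond any intra-specific threshold. p-distance and
Jukes-Cantor are available as diagnostic companions.

Deletion policy: pairwise by default (per pair, skip sites where either
character is not A/C/G/T — gaps, N, ?, and all IUPAC ambiguity codes
count as missing). Complete deletion (one dataset-wide excluded column
set) is available by flag; the two can shift low-divergence results
slightly, which is why the choice is surfaced in the CLI rather than
fixed silently.

## Consensus representatives

Per column, over the votes {A, C, G, T, '-'} (everything else ignored):
a strict majority (> half the votes) wins, gap included; otherwise the
plurality bases collapse to the minimal IUPAC code covering them (a
unique plurality base wins alone; an all-missing column is N). This is
deterministic, order-invariant and idempotent; ambiguity codes produced
by ties are subsequently skipped by pairwise deletion, which is the
conservative reading of a tie. The consensus threshold of the original
chromatogram-assembly convention is not published anywhere we know of;
strict majority is this package's convention.

## The genus simulator

The simulator emulates what a congeneric barcoding study hands the
analysis: one genus, tens of species, a nuclear locus an order of
magnitude more divergent than several plastid loci, near-zero plastid
intra-specific variation, and possibly species pairs sharing a plastid
haplotype ("plastid capture", the known failure mode of plastid-only
barcodes).

- **Topology.** Star by default: each species' founding haplotype
  evolves independently from one ancestral sequence along a branch of
  `inter_divergence / 2`, making the expected divergence between any two
  founders equal to `inter_divergence` (K2P distances are additive along
  branches) and keeping expected values closed-form. Accessions evolve
  from their founder at `intra_divergence / 2`, so conspecific accession
  pairs diverge by `intra_divergence` in expectation.
- **Process.** Substitution-only (sequences are born aligned; alignment
  construction is out of scope). Site fates are i.i.d. draws from the
  *exact* K2P transition-probability matrix for the branch length
  (p_transition = ¼ + ¼e^{−4βt} − ½e^{−2(α+β)t}, per-target
  p_transversion = ¼ − ¼e^{−4βt}, with αt = κd/(κ+2), βt = d/(κ+2)), not
  a small-branch Poisson approximation, so the K2P estimator is unbiased
  at any divergence the tests use.
- **Ground truth.** Recorded from the *realized* founders: for each
  locus, the set of species pairs with byte-identical founding
  haplotypes — exactly the pairs a zero-threshold analysis must call
  unresolved when intra-specific noise is zero. Configured capture pairs
  always appear in every plastid locus's set; at realistically low
  plastid divergence additional coincidental identical-founder pairs
  arise, as they do in real congeneric genera. The expected unresolved
  set of a concatenation is the intersection of its members' sets.
- **Determinism.** The seed is mandatory and all randomness flows from a
  single numpy Generator; identical configs give byte-identical
  datasets.

### Default conditions

`dendrobium_like_config(seed)` encodes the study structure the package
targets: 36 species (33 with multiple accessions — 25×9 + 8×8 = 289 —
plus 3 singletons; 292 accessions total) at five loci (nuclear ITS plus
plastid matK, rbcL, rpoB, rpoC1; 620/780/550/470/480 bp). Expected
inter-specific divergences per locus are 0.1714 / 0.0126 / 0.0061 /
0.0077 / 0.0042 substitutions/site; intra-specific expectations are
0.005 for ITS (realized maxima land near 0.01), 0.0008 for matK and 0
for the other plastid loci; κ = 2; one plastid-capture species pair.
These values were fixed once from the divergence ranges typical of a
congeneric orchid genus and are not tuned per run.

### What the simulator does not model

Coalescent within-species genealogies, recombination, among-site rate
heterogeneity, indels, ITS paralogs/pseudogenes, alignment error,
sequencing error, or taxonomic mislabeling. Passing tests therefore
demonstrate correctness of the *analysis* under the stated statistical
structure, not robustness of barcoding itself to those real-data
complications — in particular, real ITS data can be far messier than
the clean single-copy locus simulated here.

## Numerical and design choices

- Strict inequality at the threshold boundary (d = τ → unresolved).
- Percent rounding is decimal half-up, not banker's rounding.
- Species whose every inter-specific distance is undefined count as
  resolved, with a warning in the bundle.
- Combination distances pool site counts via concatenation, equivalent
  to running the concatenated alignment through the distance engine;
  with all member τ = 0 this makes a combination's unresolved set
  exactly the intersection of its members' sets (a property test).
- Figures are emitted as a scope → percent TSV rather than graphics;
  rendering is a pure function of the JSON bundle (byte-identical on
  re-render).

## Problem sizes in the test suite

The suite exercises the full 36-species/292-accession preset once and
otherwise uses 2–12-species genera with 150–800 bp loci; stochastic
recovery tests use 150–200 replicate pairs at 1000–2000 bp and a
200,000-site branch for the transition/transversion-ratio check. The
whole suite runs in a few seconds on one CPU.

## Known limitations

- Real published per-locus values depend on the upstream alignment
  (aligner and parameters are an external choice) and on the distance
  software's deletion setting; both can shift low-divergence plastid
  results by a pair or two.
- The per-scope τ convention for multi-locus scopes is this package's
  documented choice; with zero plastid intra-specific variation (the
  common case) it is moot.
- Thresholding on a single genus-wide τ is known to be conservative
  when one species is unusually polymorphic: a large τ from one species
  can mask genuinely distinct, closely spaced pairs elsewhere.
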