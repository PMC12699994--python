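# Methods

## Model and rationale

`topictree` treats multilocus phylogeny estimation as a two-stage problem:
summarize each locus's sequence content into a low-dimensional continuous
character, then model those characters on a tree.

**K-mer words.** A locus is a corpus; each taxon's (or population's)
sequence is a document tokenized into non-overlapping k-mers. Words shared
between documents indicate common ancestry as long as they are unlikely to
match by chance: for a random document of n bp the chance that a given
k-mer occurs is `1 − (1 − 4^−k)^n`, so requiring this to be at most q gives
`k̂ = ⌈log₄(n(1−q)/q)⌉`. The default q = 0.01 yields k = 9 across the whole
800–2000 bp locus-length band and k = 8 for the few-hundred-bp loci typical
of population surveys; both values work well in practice. For very long
documents (pooled reads, ~10⁶ bp) the formula suggests k ≈ 11–12, but
longer words (k ≈ 20) better separate repeat-rich genomes and are left to
the user via `--kmer K`. Non-overlapping (rather than sliding) windows keep
corpora small; overlapping windows add cost without adding independent
information. No reverse-complement canonicalization is applied: words are
strand-specific (a flag exists but is off by default).

**Topic frequencies.** LDA with M topics per locus (default M = 5,
symmetric priors α = η = 1/M) summarizes each document as a point θ_d on
the (M−1)-simplex. Fitting is batch variational Bayes — the standard
mean-field coordinate ascent on the variational Dirichlet parameters,
vectorized over documents; with a fixed seed it is bit-reproducible. The
implementation is ours because the pipeline fits tens of thousands of tiny
corpora (one per locus per bootstrap replicate or study replicate) and
per-fit overhead dominates; it is validated in the test suite against
scikit-learn's LatentDirichletAllocation on the same corpora and against
ground truth on corpora drawn from the generative model (mean per-document
total-variation error ≤ 0.15 under well-separated topics). Vocabulary
pruning removes words with corpus frequency < 2 by default; this
"low-frequency" filter mainly removes document-unique noise words. The
number of passes (50) is far past convergence for these corpus sizes.
Documents left without tokens after pruning receive uniform θ (with a
warning) so the character matrix stays rectangular. Topic coherence
(u_mass: mean over ordered top-word pairs of log[(D(w_i,w_j)+1)/D(w_i)],
document counts from the locus corpus) supports an optional data-driven
choice of M; a fixed M = 5 is the default because coherence selection
multiplies runtime and rarely changes the tree.

**Brownian-motion REML tree.** Per locus, one topic column is dropped
(frequencies sum to one) and the rest are square-root transformed — the
classical variance-stabilizing choice for frequencies drifting under
Brownian motion — then all loci are concatenated into a tips × Σ(M−1)
matrix. Characters evolve independently as Brownian motion with variance
c·t per branch; c is fixed at 1 and absorbed into branch lengths. Because
the root state is a nuisance parameter, the likelihood is restricted to
the n−1 pruning contrasts; it equals the multivariate-normal REML computed
from the full tree covariance (verified exactly in tests on every topology
with ≤ 6 tips) and is invariant to root placement and tip order. A
continuous-characters mode (no drop, no transform) is available by flag.

Numerics: node profiles are carried as coefficient vectors over tips, so
every likelihood evaluation is a quadratic form in the precomputed Gram
matrix of the data and costs O(n²) regardless of the number of characters.
Branch lengths are optimized by exact coordinate ascent: re-rooting the
pruning at an edge isolates its length in one contrast with variance
δ_a + δ_b + t, maximized in closed form at t* = max(0, ‖u‖²/p − δ_a − δ_b);
sweeps repeat until the log-likelihood gains < 1e-6 (cap 1000 sweeps).
Negative proposals clamp to zero; contrast variances are floored at 1e-8
during evaluation. The topology search is stepwise addition in row order
(each insertion scored after locally optimizing the three affected edges,
then a full optimization) followed by greedy NNI hill climbing; candidate
and incumbent scores use identical partial-optimization settings so
accepted moves strictly increase the score and the climb terminates. With
`global_rearrangements` (default) sweeps restart until no internal edge
improves. Ties break toward the first-encountered candidate in a fixed
edge order, so results are reproducible. The search matches exhaustive
enumeration on 5-tip problems in tests.

**Bootstrap.** Aligned loci are resampled at alignment columns
(independently per locus); unaligned data at the k-mer level, where each
document redraws its own token multiset with replacement (sizes conserved
exactly). Resampling is per document rather than pooled across documents:
pooling would move k-mers between taxa and erase exactly the tip-specific
signal the supports are meant to probe. k is estimated once from the
original data and held fixed across replicates. Replicate seeds derive
deterministically from the plan seed; the consensus is majority-rule
(dendropy) with integer percentage supports.

## The simulator

`indelsim` emulates multilocus data with indels: a root sequence (default
1000 bp, uniform base frequencies) evolves down a guide tree;
substitutions follow JC (default) or HKY(κ); insertions and deletions each
arrive as Poisson events at `indel_rate` per site per unit branch length
with geometric lengths (mean 12). Homology keys give the exact true
alignment, and gap-stripping any row reproduces the simulated sequence.
Default guide trees are balanced 7- and 14-tip shapes with external
branches 0.02 and internal branches 0.008 substitutions/site, chosen so
that expected alignment widths
L₀(1 + 2·mean_len·rate·T) stay inside the 800–2000 bp band at both study
indel rates (0.02 and 0.2 per site). What the simulator does *not*
emulate: substitution-rate heterogeneity across sites and loci, indel
length distributions heavier than geometric, selection, and within-branch
interaction of substitutions with freshly inserted residues (insertions
are drawn at equilibrium). Passing tests on simulated data therefore show
correctness of the machinery and behavior under idealized sequence
evolution, not performance on real genomes.

Default study sizes are 10 replicates of 1000 loci per scenario — small
enough to run on a laptop core, large enough that the recovery fraction C
(trees within RF ≤ 4 of the truth) is stable at the extremes (0 or 1).

## Design choices on open points

- **"Close" criterion.** "Within two rearrangements" is operationalized as
  RF ≤ 4 (each NNI changes at most one bipartition pair, contributing RF
  ≤ 2). Configurable via `--close-rf`.
- **Per-locus k.** The per-document estimates are aggregated by maximum —
  the smallest k that meets the random-match bound for every document;
  median/min are available.
- **Merging.** Pooling individuals into populations concatenates their
  sequences, making the population's k-mer bag the union of its members'.
- **Missing taxa.** A locus missing a tip is a hard error; imputation
  would silently fabricate signal.
- **Optimizer.** Variational Bayes rather than expectation propagation or
  collapsed Gibbs: any optimizer satisfying the normalization and recovery
  guarantees is acceptable here, and VB is deterministic given a seed.

## Known limitations

- With few loci (≲ 20) the LDA posterior is multimodal and the inferred
  tree can vary with the fitting seed; bootstrap supports then mix data
  uncertainty with optimizer uncertainty. Many-locus runs average this
  out.
- Vocabulary pruning (corpus frequency ≥ 2) makes gap-stripped, indel-rich
  corpora markedly easier than they would be without filtering, because
  frame-shifted junk k-mers are document-unique and are removed wholesale;
  the test suite demonstrates that disabling pruning collapses the
  unaligned high-indel analysis. Conclusions about gap treatments are
  therefore sensitive to this preprocessing choice.
- Branch lengths are in units of Brownian variance of √topic-frequencies;
  they are comparable across analyses only qualitatively, and weighted RF
  values against substitution-scaled trees mostly measure unit mismatch.
- Topic frequencies are compositional; dropping one topic and taking
  square roots is a pragmatic, not exact, mapping to the Brownian model.
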