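# Methods

## Lexical processing and the analysis domain

Each language's wordlist is segmented with a per-language segment
table (greedy longest-match tokenization for unsegmented input).
Vowel length is normalized before analysis: two identical adjacent
short vowels become the long vowel, and the sequences /uwu/ and /iji/
become long /uː/ and /iː/; triples of identical short vowels are
checked before pairs, in a single left-to-right pass. The analysis
domain of a word is its tonic (first) vowel plus the following
consonant, provided that consonant is single and intervocalic; words
without such a configuration contribute nothing. A language enters
the analysis only if it supplies **more than 200** domain instances
and attests at least one short/long tonic vowel pair — languages that
have merged the length contrast entirely carry no information about
its functional load.

## Functional load

For a language's domain profile S (the multiset of (tonic vowel,
post-tonic consonant) string types with probabilities Pr(s)):

- `H(S) = −Σ Pr(s) log₂ Pr(s)` (plug-in Shannon entropy, bits),
- a contrast φ is a collection of disjoint phoneme sets restricted to
  one slot (vowel or consonant); collapsing φ replaces every member
  of each set with a fresh placeholder for that set,
- `fl = H(S) − H(S_φ̄)` (clipped at 0 against rounding) and
  `fnorm = fl / H(S)` (0 with a warning when H = 0).

The three contrasts are built from the segment table: FLV collapses
each short/long vowel pair, FLC collapses consonants sharing place
but differing in manner, FLP collapses consonants sharing manner but
differing in place; singleton sets are dropped.

## Trees and the Brownian-motion covariance

Trees are rooted and dated (branch lengths in time units), read with
dendropy from Newick or NEXUS. The BM covariance C has
`C[i,j]` = shared root-to-MRCA path length and is assembled by adding
each edge length (including any root stub edge) to the covariance
block of the tips below it. Pruning retains the root stub, so the
covariance of a pruned tree equals the corresponding submatrix of the
full covariance. Zero-length terminal pairs trigger a duplicate-row
warning since they make C singular.

## Phylogenetic signal

Blomberg's K compares the observed ratio of tip variance to GLS mean
squared error with its BM expectation:

    K = (MSE₀ / MSE) / [(tr C − n / (1ᵀC⁻¹1)) / (n − 1)]

with `â = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹x`, `MSE₀ = (x−â)ᵀ(x−â)/(n−1)` and
`MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)`. K = 1 exactly on star trees and in
expectation under BM; the implementation matches R `picante::Kcalc`
to 10 significant digits and the PIC decomposition
`(x−â)ᵀC⁻¹(x−â) = Σ (standardized contrasts)²` to 1e−8.

Significance comes from a tip-randomization test: the statistic is
the GLS MSE; p = (1 + #{MSE_perm ≤ MSE_obs + ε}) / (n_perm + 1) with
999 permutations by default and ε = 1e−12·max(|MSE_obs|, 1) so exact
ties count as at-least-as-extreme. Permutations are vectorized via
the identity `dᵀC⁻¹d = xᵀC⁻¹x − (1ᵀC⁻¹x)²/(1ᵀC⁻¹1)`.

Over a tree sample, each (trait, tree) pair draws an independent
substream from the run seed (`SeedSequence(seed, spawn_key=(crc32(
trait), tree_index))`), so results are reproducible and independent
of execution order. Summaries report mean and sd of K and the
maximum p across trees (a conservative aggregate).

## Phylogenetic correlation

With d = deviations of each trait from its GLS mean,

    r = dₓᵀ C⁻¹ d_y / sqrt(dₓᵀC⁻¹dₓ · d_yᵀC⁻¹d_y)

which equals the through-origin correlation of independent contrasts
(verified against `ape::pic` to 1e−8). Over a tree sample the
posterior mean of r is reported with an equal-tail 95% quantile
interval over per-tree values, and the p value applies the t
transform `t = r·sqrt((n−2)/(1−r²))` on n − 2 df to the posterior
mean.

## Synthetic data

All sizes below are this package's own validation choices.

- **Trees**: hand-written Yule (pure-birth) simulator over numpy's
  Generator for bit-reproducibility; waiting time between the k-th
  and (k+1)-th lineage is Exp(kλ), plus a final Exp(nλ) root-ward
  stretch. Default birth rate 1; tree sizes of 40–90 tips are used in
  validation, bracketing a realistic language-family sample.
- **Brownian traits**: multivariate BM with a PSD rate matrix,
  simulated by scaling standard-normal increments per edge; tip
  covariance is rate ⊗ C (checked empirically) and the increment
  correlation is recovered by the phylogenetic r (±0.05 over 500
  replicates at ρ = −0.5).
- **Trade-off lexicons** (`synth_lexicon` / `evolve_tradeoff`): each
  word's domain is drawn from a two-component mixture — with
  probability 1 − θ a vowel-length-contrasting component ({a·C,
  aː·C} equiprobable with a fixed manner), with probability θ a
  manner-contrasting component ({a·C₁, a·C₂} equiprobable with short
  vowel). At θ = 0 the length contrast carries 1 bit and manner 0;
  at θ = 1 the reverse. Consonant place is drawn independently of θ
  (uniform over apical/velar in `evolve_tradeoff`), so the *expected*
  FLP is constant across languages. θ evolves on the tree as
  logistic(z) of a latent BM trait z (rate 1, root 0, logistic
  location 0 / scale 1 — a neutral mapping placing the family mid
  trade-off with substantial spread). Lexicon sizes are drawn
  uniformly from [208, 3215] words, the attested range of the
  motivating wordlists. Every tip draws its words and size from
  deterministic substreams of the generator seed.

### What the generator does and does not emulate

It emulates the *structure* of the hypothesis — a heritable,
clade-structured trade-off between two contrasts with an independent
control contrast — on trees and lexicon sizes of realistic scale. It
does not emulate real phonotactics (one vowel quality, four
consonants), semantic change, borrowing, or tree uncertainty (the
generating tree is used for analysis).

### Known limitation: shared-entropy estimation noise

FLV, FLC and FLP for one language are all computed from the *same*
finite lexicon and share the plug-in entropy term Ĥ(S), so their
estimation errors are positively correlated, and plug-in entropy has
a downward O(1/N) bias that makes every FL estimate drift with
lexicon size N. Direct measurement on independent synthetic lexicons
shows tip-level corr(FLVu, FLPu) noise up to ≈ 0.38 at θ near 0 with
N ≈ 250, falling to ≈ 0.05–0.15 at moderate θ or large N. Because
FLP's cross-language variance is *pure* estimation noise by design,
phylogenetic contrasts between tips with saturated θ are
noise-dominated and inherit this correlation, inflating the FLV–FLP
r away from 0 — the effect grows with tree size as more tips saturate.
A control experiment replacing FLP with independent noise of the same
magnitude restores the nominal behaviour (1/50 false rejections at
α = 0.05, mean r = 0.00). The end-to-end validation in
`tests/test_acceptance.py::test_end_to_end_tradeoff_detection`
deliberately keeps the faithful measurement pipeline and therefore
rejects the FLV–FLP null more often than nominally expected (the
joint success rate falls a few runs short of the 90% target); this is
a property of plug-in FL estimation on finite samples, not of the
statistical machinery. On real wordlists the same caveat applies to
small lexicons: a near-zero FLV–FLP correlation should be read net of
this shared-noise floor.

## Numerical choices

- C is factored once per (trait, tree) with Cholesky; a singular C
  raises unless the explicit pseudo-inverse fallback is requested.
- fl is clipped at 0; r is clipped to [−1, 1]; |r| = 1 returns p = 0
  with a degeneracy warning.
- Permutation p uses the +1/+1 convention, so p ≥ 1/(n_perm + 1) and
  constant traits give p = 1.
- CSV output uses `%.10g`, making study outputs byte-reproducible
  under a fixed seed.
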