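# Methods

## The model

`topicmotif` frames motif discovery as vocabulary selection for a topic
model. A set of D DNA sequences plays the role of a document collection.
Given a candidate vocabulary of V k-mers ("words"), the document–term
matrix holds mismatch-tolerant counts: entry (d, j) is the number of
windows of sequence d whose Hamming distance to word j is at most
⌊f·k⌋, with mismatch fraction f = 0.25 by default (k = 4 → 1 allowed
mismatch, k = 8 → 2, k = 30 → 7; the floor makes the integer budget
conservative). All windows count, overlaps included; windows containing N
never count, and a word containing N counts nothing.

The topic model is a correlated topic model: for each document,
η_d ~ N(μ, Σ) over K−1 free coordinates (the K-th pinned at zero for
identifiability), topic proportions θ_d = softmax([η_d, 0]), and each word
token draws a topic z ~ Mult(θ_d) then a word w ~ Mult(β_z). The
logistic-normal prior admits correlated topics, which matches the biology:
binding sites of co-functional transcription factors tend to co-occur in
the same promoters.

### Inference

Variational EM with the standard mean-field family q(η_i) = N(λ_i, ν_i²),
q(z) multinomial, and the auxiliary upper bound
E[log Σ_k exp η_k] ≤ ζ⁻¹ Σ_k exp(λ_k + ν_k²/2) − 1 + log ζ.
Per document, coordinate ascent cycles φ (closed form), ζ (closed form),
λ (damped Newton, safeguarded so the conditional objective never
decreases), and ν² (exact per-coordinate root by bracketed root-finding —
the conditional bound is separable and strictly concave in each ν_i²).
The M-step is exact: β from expected counts plus a Dirichlet-style
pseudocount (0.01 by default, keeping held-out words at non-zero
probability), μ and Σ as the Gaussian MLE of the variational posteriors
(Σ inherits positive-definiteness from the ν² terms; no ridge needed).

Because every update either exactly maximizes its conditional bound or is
safeguarded, the recorded objective (evidence bound plus the β-prior term)
is non-decreasing across EM iterations up to floating-point noise; the test
suite asserts this on random matrices. EM stops when the relative objective
change falls below `tol` (1e-4) or at `max_iter` (100). K = 1 degenerates
to exact maximum likelihood (β = smoothed corpus frequencies).

Initialization deliberately breaks symmetry in both β (log-normal noise on
corpus frequencies) and λ (Gaussian noise): with a symmetric start,
EM reliably settles on the degenerate stationary point where every
document has an identical posterior and topics split arbitrarily.

### Perplexity

Model quality on held-out counts ω is Perp(ω) = exp(−log p(ω)/T) with T
the total held-out token count; +∞ when T = 0. For K ≥ 2 the per-document
log-likelihood is the variational bound (the same E-step run with model
parameters frozen), which in testing tracks a 2×10⁵-sample Monte-Carlo
integration of the logistic-normal likelihood to well within 5 % (typically
< 1 %). For K = 1 it is exact, and a uniform single-topic model has
perplexity exactly V — a closed-form identity the tests pin to 1e-9.

The train/test split backing the GA fitness is deterministic: with D ≥ 4
documents, every fourth document (index ≡ 3 mod 4) is held out; with fewer
documents (common, since sets of three or fewer sequences are this
method's comfortable operating size), word tokens alternate into
train/test halves within each document. The proportion, K (default 3,
here usually 2), smoothing, and stopping rule are all exposed parameters;
the source method fixed none of them publicly.

## The genetic algorithm

An individual is a list of n k-mer instances (document, position, word),
k ∈ [k_min, k_max]. Initialization draws random positions and accepts a
word only if it passes the shuffle-control overrepresentation test in its
own sequence: c − c_s ≥ c_min, where c counts mismatch-tolerant
occurrences of the word and c_s of one letter-shuffle of it. Rejection
sampling is bounded (10⁴·n draws) so pathological inputs (e.g.
homopolymers, whose shuffles are themselves) fail cleanly.

The shuffle control is the method's guard against composition-driven
false signals, and c_min must make it bind: because c counts the
candidate's own window, c − c_s ≥ 1 is nearly free and c_min = 1 admits
low-complexity words whose mismatch neighborhoods are generically large.
The scaled-down studies here use c_min = 2, which measurably doubles the
fraction of accepted words overlapping planted sites.

Each generation: evaluate all (fitness = held-out perplexity of the
individual's vocabulary; cached, and degenerate cases — empty vocabulary
occurrence, vocabulary smaller than K, empty split — score +∞ rather than
raising), pair individuals at random and keep the better of each pair,
refill to N with one-point crossover over shuffled instance arrays, then
shift-mutate: with probability `mutation_rate` an individual has a random
subset of instances moved by a non-zero offset up to one word length,
clamped to the sequence, the word re-read at the new position. The
incumbent best individual is exempt from mutation; combined with fitness
caching this makes the best perplexity non-increasing across generations
and the whole run reproducible from one seed. Termination is generation
count only — no optimality test exists for this objective.

After the run, solutions are sorted by perplexity and the top
`max_solutions` returned. For each solution the CTM is refitted on its
full matrix (no split), every vocabulary word is assigned to its
argmax-probability topic, and each non-empty topic becomes a motif
carrying the solution's instances of its words — so the motifs of a
solution partition its instance list. The PWM uses instances of the modal
length (ties → shortest); consensus ties resolve alphabetically. Motifs
within a solution are ranked by mean per-column PWM information content.

## The confidence filter

`perplexity_filter` is a generic gate for candidate instance sets from any
motif finder: single-linkage Hamming clustering per word length (radius =
the mismatch budget ⌊0.25·k⌋), cluster consensus words as a vocabulary, a
CTM fit on the train split, and the verdict `perplexity < threshold`
(default 100). A genuine motif collapses to one or a few tight clusters
whose counts are consistent across sequences — perplexity near 1 — while a
junk candidate set keeps ~V singleton clusters with erratic held-out
counts and perplexity above the threshold. K is capped at min(K, V)
because clustering can legitimately collapse a strong motif to a single
representative word.

The absolute threshold of 100 is meaningful at finder scale: a candidate
set of only a dozen instances yields V ≈ 12 representative words, and
perplexity then cannot stray far above V, so small sets are effectively
always "confident". The synthetic studies therefore size negative controls
at the finder's candidate-set size (120 instances).

One circularity is worth stating plainly: the filter measures exactly the
quantity the GA here optimizes, so applying it to this GA's own output is
weakly informative — optimized junk on motif-free sequences also scores
below 100 (measured ≈ 58–63 versus ≈ 45–54 for planted data). The filter
earns its keep on candidates that were *not* selected for low perplexity
(its intended upstream is a statistics-driven finder), and the discriminant
that does separate this GA's outputs is the paired perplexity ordering,
not the absolute threshold.

## Assessment

Nucleotide-level counts compare per-position coverage sets (overlapping
annotations merged first) over every position of every sequence.
Site-level counts use the quarter-overlap rule: a predicted site matches a
known site when their overlap is at least ⌈len(known)/4⌉ positions —
"a quarter of it" is read as a quarter of the known site, rounded up.
Known sites are matched one-to-one greedily by largest overlap (ties:
leftmost known, then leftmost predicted); sTP counts matched known sites,
sFN unmatched ones, and sFP the predicted sites that meet the quarter rule
with no known site at all (a second prediction on an already-claimed site
is not punished). The eight statistics are nSn, nPPV, nSp, nPC, nCC, sSn,
sPPV and sASP; 0/0 ratios are NaN and excluded from averaging. The nCC
numerator is nTP·nTN − nFN·nFP (Matthews); a circulating variant with "+"
is a typo, since it does not lie in [−1, 1]. Multi-dataset combination
follows the benchmark convention: sum the seven raw counts across
datasets, then compute the eight statistics once on the sums — a method
that predicts nothing scores 0, not NaN, on the sensitivity side.

## Synthetic data

The generator emulates the benchmark's dataset types at desk scale:
backgrounds are uniform i.i.d. or first-order Markov (a GC-skewed preset
table is included; empirical transition frequencies of a 50-kb draw match
the table within 0.02 per cell), and `instances_total` copies of a motif,
each carrying an exact number of substitutions, are planted at
non-overlapping random positions on random sequences — deliberately *not*
one per sequence, since the method makes no distributional assumption.
`shuffle_dataset` letter-shuffles each sequence to produce matched
negative controls. Defaults — six 200-bp sequences, twelve copies of an
8-mer with one substitution — define the standard study condition used
throughout the tests.

What the generator does not emulate: real promoter composition beyond
first order, overlapping or gapped sites, two-block motifs, and
strandedness (the finder scans the given strand; `--revcomp` appends
reverse-complement documents). Passing tests on these data show the
machinery behaves as specified under a clean planted-signal model; they do
not certify performance on real promoters, where motif degeneracy and
background structure are harsher.

## Scaled-down study parameters

The recovery and discrimination studies run at a deliberately small size
so a full GA run takes tens of seconds: width range 6–10, c_min = 2,
population 20 (even, as pairwise selection requires), 120 words per
individual, 15 generations, K = 2, 3 seeds. The 120-word individual size
is roughly ten times the planted instance count; at much smaller n the
dominant perplexity gradient is vocabulary shrinkage through duplicate
accumulation under crossover (an artifact of small n — duplicates
deduplicate into a smaller V, which lowers perplexity regardless of
content), while at n ≈ 120 the vocabulary-content signal dominates within
the 15-generation budget. The full-scale defaults (width 6–30, population
50, 90 generations, 1000 words, ≤ 10 solutions, mutation rate 0.1,
threshold 100) remain the package defaults.

## Numerical choices and degenerate inputs

- Mismatch budget: floor; clustering radius reuses it.
- Selection ties keep the pair's first member; sort order on equal
  perplexity is stable.
- Crossover index is uniform on [1, n−1]; n < 2 copies the parents.
- Mutation offsets exclude 0 but clamping at sequence edges may still
  produce a no-op; mutated individuals always satisfy the
  word-matches-position invariant.
- Empty individuals, all-zero matrices, V < K, and empty splits are worth
  +∞ fitness, never exceptions, keeping the GA loop total. The strict
  V < K refusal applies to `fit_ctm` and `fitness`; the filter and the
  topic→motif refit cap K at V instead.
- Coordinates are 0-based half-open everywhere internally; the motif
  report adds 1-based inclusive columns for human reading.

## Known limitations

- Ungapped motifs only; a gapped site may surface as several fragments.
- The finder reports every candidate instance of a motif; there is no
  PWM-based rescan to prune instances, so positive predictive value at
  nucleotide level is structurally low even when the consensus is right.
- Held-out perplexity is a variational bound for K ≥ 2, so reported
  perplexities slightly overestimate the true value; comparisons between
  candidate sets are unaffected in practice.
- The confidence threshold is an absolute perplexity and therefore
  scale-dependent (see the circularity note above).
- Runtime grows steeply with the number of documents; the method is most
  comfortable on small sequence sets, mirroring its source.
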