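# Methods

## The rate estimator

The velocity of a term is estimated from the last *N* messages containing it
at the reference time *t*: Φ(w) = (M−1)/(τ_M − τ₁), where M ≤ N stamps are
actually available at *t* (the sum of consecutive inter-arrival times
telescopes, so only the first stamp, the last stamp and the count matter).
Windows are closed on the right (stamps ≤ t) and never look ahead.

Properties worth knowing:

- **Bias.** On a homogeneous Poisson stream of rate λ, the span of N
  consecutive events is Gamma(N−1, 1/λ), so E[Φ̂] = λ·(N−1)/(N−2) — a
  +3.6 % bias at the default N = 30. The bias largely cancels in the
  similarity, which is a ratio of two such estimators.
- **Undefined rates.** With fewer than two stamps, or a zero span (all
  stamps coincident), the rate is undefined and every similarity that needs
  it is 0. This extends the absent-term fallback (TSS = 0) and avoids
  infinities on corpora with duplicate timestamps.
- **Memory.** The estimator is a sliding-window statistic: after an event
  ends, its stamps remain in the window until N fresh occurrences displace
  them, so similarity responses decay over roughly N/rate seconds rather
  than instantly. The event-dynamics analyses rely on this.

## The similarity

TSS(w₁,w₂) = (Φ(w₁∧w₂)/max(Φ(w₁),Φ(w₂)))^α with α = 1/4 by default. The
exponent applies to the whole ratio: this is what makes the self-similarity
identity TSS(w,w) = 1 hold for every α and gives the measure a usable scale.
With finite windows the estimated joint rate can exceed an individual rate
(the joint window reaches further back in time), so the ratio is clipped at
1 before exponentiation; the measure is then exactly symmetric and always in
[0, 1]. Matrix diagonals are 1 for terms with a defined rate and 0
otherwise.

Tunables: `n` (window size, default 30; larger = smoother and slower to
react) and `alpha` (default 0.25; for a fixed ratio r < 1 the similarity is
decreasing in α, so smaller α stretches the top of the scale).

## Term matching

Matching is case-insensitive at the token level; tokens split on
non-alphanumeric characters, with `#` attached to the following token so
hashtags are distinct from plain words (`#worldcup` ≠ `worldcup`).
Multi-word terms match as contiguous ordered token runs. Any number of
occurrences inside one message counts once. This is a fixed, documented
convention chosen for determinism and language-agnosticism — no stemming,
lemmatization or accent folding is attempted, and substring matches
(`pie` in `piety`) are deliberately excluded.

## The stream simulator

Messages arrive as a Poisson process with piecewise-constant rate Λ; each
message draws one topic from a weighted mixture and includes each vocabulary
word independently with the topic's per-word probability. Closed forms
follow for every pair:

    rate(w)       = Λ Σ_k weight_k p_k(w)
    joint(w1,w2)  = Λ Σ_k weight_k p_k(w1) p_k(w2)

and plugging these into the similarity definition gives the analytic oracle
`true_tss` used throughout the recovery tests. The topic-mixture design was
chosen over pairwise copulas because it yields these closed forms for *all*
pairs at once and naturally produces category clusters (shared topic ⇒ high
co-occurrence) and event scenarios (a segment switch re-wires who shares a
topic with whom). Word order inside a message is fixed vocabulary order —
immaterial, since matching is order-insensitive.

What the simulator does **not** emulate: bursty/self-exciting arrivals,
retweet cascades, diurnal cycles, realistic text (messages are bags of
vocabulary words), polysemy, or multilingual structure. Passing recovery
tests therefore shows the estimator chain is correct under Poisson
assumptions, not that real social-media streams satisfy those assumptions.

Two canonical scenarios are packaged. `draw_schedule` emulates a tournament
draw: 32 exchangeable items (Λ = 2 msg/s, background inclusion 0.15) gain
per-group topics (weight 0.1, inclusion 0.8) for a 300 s event window, which
imprints an 8×4 partition on the co-occurrence structure and then relaxes.
`crisis_schedule` emulates concept drift: a concept sits in its usual
neighborhood topic (inclusion 0.3) with only baseline presence (0.02) in a
crisis topic, joins the crisis topic at 0.3 during a 1500 s event, then
reverts. The small baseline is deliberate: it keeps the concept–crisis joint
rate defined before and after the event so the sliding window can relax back
instead of freezing at its event-time value.

## Analyses

- **Group-organization performance.** Per item, take the 3 largest
  off-diagonal similarities; the score is the fraction that are groupmates
  (1, 2/3, 1/3, 0). Ties are broken by vocabulary order — measure-zero for
  real-valued similarities but reachable in synthetic data, so the rule is
  fixed and tested. For 32 items in 8 groups of 4 with no structure the
  top-3 is a uniform 3-subset of the 31 others, giving an expected score of
  3/31 ≈ 0.0968 (hypergeometric mean); the Monte-Carlo tests check this.
  Items must belong to groups of at least 4 (an item plus 3 groupmates).
- **Anchor drift.** Mean similarity of a concept to two fixed, disjoint
  anchor word sets at each time point; the concept may not belong to either
  set. The optional 2-D trajectory embeds the anchors once, by classical MDS
  of the time-averaged (1 − TSS) dissimilarities, and places the concept at
  each time by least-squares matching of its anchor dissimilarities
  (Nelder–Mead from the anchor centroid) — a reproducible projection
  convention, not a canonical one.
- **Norm series.** Frobenius norm of each matrix with the diagonal excluded
  (self-similarity is constant and would only add an offset). Subnetwork
  co-activation is quantified by the Pearson correlation of two norm series
  on a shared time grid, optionally windowed; at least 3 aligned points are
  required. Rows are not normalized before the norm.
- **Synonym rank.** Candidates sorted by ascending similarity; the synonym's
  normalized position is (rank−1)/(M−1) with mean ranks for ties, so 1.0
  means most-similar. Invariant under strictly monotone transforms of the
  scores; i.i.d. scores give 0.5 in expectation.
- **Classification.** Items are classified into categories from their
  similarity-matrix rows restricted to the columns of the training fold, so
  a held-out item never sees its own self-similarity. Folds are stratified
  by class when every class has at least k members, plain shuffled folds
  otherwise, always seeded. Shipped classifiers are Gaussian Naive Bayes and
  k-NN (standard definitions via scikit-learn); they stand in for the K\*
  instance-based classifier, whose entropic distance is not reproducible
  from its published description — the clustering claims being tested are
  classifier-robust.
- **Classical MDS.** Torgerson double-centering, B = −½ J D² J, top-d
  eigenpairs, negative eigenvalues clipped; axis signs fixed by making each
  axis's first non-zero loading positive, so embeddings are deterministic.

## Numerical and design choices

- Equal timestamps are allowed (file order breaks ties); real-valued and
  integer-second corpora are both valid.
- Short series (fewer than the requested N matches) return all available
  stamps; downstream the <2-stamp rule applies.
- Similarity matrices validate symmetry and range on construction;
  serialization is wide CSV (terms as header row/column) or long CSV
  (`term1,term2,time,tss`).
- Every CLI command, and the simulator, is a pure function of
  (inputs, configuration, seed): reruns are byte-identical.

## Problem sizes used in the validation suite

The statistical tests use sizes chosen to make their tolerances comfortable
on a single CPU: 10⁴ disjoint estimator windows per rate (three rates
spanning 0.05–5 /s) for the closed-form bias check at 1 %; 200 reference
times on a 22 000 s stationary stream for similarity recovery at 0.05
absolute; 10⁴ random 32×32 matrices for the 3/31 chance level at 0.005; and
50 replicates per event scenario for the dynamics shape assertions.

## Known limitations

- The measure is asymmetric in information content (normalization by the
  *faster* term): similarity of a rare word to a frequent one is driven by
  the frequent word's rate.
- Rate estimates from N = 30 stamps have ≈19 % coefficient of variation;
  single-time similarity values are correspondingly noisy and analyses
  should average over reference times or replicates, as the shipped
  analyses do.
- The last-N window makes the time resolution rate-dependent: rare pairs
  respond to events slowly, and a pair whose co-occurrence stops entirely
  keeps its last estimate indefinitely (its window never refreshes).
- Matching is purely lexical; polysemy, negation and multilinguality are
  out of scope.
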