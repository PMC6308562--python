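# Methods

## Problem and scope

`ferwrf` classifies a face observation into one of the six basic expressions
(anger, disgust, fear, happiness, sadness, surprise) from the standard
68-point facial landmark annotation alone. Landmark detection is an upstream
concern: the input contract is a table of labeled landmark rows, and the
package's job is the geometry-to-label pipeline — similarity-invariant
geometric descriptors, a decision-forest classifier with a
between-class-variance split criterion, out-of-bag tree weighting, and a
two-level coarse-to-fine hierarchy. The design targets low-compute,
CPU-only deployments (e.g., in-cabin driver monitoring), which is why the
model is a shallow forest over scalar geometric features rather than a
neural network over pixels.

## Geometric features

For a landmark triple {i, j, k} with vectors v_ij (i to j) and v_jk (j to k):

* distance ratio: ‖v_ij‖ / ‖v_jk‖ (Euclidean norms);
* angle relation: the unsigned angle between v_ij and v_jk, computed as
  arccos of the clamped normalized dot product, in [0, π].

Both are invariant to rotation, uniform scaling and translation of the
image, so raw pixel coordinates are consumed directly and no normalization
happens at I/O time. The angle is unsigned because no sign convention is
imposed; this makes the descriptor reflection-symmetric. Vector norms below
ε = 1e-9 px raise a degeneracy error naming the triple instead of emitting
NaN.

The default configuration supplies 84 distance-ratio and 88 angle-relation
triples drawn from the expression-bearing regions: mouth (48–67), jaw/chin
(0–16), eyes (36–47) and eyebrows (17–26). The specific triple list is a
packaged, versioned reconstruction (`ferwrf/data/default_triples.json`,
generated once with a fixed seed and region weighting mouth 0.40 / eyes 0.25
/ brows 0.20 / jaw 0.15): the dimensionalities and the region restriction
are the hard constraints, the individual triples are not claimed to match
any external choice. Custom configs are plain JSON files of [i, j, k]
arrays.

## Split criterion

At a tree node holding samples Q with feature matrix X and labels y, the
per-dimension between-class variance is

    B_f = Σ_c (|Q_c| / |Q|) (μ_f − μ_cf)²

with μ_f the node mean of dimension f and μ_cf the class-c mean, and the
node's *data similarity* is S = Σ_f B_f. A candidate split into children
L, R is scored by

    ΔG = S − (N_L/N)·S_L − (N_R/N)·S_R

and the best of the sampled candidates is taken. A note on the objective:
S is a node-level scalar, so any reading that sums it per sample merely
rescales every candidate at the node by the same factor and cannot change
the argmax; the weighted-children form above is the one that parallels
standard impurity gain and is what is implemented.

S = 0 both for pure nodes and for mixed nodes whose classes are
indistinguishable in feature space; growth stops in either case and the leaf
keeps the class-frequency distribution. This is the intended behavior: for
confusable classes the leaf posterior, not further splitting, carries the
information. An `entropy` criterion is available on the same machinery so
the two objectives can be compared; it is cross-checked in the tests against
scikit-learn's entropy tree on a separable fixture.

Candidate sampling: ⌈√D⌉ feature dimensions without replacement (D = 84 or
88 here), 10 thresholds per dimension drawn uniformly strictly inside the
node's (min, max) for that dimension; constant dimensions yield none.
Thresholds strictly inside the range guarantee non-empty children. Ties in
gain resolve to the first candidate in the seeded draw order. Growth stops
at depth 15 (root = 0), below 2 samples, or when the best gain is ≤ 1e-12
(an absolute floor that absorbs floating-point noise around zero gain).
Routing is `x[f] ≤ τ` → left.

The fast per-candidate evaluation used during growth computes S from
per-class sum vectors via S = (1/n) Σ_c ‖s_c‖²/n_c − ‖s‖²/n², one matrix
product per class for all candidates at once; the reference implementation
(`node_similarity`, `information_gain`) follows the definition directly, and
the tests pin both to an independent naive-loop oracle at 1e-10.

## Weighted forest

Each tree is grown on an in-of-bag bootstrap (N draws with replacement) and
scored on its out-of-bag samples (never drawn; on average a fraction 1/e ≈
0.368 of the data). A tree with OOB accuracy below 0.5 is discarded;
training repeats until the requested number of survivors (default 200) is
reached, capped at 10× that many attempts, after which a training-failure
error reports the attempt/survivor counts. Survivors vote with weight
w_t = OOB accuracy ∈ [0.5, 1]:

    p(c|x) = Σ_t w_t p_t(c|x) / Σ_t w_t

The normalizer is positive, so the argmax equals that of the unnormalized
weighted vote; `weighting="uniform"` recovers the plain ensemble average.
Decisions taken where the method description is silent: OOB accuracy uses
the single tree's argmax with ties to the lowest class index; an attempt
whose OOB set is empty (only plausible at toy N) is accepted at the minimum
admissible weight (the pruning threshold) with a logged warning; the target
tree count refers to survivors, since the vote divides by it.

## Hierarchy and fusion

Anger, disgust and sadness share most of their landmark geometry, so a flat
6-way model concentrates its errors inside that trio. Level 1 classifies
{fear, happiness, surprise, GROUP}; level 2 classifies {anger, disgust,
sadness} and is trained only on the group's samples. Each level trains one
forest per feature stream and fuses the two distributions as
w1·p_distratio + w2·p_anglerelat with defaults w1 = 0.4, w2 = 0.6
(constrained non-negative, summing to 1). The final distribution keeps the
level-1 mass for the easy classes and distributes the group mass by the
level-2 conditional, P(c) = q(GROUP)·r(c) — the unique combination of the
two stages that yields a normalized 6-class distribution. Fusion happens
within each level, then the levels chain. Surprise sits at level 1 (the
group is exactly the confusable trio); the `group` argument exposes the
alternative reading. Argmax ties resolve to the lowest class index in the
canonical (alphabetical) ordering.

## Synthetic data

The generator states a world, not a tuning knob. A fixed neutral template
(inter-ocular distance 200 px, image-convention y-down) is deformed by one
hand-designed displacement field per expression, loosely following
facial-action descriptions (happiness: mouth-corner raise; surprise: brow
raise + jaw drop; fear: brow raise + lip stretch; anger: brow
lowering/knitting; disgust: upper-lip/nose raise; sadness: lip-corner
depression + inner-brow raise), magnitudes capped at 15 % of the
inter-ocular distance. A sample is
prototype(intensity) + subject offset + landmark noise, then a random
similarity transform. The confusability parameter κ blends the
anger/disgust/sadness fields toward their centroid (κ = 1 collapses them),
emulating the trio's empirical similarity.

Packaged benchmark defaults: 12 subjects, 20 samples per class per subject
(1440 rows), κ = 0.5, landmark noise σ = 1.5 px, subject offset σ = 2 px,
intensity ∈ [0.7, 1], rotation ±15°, scale ∈ [0.8, 1.25], translation
±50 px, seed 42. The draw order (per subject: offset; per sample:
intensity, noise, rotation, scale, translation) is fixed so streams are
stable across versions; σ scales a unit normal draw, so changing σ does not
shift the stream.

What the generator does *not* emulate: landmark-detector failure modes
(occlusion, profile poses, specular lighting), correlated landmark errors,
temporal structure of video, or real inter-subject anatomy. A green
benchmark therefore establishes that the pipeline recovers class structure
from landmark geometry under noise, subject effects, pose jitter and
deliberate class confusability — not that any particular accuracy carries
over to a real database.

## Evaluation

`random` folds: seeded shuffle, round-robin (sizes differ by ≤ 1).
`subject_independent` folds: whole subjects round-robin after a seeded
shuffle, so no identity straddles train and test. Every training split must
contain all six classes. The report carries per-fold accuracy, the pooled
6×6 confusion matrix (counts and row-normalized percentages, rendered to
one decimal but stored at full precision), a seed/parameter echo, and a
model-size accounting: parameters = 2 per internal node + one probability
per leaf per class, summed over all forests; operations = mean root-to-leaf
comparisons over a probe set plus 3·C arithmetic per fusion stage and one
multiply per group member for the chaining. The counting convention is this
package's own and is only claimed to be self-consistent.

On the packaged benchmark (T′ = 200 per forest, 5-fold subject-independent,
seed 42) the hierarchical model and the flat baseline both reach ≈ 99.8 %;
the stated world is easier than real databases, and at this noise level the
hierarchy's benefit shows as parity rather than a margin. All of this is
recomputed by the test suite, not asserted from memory.

## Numerical notes and limitations

* Angle invariance is asserted as |Δθ|/π ≤ 1e-8: a relative criterion is
  ill-posed for angles near zero, and π is the natural scale of the feature.
* Training at benchmark scale takes ~100 s per hierarchical model on one
  CPU (pure NumPy, one BLAS product per class per node); prediction is
  microseconds per face per 100 trees.
* The forest vote is deterministic given the seed; model files and
  evaluation reports from identical invocations are byte-identical.
* With pruning at 0.5 on data where no tree can beat chance (e.g. shuffled
  labels), training fails by design rather than returning a weak model; the
  chance-level sanity check in the tests disables pruning for exactly that
  reason.
* Six-class closed vocabulary; neutral, contempt and compound expressions
  are out of scope, as is anything upstream of landmarks.
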