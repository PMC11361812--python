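# Methods

## Data model and scaling

Input is one table per condition: rows are biological variables, columns are
ordered measurements (stages, tissues, time points). All conditions must
share the variable set and the measurement count; column order is never
changed, because the lag analysis interprets it as the measurement axis. At
least 3 measurements are required (a lagged Pearson correlation needs a
3-point overlap), and in practice the displacement taxonomy is only
informative from M ≈ 5 upward.

Every row is z-scored within its condition with the **sample (n−1) standard
deviation**. Whether the original procedure used population or sample sd is
not observable from the outside; the choice only rescales rows by a constant
factor and every downstream statistic (Euclidean BMU ranking on equally
scaled rows, Pearson correlations) is invariant to it. Rows that are constant
in *any* condition have no z-score there; the default policy drops them from
**all** conditions (keeping the set aligned) and records the action in the
scaling report, an `error` policy is available. Missing values are rejected
by default (optionally the affected rows are dropped); nothing is ever
imputed. Scaling is idempotent to 1e-9.

## Reference SOM

A batch SOM on a rectangular grid, Gaussian neighborhood on integer grid
coordinates, no toroidal wrap-around:

    c_j ← Σ_i h(j, bmu_i) x_i / Σ_i h(j, bmu_i),
    h(j, b) = exp(−d_grid(j, b)² / 2σ²)

with σ decaying linearly from `max(d1, d2)/2` to a final radius over the
epochs (default 100 epochs). The batch rule was chosen over the online rule
because its result is independent of row presentation order, which makes the
determinism contract (bit-identical codebooks for a fixed seed) trivial.

Two numerical choices matter:

* **Final radius 0.3.** At σ = 0.5 a neighbor at grid distance 1 still
  carries weight e⁻² ≈ 0.135, so final prototypes are visibly mixed with
  adjacent cluster means; at 0.3 the residual coupling is e^−5.6 ≈ 0.004 and
  non-empty prototypes converge to their cluster means, which is what both
  the prototype-correlation audit and the displacement classification need.
* **Initialization.** Distinct data rows (unique patterns) are sampled
  without replacement and placed at farthest-point positions of the lattice;
  any remaining neurons start as the blend of their two nearest placed
  prototypes. Initializing every neuron with a plain row sample degenerates
  on data with replicated rows: duplicate prototypes tie every best-match
  decision (ties go to the lowest neuron id), empty neurons then copy a
  single neighboring cluster exactly, and the resulting ρ = 1 prototype
  pairs defeat the grid search. PCA initialization was rejected because it
  is undefined for the degenerate small-N cases the trainer must accept.

Neuron ids are 1-based, row-major from the top-left, and stable across the
JSON serialization (the codebook is stored both as decimal and as float hex,
so a round trip is bit-exact). Empty neurons are legal; downstream they are
size-0 circles. BMU ties are broken toward the lowest neuron id.

## Grid-size search

The optimum grid is the largest candidate whose prototypes are mutually
non-redundant: no unordered pair with Pearson correlation strictly above θ
(default 0.9). Candidates are derived from a scalar s, `d1 = ⌈s−1⌉`,
`d2 = ⌊s−1⌋`, starting at `s = √(N/2) + 1` (an override is available) and
decrementing s by 1; the search only shrinks. Per candidate,
`n_maps_per_size` (default 5) maps are trained with seeds derived from the
master seed via a seed sequence; the first map with zero redundant pairs
accepts the size and its seed is recorded, so rebuilding the reference model
is exactly the accepted map. If every candidate down to `min_neurons`
(default 2) is redundant, the smallest candidate's least-redundant map is
returned with an `exhausted` flag — data with a single dominant pattern
legitimately ends there. Constant prototypes are flagged and never counted
as redundant (a correlation threshold cannot apply to them).

## Displacement classification

For an ordered neuron pair (source a, destination b) the per-lag statistic is
the Pearson correlation of the overlapping sub-series: at lag k > 0,
`corr(a[0:M−k], b[k:M])` — a positive lag means b's pattern occurs later
along the axis. Lags run over |k| ≤ M − min_overlap (min_overlap default 3);
zero-variance windows score 0. The peak is the maximum correlation, ties
broken toward lag 0 (prefer the conservative call), then toward the negative
lag.

Decision order: **flip** if the lag-0 correlation is ≤ flip_threshold
(−0.8); else **delay** / **early** if a qualifying peak at positive /
negative lag exceeds delay_threshold (0.8); else a qualifying lag-0 peak
above the threshold is *conserved-like*; else **other**. Flip is tested
first because a strongly anti-correlated pair can also show an off-center
positive peak, and "completely opposite behavior" is the most specific
category. Early shares delay's threshold; variable-level conservation is
always neuron identity and is never overridden by the pair relation.

**Window-significance gate.** A lag only *qualifies* for the peak if its
correlation is significant for its window length (one-sided t-test,
`r > t_c/√(t_c² + n−2)`, with the level — default 0.05 — Bonferroni-split
across the lags). The gate is what makes the taxonomy usable on short
profiles: a 3-point window of two unrelated smooth curves is almost always
near-collinear, so without the gate nearly every unrelated pair shows a
spurious off-center "peak" above any reasonable threshold. An exact shift is
unaffected (its true-lag correlation is 1, significant at every window
length), so shifted patterns are still recovered at every legal lag. Set
`peak_alpha=None` to rank raw peaks instead. The reported
cross-correlation profile itself is always the raw per-window statistic.

By construction the relationship matrix has a conserved diagonal, symmetric
flips (the lag-0 value is symmetric) and transposed early/delay with negated
peak lags (the lag profile of the reversed pair is the mirrored profile).

Displaced variables take the relation of (reference neuron → test neuron);
`net_edges` aggregates them per (condition, from, to, relation[, metadata
group]) with conserved variables tallied separately, so edge counts plus
conserved always equal N.

## Synthetic fixtures

The generator emulates the geometry the method assumes: K base profiles over
M ordered points, many noisy copies per profile (control), and a test
condition built by planted per-variable operations — identity, shift by k
positions (edges extended by linear extrapolation, not wrap-around: an
earlier/later activation along a staged axis), sign flip, or replacement by
a decoy pattern. Noise is Gaussian, expressed in units of the scaled
profile's sd, drawn independently per condition.

Because the reference map is trained on the control only, a displaced test
profile can only land on a neuron whose prototype *is* that displaced
pattern; the default profile set is therefore closed under the planted
operations: `{g, shift(g,+1), −g, decoy}` with g a narrow Gaussian bump.
Narrowness keeps the shifted sibling a genuinely distinct cluster
(lag-0 correlation ≈ 0.57, below θ), while the shift still peaks at exactly
1 at lag +1. The decoy is a W-shaped (alternating-slope) curve
orthogonalized against the centered span of the others: its lag-0
correlations are exactly 0 and its short windows are far from collinear with
the bump's tails, so every family↔decoy relation is "other" with a wide
margin. Replacement ops assign the decoy family's own profile (a variable
replaced by a pattern orthogonal to *every* prototype would be equidistant
from all neurons after scaling — the BMU would be decided by the tie rule,
not by the data). Shift ops are only planted on families whose shifted
profile exists in the set, flips only where the negation does.

The canonical spec (4 families × 25 variables, M = 7) plants 60 identity, 15
one-position shifts, 15 flips and 10 replacements. A second constructor
produces K mutually uncorrelated smooth profiles (centered Gram–Schmidt over
a curve bank) for grid-optimizer studies.

What the fixtures do **not** emulate: count-model noise, heteroscedastic
measurement error, correlated variables within a family, or batch effects.
Passing tests demonstrate the method's geometric behavior — recovery of
planted pattern transformations — not robustness to real sequencing noise.

## Problem sizes

The test suite and the acceptance script run the full pipeline on fixtures
of 100 variables × 7 (or 6) measurements, 5 seeds for the stochastic
checks, 10 fixtures for the optimizer battery, and 1000 Monte-Carlo draws
for the null-rate and BMU audits — sizes at which every quantity the
package reports is recomputed from scratch in a few seconds.

## Known limitations

* The initial-size heuristic `√(N/2)+1` is a pragmatic over-provisioning
  rule; the search never grows a map, so an override is provided for data
  whose pattern diversity exceeds the heuristic's start.
* Hyperparameters of the trainer (radius schedule, epochs) are package
  defaults, not a numerical reproduction of any particular SOM library;
  models trained elsewhere will differ prototype-by-prototype.
* Short profiles (M < 5) leave almost no usable lags, and displacement
  calls then reduce to conserved/flip/other.
* No statistical significance is attached to displacement *counts*
  (e.g. permutation tests across variables); the per-window gate concerns
  individual lag correlations only.
* With multiple test conditions each is mapped independently; the package
  does not model trajectories across more than two conditions at once.
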