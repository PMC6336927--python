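# Methods

## Model

A grid-cell module is idealised as a point on the unit torus: the pair of
lattice coordinates of the current location, reduced modulo one lattice tile.
For a module of scale *s* (world units), orientation *θ* and lattice basis
*B* (columns are the lattice axes; `square` = identity, `rhombic60` = a 60°
rhombus emulating hexagonal firing fields), a world movement Δx updates the
phase as

    φ ← (φ + B⁻¹ R(−θ) Δx / s) mod 1.

This is pure phase arithmetic: no firing-rate maps, no attractor or
oscillatory-interference mechanism for how grid responses arise. Path
independence, periodicity under lattice translations, and linearity of the
update hold exactly (to floating-point precision) for any nonsingular basis
and are enforced by property tests.

Discretisation divides each lattice axis into `bins` half-open intervals; the
single active cell of a module is `⌊φ · bins⌋` per axis. A *location code* is
the ordered tuple of module phases plus a reference-frame tag (an object id,
or the distinguished `body` / `environment` tags); its discretised *code key*
is the identity used for associative storage. Joint capacity is the product
of per-module cell counts, hence exponential in the number of modules
(10 modules × 20 states = 20¹⁰ exactly, as an arbitrary-precision integer).

A *displacement code* is the per-module phase difference of two location
codes, taken on the torus. The two defining operations are mutually inverse
by construction (`location₁ + d` and `location₂ − location₁`), and the
difference is invariant under common movement of both codes, which is what
makes a single displacement encode a rigid object-on-object placement.
Decoding a displacement back to a Cartesian vector is a brute-force search
over a candidate grid inside a disc: every candidate is encoded and compared
phase-wise; the minimum-norm match wins, ties broken lexicographically. This
is deliberately transparent rather than algebraic (no lattice reduction), and
it reports an explicit "undecodable within radius" failure rather than
guessing when no candidate matches.

Objects are learned as maps from code keys to feature labels by
path-integrating along an exploration trace from a uniform-random anchor.
Composition stores a child id plus one displacement per placement; feature
resolution checks the object's own map first (direct observations shadow
inherited ones), then recurses through components in insertion order under a
depth limit (default 5), which is also the only guard against recursive
structure — cycles are legal. Behaviors are sequences of displacement keys
replayed through a variable-order suffix model: every observed suffix of
length 1..max_order (default 3) maps to the set of symbols that followed it,
and prediction uses the longest matching suffix. This replaces the
neuron-level sequence memory of the biological proposal with an exactly
testable model having the same functional contract (high-order,
context-disambiguating prediction).

Recognition keeps an explicit list of (object, location) hypotheses — one
per stored key matching the sensed feature, posed at the key's bin centres —
rather than a superimposed sparse code; the computation (union, narrow by
move–sense, intersect across columns) is the same, but exact and enumerable
at desk scale. In `strict` mode (default) a hypothesis predicting no feature
where one was sensed is eliminated, which presumes the learning traces
covered the object's features; `lenient` mode keeps such hypotheses for
incompletely explored objects. Sensing "none" moves hypotheses but
eliminates nothing. Voting intersects the candidate object sets of all
non-empty columns and prunes to the intersection; an empty intersection is
flagged as disagreement and nothing is pruned.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `scale` | — | lattice period, world units (> 0) |
| `orientation` | 0 | lattice orientation, radians |
| `bins` | (5, 5) | phase bins per lattice axis; cells per module = bins_a·bins_b |
| `noise_sd` | 0 | per-step additive phase noise (phase units); off by default |
| `max_order` | 3 | longest suffix stored by the sequence memory |
| `depth_limit` | 5 | component recursion bound in feature resolution |
| decode `grid_step` | min scale / 20 | candidate-grid spacing, world units |
| recognition step cap | 50 | sensations before reporting failure |

Two stock module sets are provided. `ModuleSet.default()` follows the
literature convention for entorhinal modules: six modules, scales in
geometric progression with ratio 1.4, fixed pseudo-random orientations, 5×5
bins. `ModuleSet.integer_tuned()` (scales 2, 3, 4, 5; bins 4², 3², 4², 5²;
axis-aligned square lattices) is tuned so each unit world movement shifts
every module's phase by a whole number of bins. The object-learning and
recognition experiments use the integer-tuned set: recognition poses start
at bin centres and integrate continuously, and whole-bin steps keep those
poses exactly consistent with the keys written during learning, so the
soundness guarantee (the true pose is never eliminated under noiseless
sensing) is exact rather than approximate. With general scales or rotated
lattices a pose near a bin edge can discretise differently from the learned
key; that regime is supported but carries no exactness guarantee.

Numerical choices: phases are reduced into [0, 1) with a guard folding a
floating-point result of exactly 1.0 back to 0.0; bin indices snap phases
within 1e−9 below a bin edge upward (wrapping at 1.0), so exact lattice
fractions such as 2/3 on a period-3 module bin as mathematics says they
should. Continuous-phase comparisons use the max-over-axes circular distance
with tolerance min bin width / 4 where a tolerance is needed. Decode
tie-breaks are lexicographic on (‖v‖, v_x, v_y).

## Synthetic worlds

The generator emulates objects in the style of everyday items explored by
touch: `n_features` labelled points (labels uniform over an alphabet of 8)
at distinct integer coordinates on a 10×10 canvas, 50 objects per library by
default, explored by sweep or random-walk traces that move point-to-point
and sense on arrival. Integer coordinates keep worked examples exact and
the brute-force oracles trivial. What this does *not* emulate: continuous
feature descriptors or sensor noise beyond an optional label flip, object
rotation relative to the sensor (the framework leaves cortical orientation
coding open, so rotated-object recognition is not claimed), occlusion,
hierarchy across spatial scales, or realistic exploration statistics.
Passing tests therefore show the location-code machinery is exact and the
recognition logic sound under idealised sensing — not that the approach is
robust to real sensory data.

Experiment sizes were chosen to keep every run to seconds on one CPU:
recognition uses 30 trials per column-count condition over a 50-object
library; collision statistics use 10,000 trials of up to 50 anchor draws at
capacity 625; the decode identity uses 100 random vectors on a 0.1-step
grid. The recognition experiment shares one world across column-count
conditions and derives each trial's walk from per-(trial, column) seeds, so
column 0's library and trajectory are identical with and without voting
partners and the voting comparison is paired, not merely distributional.

## Design choices that were genuinely open

- **Anchors** are uniform-random per learned object and stored with the
  model; nothing in the framework specifies how anchoring is chosen, only
  that representations are unique per object.
- **Feature conflicts** at an already-written key raise an error instead of
  overwriting (surfacing discretisation collisions early); `force=True`
  permits overwrite for noisy experiments.
- **Displacement resolution** reuses the grid modules' bins; the proposal
  pairs each grid module with a displacement module but names no separate
  resolution.
- **Frames**: subtraction accepts cross-frame inputs (that is how
  composition is expressed); addition demands an exact frame match, which
  catches plumbing errors in composite traversal.
- **Hypothesis enumeration** instead of superimposed sparse codes, and a
  suffix model instead of neuron-level sequence memory — both chosen for
  exactness and transparent testing; both are deliberate departures from the
  biological mechanism at equal functional contract.

## Known limitations

Single spatial level (no cortical hierarchy), no orientation/rotation
handling, point-like activity (one active cell per module; real grid
activity is a broad bump), no mechanistic account of grid formation, and
recognition noise tolerance is exposed as a parameter without a calibrated
target. The decode search is O(candidates × modules) and intended for
desk-scale radii, not long-range navigation.
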