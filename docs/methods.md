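# Methods

## The index

`shiftcodec` assigns each residue a scalar in (0, 1) by compressing its
assigned chemical shifts through a per-amino-acid-type autoencoder.  The
design rests on three assumptions:

1. Chemical shifts of a residue's atoms are jointly informative about one
   dominant latent degree of freedom (roughly, position on the
   sheet–coil–helix continuum), so a one-neuron bottleneck retains most of
   the structure-related signal.
2. Shift scales differ between atoms (¹⁵N ≈ 100–130 ppm, ¹H ≈ 6–10 ppm)
   and between residue types, so scaling must be per (residue type, atom).
3. The direction the network learns is arbitrary; a post-hoc orientation
   step (flip `s → 1 − s` so that sheet-labeled calibration residues score
   above helix-labeled ones) makes indices comparable across models.

## Atom schemes

A scheme fixes, per residue type, the ordered atom list feeding the model:

* **common** — N, C, CA, CB, H, HA (no CB for Gly, no H for Pro).
* **minimal** — N, H, CA (no H for Pro); a `carbonyl=True` variant
  substitutes C for CA, the choice suited to sparse free/bound data sets
  where CA assignments are often missing.
* **full** — backbone N, C, CA, H, HA plus CB and HB where chemically
  present.  The shipped per-type lists are an explicit, user-overridable
  registry: real deployments should override it to match the atom
  abundance of their own training pool.

Atom names are canonicalized (upper case, `HN → H`).  Only atoms known to
some scheme are retained at parse time.

## Training-pool curation and scaling

Percentile filtering removes a *whole residue* if any present scheme atom
falls strictly outside the [1st, 99th] percentile (linear interpolation
between order statistics) of its (type, atom) distribution.  This targets
referencing artifacts, which offset many atoms of a spectrum coherently.
Filtering is a training-time curation step only; at inference, out-of-range
values are clipped into [0, 1] rather than rejected, so residues of unseen
proteins are never silently dropped.

Min–max scaling is fitted per (type, atom) on the filtered pool;
`unscale(scale(x)) = x` exactly (to float precision) for unclipped values.
Parameters persist as a JSON sidecar versioned with the model bundle.

## Architecture and optimization

Encoder `k → 100 → 100 → 1`, ReLU on hidden layers, sigmoid at the
bottleneck; decoder mirrors it `1 → 100 → 100 → k`.  The decoder output
activation is a sigmoid so reconstructions live in the same [0, 1] space as
the scaled inputs (the encoder's activations are prescribed; the decoder
output's is a range-consistency choice).  With k = 6 and 100 hidden units
the model has 21,807 trainable parameters.

Training: Adam (lr 1e-3, β = 0.9/0.999), batch 64, mean squared
reconstruction error, at most 500 epochs with early stopping (patience 20)
on a 10% validation split, best-weights restore.  He initialization for
ReLU layers, Glorot for sigmoid layers, all drawn from a seeded generator;
two runs with the same config and seeds produce identical profiles.
Training uses complete cases only (residues with every scheme atom
present); one model per amino-acid type, 20 per scheme.

Numerical notes: the sigmoid is evaluated in a numerically stable split
form; indices are strictly inside (0, 1) for any finite input; decoding is
a deterministic single-valued function of the index; decoding of an
oriented model evaluates the raw decoder at `1 − s`.

## Synthetic data

The generator emulates class-conditional shift distributions: shift =
class mean + deterministic residue-type offset + Gaussian noise, with
helix/sheet/coil class means following known secondary-shift directions
(CA and C high in helix, CB and N high in sheet, HA low in helix) at
realistic ppm magnitudes, proline lacking H and glycine lacking CB,
configurable per-atom missingness, and optional contiguous same-class
blocks.  A `misreference_rate` fraction of residues (default 3%) carries a
shared-sign 6-sd offset on every atom, emulating the referencing errors the
percentile filter exists to remove; this residue-level correlation of
extremes is why whole-residue removal stays near the artifact fraction
(~4%) instead of compounding per atom.  `SyntheticSpec.two_class` builds a
helix/sheet pool with a chosen per-atom class separation for
structure-recovery experiments.  `generate_pair` copies a free-state
protein and shifts every atom of a contiguous patch by a chosen number of
sd, emulating a binding interface between free and bound forms.

What this data does *not* emulate: sequence-dependent neighbor effects,
ring currents, anisotropic or correlated within-class noise, and realistic
assignment-missingness patterns.  Passing tests therefore demonstrate that
the estimator recovers planted structure under its own assumptions, not
that it matches published indices on real BMRB entries.

## Study conditions used by the tests and acceptance script

* Structure recovery: helix/sheet pools of 450 proteins × 100 residues
  (≈ 2,200 residues per type), class separation 6 sd per atom, evaluation
  on 60 held-out proteins.  The separation is chosen from a closed-form
  capacity bound: with a one-neuron bottleneck and independent per-atom
  class-conditional noise, the per-atom reconstruction correlation is
  bounded by `sqrt((d²/4)/(d²/4+1))` at separation `d` sd — 0.83 at d = 3,
  0.93 at d = 5, 0.95 at d = 6 — so d = 6 leaves a margin over the 0.9
  recovery target that exceeds estimation noise.
* Percentile filtering: pools of 10,000 residues.
* Stability scan: 5-size subgrid {10, 45, 80, 115, 150} of the 15-size
  grid {10, 20, ..., 150}, one residue type.
* Patch recovery: minimal-scheme bundle trained on 60 proteins; 20
  seeded free/bound pairs, patch 5 of 100 residues, 4-sd perturbation.

## Known limitations

* **The index is only rank-identified.**  For any strictly monotone warp
  `g`, replacing the bottleneck value `s` by `g(s)` and composing the
  decoder with `g⁻¹` leaves the reconstruction loss unchanged, so the
  *distribution* of the index over (0, 1) is set by initialization and
  training dynamics, not by the data.  Consequently per-class median index
  values are not stable across hidden-layer sizes in this implementation:
  converged models of different widths reach equal loss with per-class
  medians differing by 0.2–0.5, and a tied-weight (transposed-decoder)
  variant reduces but does not remove the effect.  Rank-based quantities —
  AUC, orientation, divergence calls on index differences within one model,
  patch ranking — are unaffected.  Conclusions that depend on the absolute
  location of index values across differently-sized models should not be
  drawn.
* The full scheme's per-type atom lists are an approximation; override the
  registry for serious use.
* No chemical-shift re-referencing is performed; severely misreferenced
  inputs are only mitigated by training-pool filtering and inference-time
  clipping.
* The Gaussian divergence model fits absolute index differences with a
  sample mean and sd; with fewer than 5 observed differences no calls are
  made, and a zero-spread delta distribution yields no flags.
* Exact rank tests enumerate up to 12 (rank-sum) / 15 (signed-rank)
  observations and use midranks for ties; beyond that, tie-corrected
  normal approximations from scipy are used.
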