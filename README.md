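# shiftcodec

Compress a residue's NMR chemical shifts into a single, comparable number.

Backbone chemical shifts (N, H, CA, CB, C, HA, ... in ppm) carry rich,
entangled information about a residue's conformation and dynamics, but they
live in an atom-dependent multidimensional space: you cannot directly
compare a glycine's shifts with a valine's, or a free state with a bound
state, atom by atom.  `shiftcodec` trains one small autoencoder per
amino-acid type that squeezes the scaled shift vector of a residue through
a single sigmoid bottleneck neuron.  The bottleneck value — a number in
(0, 1), oriented so sheet-like residues score high and helix-like residues
low — is a per-residue index that summarizes the shift information and can
be compared across residue types, proteins and states.

It is aimed at NMR spectroscopists and structural bioinformaticians who
want to compare proteins or protein states through assigned chemical shifts
without choosing random-coil reference values.

## Model

For residue type *t* with scheme atoms `a_1..a_k`, shifts are min–max
scaled per (type, atom) over a curated training pool,

    x_scaled = (x − min(X)) / (max(X) − min(X)),

after removing whole residues carrying any atom outside its [1st, 99th]
percentile (a guard against misreferenced spectra).  The encoder is

    x ∈ [0,1]^k → ReLU(100) → ReLU(100) → σ(1)  =  s ∈ (0,1)

and the decoder mirrors it (`s → ReLU(100) → ReLU(100) → σ(k)`), trained to
minimize mean squared reconstruction error.  Because the sigmoid is
bijective, every index value decodes to one unambiguous set of simplified
shifts.  The learning direction is arbitrary, so each model carries an
orientation flag (`s → 1 − s`) calibrated on helix/sheet-labeled residues.

Downstream, two index profiles are aligned globally (BLOSUM62, affine
gaps); positions whose absolute index difference is improbable under a
Gaussian fitted to all differences (two-sided p < 0.05) are flagged as
divergent.  For free/bound pairs the amide perturbation
`d = sqrt(ΔδH² + (0.14·ΔδN)²)` and a naive consensus (min–max-scaled CSP +
min–max-scaled index difference) rank candidate interaction-patch
residues, with Wilcoxon rank-sum / signed-rank tests (exact by enumeration
at small n) for significance.

## Worked example

Everything runs on synthetic data with known ground truth — no downloads:

```python
import shiftcodec as sc

spec = sc.SyntheticSpec.two_class(separation=6.0, n_proteins=60,
                                  length=(80, 80), seed=11)
tables, truth = sc.generate_dataset(spec)
model = sc.ShiftCrypt(scheme="common", seed=7).fit(tables, labels=truth.labels)
profile = model.transform(tables[0])
for e in profile.entries[:5]:
    cls = truth.labels[(tables[0].entry_id, e.chain_id, e.residue_number)]
    print(f"{e.residue_number:3d} {e.residue_type} {e.index:.3f} {e.status}  ({cls})")
```

prints

```
  1 D 0.476 ok  (helix)
  2 D 0.424 ok  (helix)
  3 S 0.487 ok  (helix)
  4 L 0.314 ok  (helix)
  5 N 0.886 ok  (sheet)
```

— one index per residue, in (0, 1), with sheet-labeled residues high
(median 0.908 on this protein) and helix-labeled residues low (median
0.450).  Residues missing a scheme atom get `status=missing_atoms` and no
index; `encode_with_fallback` can fill them from a bundle trained on a
smaller atom scheme.

The same pipeline is available from the shell:

```sh
shiftcodec simulate --out data/ --seed 7
shiftcodec train    --data data/ --scheme common --out bundle/ --seed 7
shiftcodec encode   --in data/syn0000.tsv --bundle bundle/ --out profile.tsv
shiftcodec compare  --a free.profile.tsv --b bound.profile.tsv \
                    --shifts-a free.tsv --shifts-b bound.tsv --out report.tsv
```

`convert` translates between NMR-STAR (v3.1/v2.1 `Atom_chem_shift` loops)
and a plain TSV dialect (one row per residue, one column per atom).

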