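# Methods

## Pocket graphs

A pocket file (PDB-format ATOM/HETATM records, one pocket per file) is
parsed into its non-hydrogen atoms; only the first alternate location is
kept and residue indices are renumbered consecutively (0-based) in chain
order. Nodes are atoms; edges connect every atom pair within a contact
cutoff of 4.5 Å, stored symmetrically. The edge attribute separates
covalent pairs from contacts: a pair is classified covalent when its
distance is at most 1.9 Å (2.1 Å when S or P is involved); multiplicity
defaults to 1 unless CONECT records (duplicated neighbour serials) or a
user bond table say otherwise. PDB files carry no bond orders, so the
distance rule is the standard fallback and the attribute mainly
distinguishes bonded from non-bonded edges.

Node features, in fixed column order: hydrophobicity, charge,
binding-site propensity, SASA (Å²), sequence entropy, and the three
normalized coordinates (Å).

* Residue-level scalars (hydrophobicity — Kyte–Doolittle; net formal
  charge at physiological pH; binding propensity rescaled to [0, 1]) are
  broadcast to every atom of the residue. They ship as an editable YAML
  table (`pockmol/data/residue_properties.yaml`) with an explicit UNK
  fallback row (all zeros) for non-standard residues.
* SASA is computed by Shrake–Rupley sphere sampling: 960 quasi-uniform
  points per atom on a golden-spiral lattice, probe radius 1.4 Å, Bondi
  van der Waals radii. A fully buried atom scores exactly 0; a single
  isolated atom reproduces the closed form 4π(r+p)² to sampling
  resolution. The implementation is cross-checked in the tests against
  an independent random-point sampler at 10× density and against
  biotite's Shrake–Rupley.
* Sequence entropy defaults to 0 when no alignment profile is supplied
  (an entropy column requires an MSA the tool cannot fabricate); a
  per-residue profile can be passed as a TSV.
* Coordinates are centered at the origin and rotated onto principal
  axes, ordered by decreasing variance. The eigenvector sign ambiguity
  is resolved by forcing each axis' largest-magnitude coordinate
  positive, making the transform deterministic; clouds with fewer than
  3 points or rank-deficient spread fall back to centering only and the
  graph is flagged (`normalized=False`).

## Token grammar

Molecules are tokenized with a self-referencing, valence-constrained
grammar in the SELFIES style, implemented in `pockmol.grammar`. The
decoder is a derivation machine: atom tokens (e.g. `[C]`, `[=O]`) attach
a new atom to the current one with a bond order capped by both atoms'
remaining valences; `[Branch1/2]` and `[Ring1/2]` tokens are immediately
followed by index tokens carrying the branch length or ring gap
(information is localized — no long-range matching as in SMILES);
instructions that cannot be satisfied are skipped. Because no derivation
step can exceed an element's maximum valence (C 4, N 3, O 2, S 6, P 5,
halogens 1 — each an RDKit-sanitizable bond count for the neutral atom),
**every** token sequence decodes to a valid molecule; the test suite
verifies 100% validity over 10,000 uniformly random sequences. The
encoder direction kekulizes, strips stereochemistry, and walks a
deterministic DFS over the canonical atom ordering, so
decode(encode(m)) equals m under RDKit canonicalization — the single
molecule-identity definition shared by the tokenizer, the frequency
ranking and the evaluation layer.

The grammar covers neutral organic molecules over {C, N, O, S, P, F,
Cl, Br, I}; charges, isotopes, radicals and stereo descriptors are out
of scope and rejected at encode time with a clear error. The alphabet
has 21 chemical tokens; vocabularies add `<pad>` (index 0) and `<eos>`
(index 1). There is no start-of-sequence token because the graph
embedding occupies the decoder's first input slot. Default length cap:
140 tokens.

## Encoder

Per layer and channel c: `(1+ε_c)·x_i + Σ_j h_ω_c(e_ij)·x_j`, where
ε_c is trainable (initialized 0) and h_ω_c is a two-layer (tanh) network
from the scalar edge attribute to a scalar weight. Channel outputs are
concatenated and passed through the update network h_θ (linear → ReLU →
linear). Layer outputs are aggregated by a jumping-knowledge network
(concatenation by default; `max`/`sum` are available in config) and read
out by Set2Set (LSTM-driven attention, output length twice the node
dimension). The whole map is permutation-invariant; the message-passing
layer is tested against a dense N×N reference to 1e-6 and invariance to
1e-5 over 100 relabelings.

Numerical conventions: all floating math is float32. Raw node features
keep physical units in the `PocketGraph`; the encoder rescales them on
entry by fixed constants (hydrophobicity /4.5, SASA /50 Å², coordinates
/10 Å) so every input is O(1) — without this the recurrent gates
saturate and training collapses to a pocket-independent language model.
The Set2Set LSTM bias is initialized with small random values; with a
zero bias and zero initial state the first hidden states are
structurally zero and the recurrent weights receive no gradient.

Defaults (library-scale, fully configurable): 4 layers, 8 channels,
hidden width 64, 3 Set2Set steps. The desk-scale experiments below use
a smaller 2×4×16 model. Encoder weights are randomly initialized from a
recorded seed; a checkpoint-loading hook accepts pretrained weights but
none are required.

## Decoder and training

Single-layer GRU (hidden 512 by default; 64 at desk scale), token
embedding 128 (32 at desk scale). The graph embedding is linearly
projected to the token-embedding width and consumed at step 0 with a
zero initial hidden state; teacher forcing feeds ground-truth previous
tokens, inference feeds the model's own samples and stops at `<eos>` or
the length cap (truncations are flagged and excluded from ranking but
counted). `<pad>` keeps finite probability under the softmax (the
sequence measure is over the full vocabulary, and the tests verify it
sums to one by exhaustive enumeration) but is masked out of the sampling
support; padded steps are masked from the loss. The loss is the mean
over sequences of the per-sequence sum of negative log-probabilities,
which keeps the scale independent of batch size.

Training uses Adam (lr 1e-3 by default, 5e-3 in the desk-scale
experiments), global gradient-norm clipping at 5, seeded epoch-level
shuffling, batch size 32 (8 at desk scale). A NaN loss aborts with a
diagnostic. Checkpoints are single npz archives holding both halves'
tensors, the configs, and the vocabulary; a reloaded checkpoint
reproduces the training loss bit-exactly on CPU.

Dataset assembly follows the study protocol: records with synthetic
accessibility score ≤ 1 or ≥ 6 are removed (trivially simple or
implausibly complex molecules; the strict interior 1 < SA < 6 is kept),
with the Ertl–Schuffenhauer estimator from RDKit's contrib tree as the
default scorer and any SMILES→float callable accepted in its place; the
filtered set is split 90/10 into train/test under a recorded seed.

## Synthetic fixtures and the planted-signal experiment

The fixture generator emulates pocket files (compact atom clusters with
nearest-neighbour spacing 1.2–2.0 Å, diameter < 40 Å, standard residue
names, realistic element mix) paired with ligands from a built-in
library of 20 valid neutral drug-like molecules spanning 3–30 heavy
atoms. It does **not** emulate real protein geometry — no side-chain
topology, secondary structure or packing — so passing tests demonstrate
that the machinery learns and evaluates correctly, not that the model
is accurate on real pockets.

In a planted dataset, pocket *i* is biased toward signature residue *i*
with probability `signal_strength` per residue, injectively mapped to
ligand *i*; the signal lives only in encoder-visible graph features,
never in identifiers. With `signal_strength = 0` all pockets share one
residue distribution (null control). The overfit-recovery experiment —
the desk-scale stand-in for full-dataset hit-rate benchmarking — trains
a small model (encoder 2 layers × 4 channels × width 16, Set2Set 3
steps; decoder embedding 32, hidden 64) on 8 pockets of 50–90 atoms for
400 epochs (~30 s on one CPU core) and asks greedy decoding to return
the exact planted ligand. Under the fixed study seeds it recovers at
least 7 of 8 pockets, while the unconditional baseline (embedding
replaced by a constant) is structurally capped at 1 of 8: this
separates learning P(molecule | pocket) from learning P(molecule).
Optimization at this scale is initialization-sensitive — some seeds
plateau before full recovery — so the experiment is defined as a fixed
deterministic protocol with its seeds recorded; this is a known
limitation, not averaged away. Notably, a *frozen* randomly initialized
encoder still yields distinct embeddings for distinct pockets (it is an
almost-surely injective feature map), so freezing the encoder does not
remove the conditioning signal; only the constant-embedding baseline
does.

## Generation and evaluation

Sampling draws molecules in batches (default 2,048; 20,480 total takes
exactly 10 batches) conditioned on one pocket embedding, decodes and
canonicalizes them, groups identical molecules, ranks by frequency with
deterministic lexicographic tie-breaking, and keeps the top 100.

Evaluation scores each pocket by the maximum Tanimoto coefficient
between its samples and its label ligand over Morgan fingerprints
(radius 2, 2048 bits — the community-default binary substructure
fingerprint; absolute TC values depend on this choice and the config is
swappable). Hit rates are the percentage of pockets at thresholds
0.7/0.8/0.9/1.0 and are nonincreasing in the threshold by construction.
The Fisher–Pitman permutation test compares group means two-sided:
exhaustive over label assignments when their count fits the permutation
budget (p = hits/total, observed assignment included), Monte-Carlo with
an add-one estimator otherwise (p is never 0). Type-I error at α = 0.05
calibrates to the 3–7% band over 1,000 null simulations. Pocket-size
statistics bin pockets at <100, 100–160, 161–220 and >220 heavy atoms
and report linear-interpolation quartiles and IQR of ligand sizes.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely at desk scale:
8–20 synthetic pockets of 20–120 atoms, 10,000-sequence grammar sweeps,
20,480-sample generation runs with a small model, 1,000-replicate test
calibration. These sizes make the full pipeline reproducible in minutes
on one CPU core; they are stand-ins for, not reproductions of,
training on tens of thousands of real pockets.

## Known limitations

* The grammar's chemical subset excludes charged/isotopic/stereo
  species; label ligands outside the subset must be neutralized or
  excluded upstream.
* Bond multiplicities on pocket edges are heuristic (distance rules +
  CONECT); the hook for a curated bond table exists.
* The desk-scale training experiment is init-sensitive (see above); at
  realistic data scale this is the usual deep-learning variance, not a
  property of the method.
* Beam search, attention over node embeddings, and drug-likeness or
  toxicity filtering of samples are out of scope.
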