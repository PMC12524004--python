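# Methods

## The model

`plm2mol` implements conditional de novo ligand design: given only a
fixed-length embedding *x* of a protein (a 1024-component ProtT5-style
protein-language-model vector in full-scale use), a decoder-only
transformer models the conditional distribution *f*(*l* | *x*) over
ligand SMILES strings *l* and is sampled autoregressively to propose
candidate binders.

A molecule is a token matrix *S* ∈ {0,1}^(L×s): each curated SMILES is
split into single characters over an *s* = 33 symbol alphabet (with the
two-letter halogens substituted, Cl→D and Br→E), delimited by
begin-of-sequence `$` and end-of-sequence `~`, and right-padded with
`€` to *L* = 97 positions (raw length ≤ 95).  The decoder input is
*Y* = *S E* + *P*, with a learned token embedding *E* ∈ R^(s×d_m) and
the constant sinusoidal positional matrix *P* ∈ R^(L×d_m).

The network stacks *N* = 2 identical blocks of

1. causally masked multi-head self-attention (unchanged from the
   standard transformer decoder),
2. protein cross-attention, where per head *i* the queries come from
   the previous sub-layer, *Q_i* = *Y W^Q_i*, while the key and value
   are single rows computed from the protein vector,
   *K_i* = *x W^K_i* and *V_i* = *x W^V_i*, so that
   *Z_i* = softmax(*Q_i K_iᵀ*/√d_k) *V_i* and
   *Z* = concat(*Z_1..Z_h*) *W^O*,
3. a position-wise feed-forward network of width 4·d_m,

each sub-layer wrapped in residual addition followed by layer
normalization (post-norm).  Because the key axis has length one, the
softmax in step 2 is identically 1 and every row of *Z_i* equals
*V_i*: the protein conditions all positions identically before residual
mixing, a property asserted by the tests.  Full-scale defaults are
*h* = 32 heads and d_m = 1024 (equal to the embedding width, a hard
contract of the architecture); 100 epochs with batches of 200 at a
fixed Adam learning rate of 0.001.

Training is teacher-forced next-token cross-entropy with padding
targets excluded.  The loss choice, Glorot-uniform initialization, and
post-norm placement are the standard options for this architecture
family; all are configurable.  The implementation is pure numpy with
hand-derived backpropagation; gradients are verified against central
finite differences in the test suite, and the full forward pass is
verified against an independent per-head, per-position dense oracle at
tolerance 1e-5.

## Generation

Sampling starts from `$` and repeatedly feeds the prefix through the
decoder; the next character *c_k* is drawn from *p_k* = softmax(*y_k*)
by inverse-CDF sampling: draw *r* uniform on [0, 1) and take the
smallest index whose cumulative probability strictly exceeds *r* (the
tie case "cumulative exactly equals *r*" has probability zero, so a
boundary convention is required; strict inequality on a half-open
interval is used).  Generation stops at `~` or at the encoding width
(the string is then flagged truncated).  The structural delimiters `$`
and `€` are masked out of the distribution before sampling; no
temperature, top-k or beam search is applied.  Each per-protein sample
set draws from one stream seeded from (global seed, protein id); the
default set size is 1000 molecules per protein.

## Data curation

Per-record stages, in order: optional record filters (affinity
≤ 100 nM by default, assay/organism filters only when the fields are
present); SMILES parsing (failures are rejections, not errors);
stereochemistry removal; desalting (keep the fragment with the most
heavy atoms, ties broken by molecular weight) and neutralization by
proton addition/removal (species that cannot be neutralized are
rejected at the desalt stage); rejection of carbon-free structures;
rejection of any element outside {H, C, N, O, F, Br, I, Cl, P, S}
(this whitelist subsumes a separate metal check); canonical SMILES
output.  Dataset assembly deduplicates (protein, canonical SMILES)
pairs, then trims unique ligands whose SMILES length falls strictly
outside the [2.5, 97.5] percentile band of the unique-ligand length
distribution (linear-interpolation percentiles, inclusive survival
bounds; computed over unique ligands rather than pair rows — both
conventions are defensible, this one avoids weighting by ligand
promiscuity and is configurable).

## Train/test splitting

Splits are made at the protein level so that every (train, test)
protein pair has global-alignment similarity below 80%.  Similarity is
scored with Needleman–Wunsch global alignment under identity scoring
(match +1, mismatch 0, gap 0 — the alignment score is then the maximum
number of identically aligned residues), normalized by the longer
sequence length.  The published protocol names the algorithm but not
the scoring matrix; identity scoring is the simplest defensible choice
and a substitution-matrix mode can be configured through the aligner.
Proteins are grouped into single-linkage clusters of the ≥-threshold
similarity graph and clusters are assigned whole to one side by a
seeded randomized greedy packing targeting the requested fraction
(default 2/3) of interaction pairs in training.  Whole-cluster
assignment makes the constraint structural rather than statistical:
no cross-set pair can reach the threshold.  Distinct seeds give the
independent replicate splits.

## Quality metrics and evaluation statistics

Validity is the percentage of generated strings RDKit can parse;
unicity the percentage of distinct canonical forms among the valid;
novelty the percentage of unique forms absent from the training
ligands (a "new molecule" is a generated, valid, unique molecule not
in the training set; novelty is measured against the global training
ligand set).  Internal diversity is the mean Tanimoto distance over
unordered distinct pairs and MaxSim the mean, over generated
molecules, of the maximum Tanimoto similarity to the reference
actives, both on Morgan fingerprints of radius 2 (2048 bits — the
community default width).  QED, the Ertl–Schuffenhauer synthetic
accessibility score, Crippen logP, molecular weight and PAINS
substructure alerts come from their published RDKit implementations.

The DTI statistics consume externally predicted (protein, molecule,
score) tables; the predictor itself is out of scope.  For each protein
A the comparison sets are: generated-for-A (POS_G), generated for other
proteins (NEG_G), known ligands of other proteins (NEG_D), and known
binders of A (TRUE_POS); negatives exclude all molecules associated
with A, are sampled without replacement (seeded), and every comparison
is equal-sized.  AUC = U/(n₁n₂) with midrank tie credit; the one-sided
Mann–Whitney p uses exact enumeration for n₁n₂ ≤ 200 without ties and
the tie-corrected normal approximation otherwise.  Multiplicity is
controlled by Benjamini–Hochberg FDR; enrichment of true positives
above a fixed score threshold (default 0.923, the recommended
high-precision operating point of the upstream predictor) uses the
one-sided Fisher exact test; paired per-protein AUC vectors are
compared by Pearson correlation.  Comparisons against known binders
are restricted to proteins with at least 10 known ligands.
Reproduced-ligand mining matches generated canonical SMILES against the
known-pair table: a *proper* hit reproduces a known ligand of the
generating protein, a *repurposed* triple (A, l, B) reproduces a ligand
known only for a different protein.

## Synthetic fixtures

The generator produces the study conditions at desk scale.  Molecule
families are enumerated from hand-written scaffolds (alkyl substituent
grids on amide, benzyl ether, piperidine, tert-butylphenyl and
sulfonamide cores) restricted to whitelist elements, with no
stereocenters and no charges; members are emitted in canonical form,
so they survive curation unchanged, are pairwise disjoint across
families, and lie within the 24–95 character window of the full-scale
corpus.  Protein embeddings are drawn as family centroids
(spherical standard Gaussian in d dimensions) plus isotropic noise
σ = 0.1 — separated clusters in which family identity is recoverable,
the desk-scale stand-in for the binding-relevant structure of real PLM
embeddings.  Synthetic amino-acid sequences are per-family templates
with 5% per-residue point mutations, planting ≥80% within-family and
<80% across-family similarity for the split tests.  Score fixtures
draw positives from Normal(δ, 1) and negatives from Normal(0, 1),
whose population AUC is Φ(δ/√2) in closed form.

What the fixtures do *not* emulate: real chemical diversity (members
share scaffolds), binding physics, the long-tailed ligand-count
distribution of curated corpora, or the geometry of real PLM
embeddings.  Passing the desk-scale tests therefore demonstrates the
correctness of the machinery and the learnability of embedding
conditioning, not full-scale generative performance.

### The conditional-recovery experiment

Three families of 200 molecules, 30 proteins (10 per family), embedding
dimension 32, a 2-layer/2-head/d_m = 32 decoder trained 25 epochs
(batch 200, lr 0.001) on all 6000 (protein, molecule) pairs, then 40
molecules sampled from a *held-out* embedding of each family (a fresh
draw from the family's centroid, never used in training).  The claim
verified: for every family f, the fraction of generated molecules that
are exact members of family f strictly exceeds the fraction belonging
to either other family.  These problem sizes are the smallest at which
the conditioning signal is reliably learned on a single CPU in a few
minutes; they are fixed, seeded defaults.

## Numerical choices and degenerate inputs

* Layer-norm epsilon 1e-5; float64 arithmetic throughout (small
  models; enables tight oracle and finite-difference comparisons).
* `sample_index` guards against cumulative sums falling epsilon short
  of 1 by returning the last index.
* Constant identical scores on both sides of an AUC comparison return
  (0.5, 1.0) by convention; degenerate Fisher tables return p = 1;
  zero-variance Pearson inputs return an undefined marker rather than
  a value.
* Unparseable SMILES are stage-recorded rejections in curation and
  per-molecule exclusions (logged) in metrics, never exceptions.
* Vocabulary mismatches are errors naming the character and position;
  the one-hot width is a model contract, so the alphabet is never
  silently extended.

## Known limitations

* The full-scale configuration (d_m = 1024, h = 32, L = 97,
  ChEMBL-sized corpora) is expressible but not trainable in reasonable
  time in this pure-numpy implementation; desk-scale configurations
  are the supported regime.  GPU/distributed training is out of scope.
* The pipeline's small preset trains on two of three families (the
  third is held out by the similarity split), so test-side generation
  quality is near zero at toy scale — the expected behavior for a
  memorization-scale model confronted with an unseen family, shown
  honestly in the pipeline metrics.
* Exact Mann–Whitney enumeration is used only for small tie-free
  samples; elsewhere the tie-corrected normal approximation applies.
* Neutralization follows the RDKit uncharger; exotic zwitterions that
  cannot be neutralized are rejected rather than kept charged.
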