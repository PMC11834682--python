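# Methods

`degradict` treats biodegradation product prediction as sequence-to-
sequence translation over SMILES strings: the reactant string goes into
an encoder–decoder transformer, and ranked candidate product strings
come out of a beam decoder with raw sequence probabilities attached.
This note records the model, the conventions around it, the choices
that were genuinely open, and what the synthetic test corpus does and
does not demonstrate.

## Standardisation

String equality must mean molecule equality before any of the
evaluation machinery is sound. Every compound therefore passes through:

1. **Stereo removal.** Chirality tags and double-bond geometry are
   cleared on the parsed molecule, not by deleting `@`, `/`, `\`
   characters from the string — raw character deletion can corrupt
   ring-closure syntax in pathological writings. The contract is on the
   output: no stereo markers survive.
2. **17 SMIRKS rewrite rules**, fixing protonation conventions
   (carboxylic acids → carboxylates, phenols → phenolates, sulfonic /
   sulfuric / phosphoric acids → anions, ammonium → amine, enol ↔ keto)
   and replacing the Coenzyme A moiety with `[O-]`. The rules are
   applied with RDKit's reaction engine on explicit-hydrogen molecules.
   Because RDKit copies unspecified atom properties from the matched
   reactant atom into the product, the three templates whose chemistry
   is "remove H and neutralise" carry an explicit `+0` product charge;
   the matching patterns are unchanged.
3. **Canonicalisation** with RDKit's canonical SMILES writer. The
   guarantee needed is "equal molecules, equal strings", not any
   particular canonical form.

Each rule is applied to a fixpoint, in list order, and the whole list
is repeated until a full pass changes nothing. The outer loop matters:
enolate protonation (rule 9) can create an enol that the enol→keto rule
(rule 1, earlier in the list) consumes, and a single pass would leave a
non-idempotent result. Termination is safe because rule 9 is the only
protonating rule and its output feeds only deprotonating/ketonising
rules; a hard cap of 20 passes guards against pattern-set edits ever
introducing a productive cycle.

Multi-compound strings are split into fragments, standardised
independently, and re-joined sorted lexicographically, giving product
*sets* a unique serialisation. A string that fails anywhere in this
pipeline is *invalid* — that is the validity detector used by decoding
and pathway expansion.

Reactions whose sole product is carbon dioxide are dropped from
training corpora: they encode complete mineralisation, which is
over-idealised as a single reaction step.

## Tokenisation

The community-standard SMILES lexer: one token per character except
bracket atoms (`[O-]`, `[nH]`), two-letter halogens (`Cl`, `Br`) and
two-digit ring references (`%12`). Concatenating tokens reproduces the
input exactly, so detokenisation is string join. Vocabularies reserve
indices 0–3 for padding, sequence-start, sequence-end and unknown, then
order tokens by corpus frequency (ties lexicographic) — deterministic
given the corpus. Sequences longer than `max_seq_len` (276 including
the start/end symbols) are rejected with a warning, never truncated: a
truncated SMILES is a different molecule.

## Model and training

A standard post-norm encoder–decoder transformer, implemented directly
in NumPy (float64) with hand-written backward passes and Adam. Full-
scale defaults: 4 encoder and 4 decoder layers, 8 heads, embedding 256,
feed-forward 2048, dropout 0.1 on residuals and embeddings, maximum
sequence length 276.

The learning rate follows the inverse-square-root schedule with linear
warmup,

    lr(step) = d^-0.5 · min(step^-0.5, step · warmup^-1.5),

with `d` the embedding dimension and `warmup = 4000` steps at full
scale. Training is teacher-forced cross-entropy on product tokens with
padding masked out of attention and loss; early stopping halts when the
validation loss has not strictly decreased for 10 consecutive epochs,
with a hard cap of 250 epochs.

**Transfer learning.** `finetune` continues training on a new corpus
with every weight trainable and the *global step counter preserved*, so
the schedule resumes at the decayed learning rate of the final
pre-training step instead of re-warming; the batch size drops from 128
to 64 to get more updates per epoch on small corpora. Early-stopping
bookkeeping restarts for the new phase; the step counter does not.

Open details the schedule's source does not pin down were resolved as:
Adam with default moments (0.9/0.999), no label smoothing, no weight
tying between embeddings and output projection, no gradient clipping or
weight decay, Xavier-uniform linear initialisation. Initialisation,
batch shuffling and dropout all derive from a single seed, so equal
seeds give bitwise-equal models.

**Desk-scale profile.** All training-based tests and the acceptance
script use a 2-layer/64-dim/4-head variant (feed-forward 256) trained
on 2000 synthetic-grammar reactions with warmup scaled to 400 steps —
the full-scale 4000-step warmup would leave a toy run inside the warmup
ramp for its entire budget. Everything else (batch sizes 128/64,
patience 10, schedule shape, decoding) is identical to full scale.

## Decoding

Beam search from the sequence-start symbol; at each step the
`beam_width` highest-scoring sequences survive, finished sequences
competing for slots alongside unfinished ones. Width 8 is used for
single-reaction ranking and width 5 inside pathway prediction, where
every retained product is itself re-decoded.

A candidate's probability is the **raw product of per-token
probabilities — no length normalisation**: thresholding and pathway
conditional probabilities need true products, not length-corrected
scores. Accumulation is in log space and exponentiated at the
interface; reported probabilities match naive products to 1e-10. Ties
break lexicographically on token indices. Zero-probability extensions
never enter the beam, keeping all reported probabilities in (0, 1].
Decoded candidates are split on `.`, standardised per compound, and
flagged invalid (not raised) when standardisation fails.

## Evaluation

**Product-set equality** is subset-based: a prediction matches when the
actual products are a subset of the predicted set. Order-free, and
extra predicted compounds are not penalised — biodegradation datasets
routinely omit co-products.

**Top-K**: a true reaction is a hit when any of its reactant's K most
probable candidates matches. The hit fraction is reported as both
precision and recall; the metric simply has no separate notion of the
two, which is the critique it exists to illustrate (it resembles recall
far more than accuracy).

**Single generation**: candidates with probability ≥ threshold (accept
at equality) are positive predictions. Identical standardised product
sets from different beams are first deduplicated per reactant, keeping
the maximum probability — beams frequently collapse after
standardisation. Invalid candidates above threshold count in the
precision denominator (the model did positively predict them) but can
never match. Precision = matching accepted / accepted; recall = true
reactions matched / true reactions. With zero accepted candidates
precision is undefined and reported as 1.0 with a degenerate flag, so
PR curves stay defined at high thresholds. The default threshold grid
is 101 even points on [0, 1]; AUC is the trapezoid over the achieved
(recall, precision) points sorted by recall, with no extrapolation to
recall 0 or 1 (a single point degenerates to the precision × recall
rectangle, documented as such).

**Cross-validation** splits on *pathways*, not reactions: compounds
within one pathway are similar, and splitting by pathway keeps the test
set farther from the training distribution. After the (seeded) fold
assignment, any training reaction whose full reactant string appears as
a test-set reactant, or whose full product string appears as a test-set
product, is removed. The comparison is on whole dot-joined sides — the
literal reading of "appears as a reactant/product"; per-compound
filtering would be stricter than intended.

## Pathway prediction and scoring

Prediction expands breadth-first from the root: each frontier compound
is beam-decoded (width 5); every valid candidate set contributes its
compounds as children with conditional probability = parent's ×
candidate's; children below the threshold are pruned; invalid
candidates are dropped; a compound already present in the pathway is
not duplicated (the prediction stays a tree; breadth-first order means
the first occurrence is the shallowest). One global threshold applies
at every depth — conditional probabilities can only shrink along a
path, which prunes deep growth naturally. The evaluation profile runs
to depth 7 unbounded in width; the runtime profile uses depth 4 with at
most 3 children per node.

Scoring weights a compound at depth `d` by `1/2^d` and proceeds
top-down from the shared root. For a true node matched at predicted
node `p`, each true child is searched among the unclaimed descendants
of `p` breadth-first (nearest first); predicted nodes strictly between
`p` and the match are *intermediates* and score-neutral — true pathways
routinely omit short-lived intermediates, so predicting one should not
cost anything. A matched true node scores at its depth in the *true*
pathway (a product found via intermediates is scored as if it were an
immediate child). Each predicted node can satisfy at most one true node
(nearest-first claiming prevents double counting). Unmatched,
non-intermediate predicted nodes are errors weighted by their
*collapsed* depth, counting only non-intermediate ancestors — an error
below an intermediate chain hurts as if the chain were not there, and a
deeper error always hurts less than a shallower one. Recall is matched
weight over total true weight (root excluded); precision is matched
weight over matched + error weight, degenerate-1.0 for a root-only
prediction. Curves over a threshold grid average per-pathway precision
and recall with equal weight per pathway.

True pathways may be DAGs (branches can converge on one product); depth
is the shortest edge-count from the root, which keeps weights unique.

## Synthetic corpus

The generator emulates the *structure* the method assumes, not real
biotransformation chemistry: rule-governed single-reactant reactions,
several rules applicable to one reactant, dot-joined multi-product
reactions, branching pathways, and terminal mineralisation to CO2. Its
molecules are linear carbon chains (3–8 carbons) with one functional
terminus; its seven rules are anchored string rewrites — halide
hydrolysis, deamination, alcohol oxidation to the carboxylate,
β-oxidation-style chain shortening emitting acetate as a second
product, decarboxylation emitting CO2 alongside the shortened alkane,
and acetate mineralisation to CO2 as sole product (exercising the CO2
filter). Rules are deliberately plain string rewrites validated through
RDKit canonicalisation, independent of the SMIRKS machinery they help
test; every emitted compound is a fixpoint of the standardiser.

Branch probabilities are fixed so that the main channel dominates the
decarboxylation side channel 6:1. This is a property a learnability
check needs by construction: a reactant whose true products split
evenly between two channels caps top-1 accuracy at 50% for a perfect
model, so a grammar meant to verify ≥90% top-1 must make secondary
channels minor. Grammar variant "B" rewrites the halide/alcohol rules
to different products over the same token alphabet, supporting
transfer-learning experiments (pre-train on A, fine-tune on B).

**What passing these tests shows — and does not.** The grammar has a
vocabulary of ~10 token types, a few dozen distinct reactions, and
near-deterministic reactant→product mappings. Success demonstrates that
the pipeline is wired correctly end to end: standardisation is stable,
the transformer and its gradients optimise, beam decoding ranks
faithfully, transfer learning warm-starts as specified, and every
evaluation tier computes its published worked examples. It says nothing
about accuracy on real biodegradation data, whose reaction diversity,
ambiguity and missing intermediates are orders of magnitude harder; the
printed fixtures and metric algebra, not the grammar, are what carry
over.

The worked-example fixtures map the abstract compound labels A–F of the
printed examples to distinct linear alkanes so the full standardisation
and set machinery runs unchanged.

## Numerical and degenerate-input choices

- float64 throughout the network; probabilities exponentiated from log
  space only at interfaces.
- Softmax is shift-normalised; attention masks are additive −1e9.
- Empty training sets, empty corpora, fewer pathways than folds,
  non-increasing threshold grids, step 0 in the schedule, cyclic or
  root-unreachable pathway graphs: all rejected with explicit errors.
- Invalid SMILES from the decoder is data (flagged), not an exception;
  invalid *input* SMILES raises.
- Checkpoints carry parameters, train state, config, history and the
  vocabulary with a content hash; loading verifies architecture and
  hash.

## Known limitations

- The NumPy kernel is single-threaded BLAS-bound; full-scale (4+4
  layer, d=256) pre-training on ~10^6 reactions is architecturally
  supported but not practical here — the implementation targets the
  desk-scale regime.
- Pathway predictions are trees; converging predicted branches collapse
  onto the first (shallowest) occurrence of a compound.
- No tautomer enumeration or pKa modelling beyond the 17 rules; no
  environmental-context conditioning; no sampling or constrained
  decoding.
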