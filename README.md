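# degradict

Sequence-to-sequence transformer prediction of biodegradation products
and pathways from SMILES.

When a chemical is released into the environment, microbes degrade it
step by step into transformation products, some of which are more
harmful than the parent compound. Regulators increasingly require these
degradation pathways to be modelled before a chemical is approved.
Classical prediction tools encode expert transformation rules
(SMIRKS/SMARTS patterns); rules are expensive to curate and cannot be
applied to every molecule, so their *coverage* of new compounds is
limited. `degradict` takes the purely data-driven route: product
prediction is treated as translation,

    reactant SMILES  ──encoder–decoder transformer──▶  product SMILES,

which applies to any parseable molecule (100% coverage by
construction). The package is aimed at cheminformaticians working on
biodegradation and reaction prediction who need the full surrounding
workflow, not just a model:

- **Standardisation** — stereochemistry removal plus 17 SMIRKS
  protonation/CoA rewrites and canonicalisation, so byte equality of
  SMILES means molecule equality (`standardize`, `SmilesStandardizer`).
- **Model** — a NumPy encoder–decoder transformer (multi-head
  attention, post-norm, sinusoidal positions) trained with the warmup
  schedule `lr = d^-1/2 · min(step^-1/2, step · warmup^-3/2)`, early
  stopping on validation loss, and a transfer-learning protocol that
  fine-tunes *all* weights while continuing the learning-rate schedule
  from the final pre-training step (`ReactionTransformer.fit` /
  `.finetune`).
- **Decoding** — beam search returning ranked candidate product sets
  with raw sequence probabilities, `P(seq) = ∏ P(token)`
  (`beam_decode`, widths 8 for single reactions, 5 inside pathways).
- **Evaluation** — subset-based product-set equality; Top-K hit rates;
  threshold precision–recall curves with AUC
  (accepted = candidates with `p ≥ t`); pathway-level tenfold
  cross-validation with reactant/product leakage filtering.
- **Pathway engine** — recursive breadth-first pathway prediction
  pruned by root-conditional probability, and the depth-weighted
  pathway metric: a compound at depth `d` weighs `1/2^d`, predicted
  intermediates between matched compounds are score-neutral, and errors
  are discounted by their collapsed depth (`predict_pathway`,
  `multigen_scores`).
- **Synthetic corpus** — a seeded rule grammar over simple molecules
  that reproduces the *structure* of biodegradation data (multiple
  rules per reactant, multi-product reactions, branching pathways, CO2
  mineralisation) so the whole pipeline trains and evaluates in minutes
  with no downloads (`default_grammar`, `generate_pathways`).

See `docs/methods.md` for the model details and design decisions.

## Worked example

Train the desk-scale reference model (2-layer/64-dim) on 2000
synthetic-grammar reactions, then rank products and expand a pathway:

```python
import degradict as dd

dd.standardize("C[C@H](N)C(=O)O")        # 'CC(N)C(=O)[O-]'
dd.standardize("OC(=O)c1ccc(O)cc1")      # 'O=C([O-])c1ccc([O-])cc1'

grammar = dd.default_grammar()
corpus = dd.generate_pathways(grammar, n=1500, max_depth=4, seed=11)
reactions = [r.to_smiles() for r in corpus.reactions][:2000]

est = dd.ReactionTransformer(
    encoder_layers=2, decoder_layers=2, heads=4, embedding_dim=64,
    feedforward_dim=256, batch_size=128, finetune_batch_size=64,
    max_epochs=60, patience=10, warmup_steps=400,
    standardize_inputs=False, random_state=0)
est.fit(reactions)                        # ~2.5 min on one CPU core

for rank, (smiles, prob) in enumerate(est.predict(["CCCCCl"], beam_width=3)[0], 1):
    print(f"{rank}  {smiles:22s}  {prob:.3f}")

pw = dd.predict_pathway(est, "CCCCCl",
                        dd.MultiGenConfig(threshold=0.1, max_depth=3, beam_width=3))
for node in sorted(pw.nodes, key=pw.depth):
    print(f"depth {pw.depth(node)}  p={pw.conditional_probability(node):.3f}  {node}")
```

prints

```
1  CCCCO                   1.000
2  CCCO                    0.000
3  CCCC(=O)[O-]            0.000
depth 0  p=1.000  CCCCCl
depth 1  p=1.000  CCCCO
depth 2  p=0.999  CCCC(=O)[O-]
depth 3  p=0.901  CC(=O)[O-]
```

The model has learned the grammar's main degradation channel: butyl
chloride hydrolyses to butanol (probability 1.000, the two minor
candidates fall below 1e-3), butanol oxidises to butanoate, and
butanoate chain-shortens to acetate. The pathway column shows each
compound's conditional probability from the root — the product of edge
probabilities along the path, the quantity thresholded during recursive
prediction.

The same workflow is scriptable from the shell (`degradict standardize
/ generate / pretrain / finetune / predict / predict-pathway / evaluate
/ crossval`); each run logs a JSON summary with its seed and per-stage
counts to stderr.

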