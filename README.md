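# circmil

Attention-based multiple-instance learning (MIL) for telling circular RNA
(circRNA) apart from other long non-coding RNA (lncRNA) using nothing but
the raw transcript sequence — and for reading the trained attention back
onto the sequence to nominate the loci that drive the decision.

## The idea

Back-splicing leaves no single diagnostic landmark in a circRNA's
sequence: the informative loci are short, sparse, and buried in hundreds
to thousands of background nucleotides, and transcripts vary enormously
in length.  That is exactly the setting multiple-instance learning was
made for, so the classifier treats each transcript as a *bag* of
fixed-length windows:

1. **Instancing.** The transcript (≥ 200 nt) is circularized — 5′ and 3′
   ends joined, because the molecule of interest is a closed loop — and a
   window of `w` nt is slid from the 5′ end in steps of `s` nt
   (70/5 at full scale).  The number of instances is
   `k = round(L / s)` (half-up), and windows near the tail wrap through
   the junction.
2. **Instance encoder.** Each window is embedded (15-symbol alphabet
   `A,T,G,C,N` + IUPAC codes → 4 dims) and read by a two-layer
   bidirectional LSTM; the final hidden states of both directions are
   concatenated and mapped by a two-layer FCN to the instance feature
   `cᵢ ∈ ℝᴹ` (M = 100 at full scale).
3. **Attention pooling.** The bag feature is a learned convex
   combination of instance features,

       α = softmax(wᵀ tanh(V Cᵀ)),   z = Σᵢ αᵢ cᵢ,

   with `V ∈ ℝᴸˣᴹ`, `w ∈ ℝᴸ` trainable.  A sigmoid head on `z` gives
   P(circRNA).  Training uses binary cross-entropy with Adam
   (lr 2·10⁻⁴, betas (0.9, 0.999), weight decay 10⁻⁵ by default).
4. **Attention → sequence.** Each instance's attention weight is spread
   over the positions its window covers; the per-position mean is min–max
   scaled to [0, 1], and maximal runs scoring > 0.6 of length ≥ 8 become
   **high-attention splices**, exported as FASTA together with the exact
   MEME command (`-mod zoops -minw 6 -maxw 50 -objfun classic
   -markov_order 0`) for motif enrichment.
5. **Fusion head (optional).** The 100-dim weighted feature `z` can be
   concatenated with precomputed reverse-complement-matching (40) and
   conservation (23) descriptor vectors and fed to a 163-80-20-1 MLP.

Evaluation reports accuracy, sensitivity, specificity, precision, MCC,
F1 and ROC AUC.  The neural network runs on a small, fully tested
reverse-mode autodiff engine over numpy — CPU-only, deterministic under a
fixed seed.

## Worked example

Train a reduced model on synthetic transcripts whose positives carry
three mutated copies of a 15-nt motif (`TGAGGTCACGCATGG`, 10% per-base
mutation) over an i.i.d. background — negatives are pure background with
the same length distribution:

```python
from circmil import CircMIL, ModelConfig, TrainConfig, WindowGeometry
from circmil.synthetic import SeqSimConfig, simulate_sequences

sim = dict(motifs=(("TGAGGTCACGCATGG", 0.10),), motifs_per_positive=3)
train_recs, _ = simulate_sequences(SeqSimConfig(n_pos=500, n_neg=500, seed=1, **sim))
val_recs, _ = simulate_sequences(SeqSimConfig(n_pos=50, n_neg=50, seed=901, **sim))

model = CircMIL(train_recs, val_recs,
                geometry=WindowGeometry(window=20, step=10),
                model_config=ModelConfig(rnn_hidden=32, fcn_hidden=64,
                                         feature_dim=32, attention_hidden=16),
                train_config=TrainConfig(lr=3e-3, epochs=15, batch_bags=16))
results = model.fit()
print(results.summary())
```

```
Attention-MIL bag classifier
============================================================
window/step:        20/10 nt
instance feature M: 32
attention width L:  16
parameters:         42140
epochs run:         15
selected epoch:     15
final train loss:   0.0556
final train acc:    0.9830
final val acc:      0.9700
final val AUC:      0.9884
```

The model separates the classes (validation AUC 0.99), and the attention
map points straight at the planted motif:

```python
rec = val_recs[0]
print(results.predict_proba([rec])[0])   # 1.0
for sp in results.splices(rec):
    print(sp.start, sp.end, round(sp.mean_scaled_score, 3), sp.subsequence)
```

```
60 80 0.878 CTTTGAGGTCACGAAGGGCC
160 180 0.882 AAGGTCACGCATGGTCCTTA
270 290 0.940 TGAGTGAGGTCACGGTAGGA
```

All three extracted splices contain a planted `TGAGGTCACG…` copy — the
per-base attention recovered the ground-truth loci without ever seeing
position labels.  (Runtime: about three minutes on one CPU core.)

The same pipeline is available from the shell:

```bash
circmil simulate --preset quick --seed 3 --out sim/
circmil prepare --positives sim/positives.fasta --negatives sim/negatives.fasta \
        --window 20 --step 10 --seed 1 --out prep/
circmil train --data prep/ --window 20 --step 10 --hidden 32 \
        --feature-dim 32 --attention 16 --epochs 15 --lr 3e-3 --out model/
circmil evaluate --model model/ --positives prep/test_pos.fasta \
        --negatives prep/test_neg.fasta --window 20 --step 10 --out eval/
circmil attend --model model/ --fasta prep/test_pos.fasta \
        --window 20 --step 10 --out attend/   # profiles, splices, MEME export
```

Every subcommand writes a `manifest.json` (command, parameters, seed,
version) so any stage can be re-run bit-identically.

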