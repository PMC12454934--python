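# targetpep

Residue-level detection and classification of eukaryotic protein
**targeting peptides** — the short sorting signals that direct a protein to
its subcellular destination. The toolkit covers eight signal classes:

| class | signal | placement |
|-------|--------|-----------|
| ER  | ER retention signal (KDEL-like tetrapeptide) | C-terminal, 4 residues |
| PTS | peroxisomal targeting signal (PTS1) | C-terminal tripeptide |
| MT  | mitochondrial transit peptide | N-terminal |
| SP  | secretory signal peptide | N-terminal |
| CH  | chloroplast transit peptide | N-terminal |
| TH  | thylakoid transit peptide | immediately after CH |
| NLS | nuclear localization signal | internal, 1–3 segments |
| NES | nuclear export signal | internal |

## Who this is for

Researchers who want a self-contained, fully testable implementation of a
per-residue sorting-signal detector: sequence encoding by overlapping
fixed-length fragments with overlap-mean reassembly, eight task-specific
heads over a shared encoder, dual residue/protein losses with per-head
early stopping, threshold-free max-pooling inference, homology-aware
cross-validation partitioning, binomial-mutation augmentation, and the
standard evaluation suite (MCC, F1, exact cleavage-site accuracy, SOV).
Everything runs on one CPU; a built-in generator plants synthetic signals
so no external data is needed.

## The model in brief

A protein of length $L$ is split into fragments of 1022 residues with a
200-residue overlap; each fragment is encoded independently (BEGIN/END/pad
tokens stripped) and overlapping positions are averaged, giving an
$L \times D$ embedding. Eight heads map this to an $8 \times L$ matrix
$S$ of per-residue signal strengths in $[0,1]$ — CNN heads for the
variable-position NLS/NES, position-wise MLPs for the terminus-anchored
classes. Training minimises

* a residue-level weighted categorical cross-entropy over 9 categories,
  with the OTHER row defined as $1-\max_c S_{c\ell}$ per position, and
* a protein-level weighted binary cross-entropy on the horizontal maxima
  $\hat s_c = \max_\ell S_{c\ell}$ (multi-label, so CH+TH can coexist).

Inference takes the vertical maximum per position and calls class $c$ iff
$S_{c\ell} > 1 - S_{c\ell}$, i.e. the winner must beat its own OTHER
complement — no tunable threshold. Parameter-efficient fine-tuning of the
encoder is supported as last-K layers, LoRA ($h = W_0x + BAx$, rank
$r \ll \min(d,k)$), or bottleneck adapters.

Evaluation uses the Matthews correlation coefficient

$$MCC = \frac{TP\cdot TN - FP\cdot FN}{\sqrt{(TP{+}FP)(TP{+}FN)(TN{+}FP)(TN{+}FN)}},$$

the F1 score, exact cleavage-site accuracy for terminus-anchored classes,
and the segment-overlap measure

$$SOV = \frac{\sum_i \min(OV(i),\ \alpha_i\,union(i))}{\sum_i |S_{obs,i}|},
\qquad \alpha_i = 1 - \frac{\big||S_{obs,i}|-|S_{pred,i}|\big|}{union(i)}$$

for the segment classes NLS/NES. See `docs/methods.md` for the full
account.

## Worked example

```bash
# 1. generate a synthetic dataset (planted signals, seeded)
targetpep simulate --out data/ --seed 7 --n-per-class 8
# [simulate] seed=7 proteins=80 annotations=80 out=data seconds=0.0

# 2. identity-controlled 5-fold partition (<30% cross-fold identity)
targetpep partition --fasta data/proteins.fasta --out data/folds.tsv \
    --annotations data/annotations.tsv --k 5 --seed 1
# [partition] seed=1 proteins=80 k=5 threshold=0.3 violations=0 \
#             out=data/folds.tsv seconds=2.3

# 3. train a small detector (desk scale)
targetpep train --fasta data/proteins.fasta \
    --annotations data/annotations.tsv --folds data/folds.tsv \
    --out-dir run/ --epochs 10 --patience 3 \
    --fragment-length 192 --overlap 48 --seed 0

# 4. predict and evaluate on the same FASTA
targetpep predict --model run/checkpoint.npz \
    --fasta data/proteins.fasta --out-segments run/segments.tsv
targetpep evaluate --truth data/annotations.tsv \
    --predictions run/segments.tsv --fasta data/proteins.fasta
```

The evaluate step prints a per-class table; on a trained model the
interesting columns are `mcc`/`f1` (protein-level multi-label calls),
`cleavage_accuracy` (exact free-end position for ER/PTS/MT/SP/CH/TH; the
denominator is the number of *predicted* proteins of the class) and `sov`
(segment overlap for NLS/NES). `Average` and `Weighted average` rows
aggregate across classes unweighted and by truth counts.

In Python the same pipeline is three calls:

```python
from targetpep import (SyntheticConfig, generate_dataset,
                       cluster_and_partition, SignalModel, ModelConfig,
                       TrainingConfig, train, predict_dataset)

records, annotations = generate_dataset(SyntheticConfig(seed=7))
folds = cluster_and_partition(records, annotations=annotations, rng=1)
model, history = train(SignalModel(ModelConfig(fragment_length=192,
                                               overlap=48)),
                       records, annotations, folds.folds, TrainingConfig())
matrices, segments = predict_dataset(model, records)
```

A `contacts` subcommand computes inter-chain residue contacts (< 5 Å,
any-atom) from a PDB complex, and `export-segments` writes detected
segments as FASTA for external motif tools.

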