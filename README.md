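# pairiface

Sequence-based prediction of inter-protein interface residue pairs for
eukaryotic heterodimers. The pipeline combines:

1. **Co-evolution** (`pairiface.coevolution`) — a perturbation-based
   conditional-mutual-information statistic between columns of two
   species-matched, concatenated multiple sequence alignments
   (`pairiface.msa`). The default "weighted" mode is exactly equal to the
   mutual information of the smoothed joint column table, which gives it a
   closed-form oracle.
2. **Pairwise features** (`pairiface.features`) — nine M×N matrices
   (co-evolution, charge/hydropathy/size compatibility, RSA product,
   secondary-structure pair rank, three contact-potential variants), each
   min–max scaled to [0, 1].
3. **Environment features** (`pairiface.environment`) — the nine base
   matrices convolved with a ring-decay kernel (3×3–7×7, 10–25 % decay),
   giving 18 features per residue pair.
4. **Random-forest classification** (`pairiface.classifier`) — 5:1
   negative down-sampling, F1-scored hyperparameter grid search on a
   stratified 75:25 split, leave-one-complex-out evaluation, feature
   importances.
5. **Network post-filter** (`pairiface.netfilter`) — removes buried
   residues (RSA = 0) and residues in strong intra-protein co-evolution
   networks, keeps clustered predictions via unitary window-sum scoring
   (cutoff 2 for 3×3, 6 for 5×5), and maps 3-residue interaction
   stretches.

Training labels come from complex structures (`pairiface.labeling`): seed
pairs at < 5 Å heavy-atom distance, expanded ±2 residues under a 10 Å
Cβ-distance cap. `pairiface.synthetic` generates complete synthetic
fixtures (toy complexes, annotations, alignments with planted
covariation) so everything runs without external data.

## CLI

Each stage is a subcommand; outputs include the effective config and a
file manifest. A full run on a synthetic fixture:

```sh
pairiface simulate --out fix --m 30 --n 25 --n-interface 4 --seed 1
pairiface features --aln-a fix/proteinA.fasta --aln-b fix/proteinB.fasta \
    --ann-a fix/proteinA_annotations.tsv --ann-b fix/proteinB_annotations.tsv \
    --out feats --kernel-size 5 --decay 0.10
pairiface label --pdb fix/complex.pdb --chain-a A --chain-b B --out labels
pairiface train --complex c1:feats/stack.tsv:labels/labels.tsv --out model --fast-grid
pairiface predict --model model/model.joblib --stack feats/stack.tsv --out pred
pairiface filter --predictions pred/predictions.tsv --probabilities pred/probabilities.tsv \
    --aln-a fix/proteinA.fasta --aln-b fix/proteinB.fasta \
    --ann-a fix/proteinA_annotations.tsv --ann-b fix/proteinB_annotations.tsv \
    --out filt --kernel-size 3
pairiface evaluate --predictions pred/predictions.tsv --labels labels/labels.tsv --out eval
```

Annotation TSVs have columns `index` (1-based), `aa`, `rsa` (0–1), `ssp`
(H/E/C) and can come from any predictor or from structures. The bundled
20×20 property tables are documented surrogates derived from standard
scalar scales; curated tables can be substituted as TSVs
(`pairiface.features.read_property_table`).

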