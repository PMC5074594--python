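# mirnafeat

Numerical-feature analysis of pre-miRNA hairpins, for the question: *do
animal and plant miRNA precursors differ numerically, and can a small
feature subset tell them apart?*

Animal and plant pre-miRNAs fold into the same kind of stem–loop, but
their precursors differ systematically in length, secondary-structure
composition and folding energy. `mirnafeat` computes a 132-value
numerical descriptor of any hairpin (sequence, structure, energy and
entropy features), screens every feature between two labelled cohorts
with the two-sample Kolmogorov–Smirnov test and a Welch t-test, selects
a compact subset by correlation-based feature selection (CFS), and
classifies hairpins with a logistic model — including the published
fixed-coefficient animal/plant model

```
Logit(P) = 6.1436 + 0.0893·x1 − 0.0691·x2 − 0.0241·x3 + 0.0263·x4
```

where *P* is the probability that a hairpin is an animal pre-miRNA, *x1*
the helix number, *x2* the stack number, *x3* the precursor length (nt)
and *x4* the minimum free energy (kcal/mol).

It is aimed at researchers doing comparative miRNA genomics who have
hairpin sequences (e.g. from a miRBase-style registry) plus secondary
structures from any MFE folder, and at anyone who wants a reproducible
re-implementation of this feature pipeline to probe or extend.

## The 132 features

| class | n | content |
|-------|---|---------|
| A | 4 | mononucleotide frequencies |
| B | 16 | overlapping dinucleotide frequencies |
| C | 64 | overlapping trinucleotide frequencies |
| D | 32 | triplet matching-state frequencies (base × paired/unpaired marks of left neighbour, self, right neighbour, e.g. `G++.`) |
| E | 5 | bulge-loop, helix, interior-loop, stack counts; length |
| F | 3 | MFE; AMFE = 100·MFE/L; MFEI = AMFE/(100·GC) |
| G | 4 | GC fraction, (G+C)/(A+U), A/C, G/U |
| H | 4 | Shannon entropies (bits) of classes A–D: IESN, IEDN, IETN, IESS |

Structures come in as dot-bracket strings (Vienna text), Mfold CT files,
or from a pluggable folding adapter (`RNAfold` supported); no folding
engine is ever required when structures are precomputed. A synthetic
generator emits labelled animal-like/plant-like cohorts so the whole
pipeline runs with no downloads.

## Worked example

```python
import mirnafeat as mf
from mirnafeat.classify import PUBLISHED_FEATURES, cross_validate, published_model

records = mf.generate_cohorts(seed=1)          # 500 animal-like + 500 plant-like
table = mf.extract_table(records)              # 1000 x 132 feature table

scr = mf.screen_features(table)                # KS + t-test per feature
print(scr.sort_values("ks_d", ascending=False)
         .head(3)[["feature", "ks_d", "direction"]].to_string(index=False))
# feature  ks_d direction
#  length  0.70     plant
# n_stack  0.66     plant
#     MFE  0.66    animal

rep = cross_validate(table, list(PUBLISHED_FEATURES), k=10, seed=1)
print(f"tp_rate={rep.tp_rate:.3f} precision={rep.precision:.3f} roc_area={rep.roc_area:.3f}")
# tp_rate=0.842 precision=0.858 roc_area=0.844

m = published_model()
fv = {"n_helix": 3, "n_stack": 20, "length": 85, "MFE": -35}
print(f"P(animal)={m.predict_proba(fv):.3f}  call={m.predict_label(fv)}")
# P(animal)=0.887  call=animal
```

The screening shows the three axes on which the cohorts separate most —
precursor length and stack number run higher in the plant-like class,
MFE higher (less negative) in the animal-like class — and a 10-fold
cross-validated logistic model on the four published features reaches a
ROC area of 0.84 on these synthetic cohorts. The last lines score one
hairpin with the published model: a short 85-nt precursor with 20 stacks
is called animal with probability 0.887.

The same pipeline is available from the shell:

```
mirnafeat simulate --n-animal 500 --n-plant 500 --seed 1 --out-dir data/
mirnafeat pipeline --structures data/hairpins.vienna --labels data/labels.tsv \
    --seed 1 --out-dir run/
cat run/summary.txt
```

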