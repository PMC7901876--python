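# cdta — test assembly for cognitive diagnosis by maximin inter-class distance

Cognitive diagnostic assessment classifies each examinee into one of
T = 2^K latent classes — the binary patterns of K skills ("attributes") —
from their responses to items calibrated under a cognitive diagnostic
model (DINA, DINO or R-RUM). How accurately examinees can be classified
depends on how well the administered test separates the latent classes.
`cdta` assembles fixed-length tests from a calibrated item bank so that
the *minimum* Kullback–Leibler separation between any two latent classes
is as large as possible.

Each item j separates classes u, v by the KL divergence between its
Bernoulli response distributions, D(u,v,j). Stacking all ordered class
pairs gives a pair-by-item matrix V, and test assembly becomes a mixed 0–1
linear program over the selection vector x and a slack scalar y:

    min  f1·x + f2·y   s.t.   V x + y ≥ b,   Σ x_j = J,   x ∈ {0,1}^M

with f1_j = −mean(V[:,j]), f2 = J·mean(V), b_t = J·mean(V[t,:]). Minimizing
f2·y maximizes the smallest inter-class distance of the test while f1·x
rewards the mean; the program is solved with HiGHS branch-and-bound. A
*simplified* distance matrix keeps only the T·K nearest-neighbour
(Hamming-distance-1) class pairs — the hardest to separate — shrinking the
program 32-fold at K = 8 with no measurable accuracy loss. CDI-greedy
(selection by the inverse-Hamming-weighted mean of an item's pairwise KL
distances) and uniform random assembly are included as baselines, and a
Monte-Carlo harness measures the attribute- (ACR) and pattern-level (PCR)
classification accuracy each method delivers. Item-count (IC) and
attribute-coverage (AC) blueprint constraints are supported in all three
assemblers.

The package is for psychometricians and methodologists building or
evaluating diagnostic tests from calibrated banks, and for simulation
studies of test-assembly strategies.

## Worked example

```sh
python examples/assemble_test.py
```

```
bank: 60 DINA items, 3 attributes -> 8 latent classes, 24 simplified class pairs
maximin    items=[7, 8, 9, 17, 23, 25, 26, 28, 38, 54] min pair distance=2.024  mean=4.533
cdi-greedy items=[3, 7, 8, 10, 17, 23, 25, 28, 36, 38] min pair distance=0.989  mean=5.238
random     items=[8, 14, 18, 38, 39, 42, 44, 56, 58, 60] min pair distance=0.369  mean=2.637
```

Each row is a 10-item test; `min pair distance` is the summed KL
separation of the two latent classes that test distinguishes *worst*.
CDI-greedy accumulates more total information (`mean`) but leaves one
class pair nearly twice as confusable as the maximin test does; random
selection is far worse on both. That minimum is what drives whole-pattern
classification accuracy:

```sh
python examples/classification_accuracy.py
```

```
mean accuracy over 10 paired replications:
method constraint    acr    pcr
   mmd         NC 0.9492 0.8678
   cdi         NC 0.9309 0.8142
random         NC 0.8447 0.6282

maximin beats cdi-greedy on PCR in 80% of replications
```

`acr` is the proportion of correctly recovered attribute entries, `pcr`
the proportion of examinees whose full pattern is exactly recovered.
`examples/distance_matrices.py` and `examples/simplification_check.py`
walk through the distance construction and the full-vs-simplified ANOVA
comparison.

A thin CLI wraps the same functions for shell pipelines:

```sh
cdta bank -M 300 -K 4 --model dina --seed 1 --out bank/
cdta assemble --qmatrix bank/qmatrix.csv --params bank/parameters.csv \
     --model dina --method mmd --length 20 --out selection.json
cdta experiment --config config.json --out results/
```

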