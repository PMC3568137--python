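# cisevol

Maximum-likelihood detection of **correlated evolution between positions
within transcription-factor binding sites**, from gapless 5-species
(human, chimp, mouse, rat, dog) alignments of binding-site instances.

The positional weight matrix (PWM) model of TF binding assumes the
positions of a binding site are independent. If two positions actually
interact — structurally, or through context-dependent mutation — their
*substitution histories* should track each other across the many genomic
instances of the motif. `cisevol` quantifies this with a likelihood-ratio
statistic over ancestral reconstructions and calibrates it against
permutation controls.

## The statistic

For PWM *M* with *N* binding-site instances and position *i*, each instance
*k* contributes an alignment column with tree likelihood
Pr(*T<sup>k</sup>* | *A<sup>s</sup>*) under each of the 4⁴ = 256 complete
ancestral assignments *A<sup>s</sup>* (one base per internal node of the
rooted 5-taxon tree, HKY85 substitution model). Assignments are weighted by
how well they explain all instances:

    W(A_s) = Σ_k Pr(T_k | A_s)          Pr(A_s) = W(A_s) / Σ_p W(A_p)

and Pr(*T<sup>k</sup>*) = Σ<sub>s</sub> Pr(*A<sup>s</sup>*) Pr(*T<sup>k</sup>* | *A<sup>s</sup>*).
For a position pair (*i*, *j*) the same construction runs over 256×256
assignment pairs, and the co-evolution score is the summed log-likelihood
ratio of joint versus independent models (natural log):

    CoEvol(i,j) = Σ_k [ log Pr(T_i^k, T_j^k) − log Pr(T_i^k) − log Pr(T_j^k) ]

Significance comes from the **Shuffle** control (re-pairing the *N*
instances of the two positions; 100 replicates → empirical p, then
Storey–Tibshirani q-values at FDR 0.05), with **Random** (scattered
alignment columns) and **RandomContext** (contiguous promoter slices,
matched by tree-likelihood bins) controls for baseline and
context-dependent mutation. Detected co-evolution is further decomposed
into per-branch nucleotide quadruples (*u*,*v*,*x*,*y*) — *u*→*v* at one
position co-occurring with *x*→*y* at the other — with enrichment and
reciprocal-rank analyses, and dependency maps are compared across PWMs with
a Jaccard-like index.

## Worked example

```bash
python examples/01_coevol_basics.py
```

simulates 120 sites of length 6 on the default mammalian tree with a hard
preferred-pair constraint (A/A or G/G) between positions 1 and 3 and prints

```
pair   scope   CoEvol
(0,1)   1          5.40
(0,2)   2         11.15
...
(1,3)   2         68.65  <-- coupled
...
(4,5)   1          2.04
```

The coupled pair's score (68.65) stands far above the uncoupled pairs,
which fluctuate around the statistic's (positive) finite-sample baseline —
which is why calling significance goes through the Shuffle control, not
through the raw value. `examples/02_significance_and_controls.py` shows
that step: the programmed pair gets empirical p `<0.01` and q = 0 while
every other pair is far from the FDR threshold.
`examples/03_quadruples.py` recovers a programmed A↔G co-substitution as
the top-ranked quadruples AGAG/GAGA, `examples/04_scan_and_extract.py`
demonstrates PWM scanning with exact DP p-values, and
`examples/05_full_pipeline.py` is a three-motif end-to-end run producing
TSV reports and text dependency maps.

A thin CLI mirrors these steps (`cisevol simulate | scan | extract-sites |
fit-phylo | coevol | controls | run-all`); run `cisevol --help`.

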