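# scle — single-cell landscape entropy for critical-transition detection

`scle` detects the **critical (pre-transition) stage** along a staged
single-cell expression series and extracts the **dynamic network biomarker
(DNB)** gene module that announces it.  It is aimed at analysts who already
have (i) a gene × cell expression matrix, (ii) an ordered partition of the
cells into stages (pseudotime clusters, disease grades, time points) and
(iii) a protein–protein interaction network, and who want a quantitative
early-warning signal for an abrupt state change — for example, epithelial
cells tipping from a benign into a deteriorated state along a
tumorigenesis trajectory.

## The statistic

Dynamic network biomarker theory says that just before a critical
transition a small, connected group of genes shows three signatures: its
standard deviation rises sharply (SD_in ↑), its internal correlation rises
sharply (PCC_in ↑), and its correlation with all other genes falls
(PCC_out ↓).  `scle` quantifies this with a single-cell landscape entropy
score.  For gene *g* with first-order PPI neighbors *g*₁…*g*_Q and the
cells of stage *t*:

    H_t(g) = [ −1/ln Q · Σᵢ pᵢ ln pᵢ ] · SD(g at t),
    pᵢ     = |PCC(g, gᵢ)| / Σⱼ |PCC(g, gⱼ)|

i.e. the normalized Shannon entropy of the gene's neighbor-correlation
weights times its expression standard deviation, both computed within the
stage on ln(1+x)-normalized values.  The stage score

    H_t = Σ (top R local scores at stage t),  R = ⌈0.05 · M⌉

sums the strongest 5 % of the M network genes.  A sharp peak of H_t marks
the critical stage; its top-R contributors are the DNB module; the
module's first-order neighbors are then scanned for post-critical trend
reversal ("flip-flop") with a two-slope statistic.  An optional
stage-label permutation test attaches a p-value to the peak.

## Worked example

A bundled simulator generates staged expression over a generated network
with a planted transition: by default 200 genes × 6 stages × 60 cells, a
20-gene connected module whose SD triples and whose internal correlation
jumps to 0.8 at stage 4.

```bash
python examples/01_simulate_and_detect.py
```

```
stage   H_t
S1     5.395
S2     5.364
S3     5.537
S4    14.015  <- critical
S5     5.449
S6     5.569

critical stage: S4 (planted: S4)
fold change over previous stage: 2.53
permutation p-value (B=99): 0.01
```

H_t is flat (~5.4) away from the transition and jumps 2.5-fold exactly at
the planted stage; p = 0.01 means none of 99 label permutations matched
the observed peak.  `examples/02_dnb_module.py` recovers the planted
module with recall 1.00 and prints its per-stage signature (SD_in
0.49 → 1.62, PCC_in 0.11 → 0.83 at S4, PCC_out lowest at S4);
`examples/03_neighbor_reversal.py` ranks the planted rise-then-fall
neighbor gene first among 157 DNB neighbors.

The same pipeline runs from the shell on TSV/MatrixMarket inputs:

```bash
scle simulate --outdir sim --seed 7
scle run --expression sim/expression.tsv --labels sim/labels.tsv \
         --network sim/network.tsv --stage-order S1,S2,S3,S4,S5,S6 \
         --outdir out --permutations 99
```

which writes stage and local score tables, the DNB gene and neighbor
lists, the three-property statistics, the reversal table, and a JSON
manifest from which the run can be reproduced bit-identically
(`scle.run_from_manifest`).

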