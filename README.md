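# loopfit

Loop calling for HiChIP/PLAC-seq style contact maps. `loopfit` estimates the
statistical significance of intra-chromosomal bin-pair contact counts against
an empirical background that jointly models distance decay and per-bin
coverage bias, and ships the surrounding toolkit: a bystander-loop merging
filter, a coverage-driven matrix simulator, loop-set evaluation
(overlap / recovery / aggregate peak analysis), and differential-contact
utilities.

## Method overview

1. **Binning & annotation** (`loopfit.io_contacts`) — valid-pairs or sparse
   contact text is binned at a fixed resolution (default 5 kb) within a
   closed genomic distance window (default 20 kb – 2 Mb); bins overlapping a
   reference peak set (BED) are flagged; pairs are classed PP / PN / NN.
2. **Bias** (`loopfit.bias`) — per-bin bias either as the coverage ratio to
   the mean of non-zero same-peak-status bins, or via ICE matrix balancing.
3. **Background** (`loopfit.background`) — all possible pairs of the chosen
   class (stringent `S` = peak-to-peak, loose `L` = peak-to-all) are split
   into ≤ M (default 200) equal-occupancy distance strata; a monotone
   non-increasing spline models prior contact probability vs distance, or,
   with bias correction, a per-stratum OLS of log counts on log anchor
   biases is smoothed across distance with splines.
4. **Significance** (`loopfit.significance`) — each foreground pair with at
   least one contact and positive biases is tested with a binomial tail
   (trials = total background contacts, success probability = expected
   count / total expected); Benjamini–Hochberg q-values are computed once
   genome-wide and pairs with q ≤ FDR (default 0.01) are reported.
5. **Merging filter** (`loopfit.merge_filter`) — adjacent significant loops
   (8-connectivity) form components; within each component a greedy pass
   admits loops farther than B bins (Chebyshev, default B = 2) from every
   stronger admitted loop; a MIN variant keeps only the best loop.
6. **Simulation** (`loopfit.simulate`) — alternating row/column proportional
   scaling of a symmetric matrix toward a target coverage vector (with
   shuffled-coverage nulls), plus fully synthetic fixtures with implanted
   loops and known ground truth.
7. **Evaluation** (`loopfit.evaluate`) — 5 kb slack loop overlap, recovery
   curves, APA matrices and scores (center vs 15–30 kb block, center vs
   rest, corner scores).
8. **Differential** (`loopfit.differential`) — exact count tests on the
   union of non-zero pairs across replicated conditions, FDR 5% + |FC| > 2
   gates, HD/ND/LD anchor classification, five pair categories, and
   loop-supported filtering with exclusivity labels.

## CLI

```sh
# generate a synthetic fixture with 20 implanted 8x loops
loopfit fixture --n-bins 400 --seed 1 --out fx/

# call loops on it (peak-to-all foreground, loose background, coverage bias)
loopfit call --matrix fx/contacts.txt --peaks fx/peaks.bed \
    --chromsizes fx/chrom.sizes --coverage fx/coverage.bedgraph \
    --fg p2a --bg L --bias coverage --fdr 0.01 --out calls/

# bystander filtering of any BEDPE-with-score file
loopfit merge calls/loops.bedpe --rank q --window 2 --out merged.bedpe

# coverage-driven simulation (add --shuffle for the permuted null)
loopfit simulate --matrix hic.tsv --coverage chip.txt --seed 7

# evaluation
loopfit recovery --calls merged.bedpe --reference ref.bedpe
loopfit apa --loops merged.bedpe --matrix normalized.tsv

# differential contacts between replicated conditions
loopfit diff --counts pairs.tsv --cond-a a0,a1 --cond-b b0,b1,b2
```

Every run writes a `manifest.json` with the configuration, seed and
package version for reproducibility.

## Layout

```
src/loopfit/        io_contacts, bias, background, significance,
                    merge_filter, simulate, evaluate, differential, cli
tests/              unit + property tests and test_acceptance.py
scripts/acceptance.py
```
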