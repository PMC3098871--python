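# promchip

Model-based analysis of transcription-factor occupancy on promoter tiling
microarrays, with the downstream steps needed to turn binding events into
a target-gene story: motif scanning at empirically calibrated cutoffs,
time-course expression normalization and permutation testing, and
ChIP × expression integration with gene-set enrichment. A first-class
synthetic-data module generates every input with a machine-readable truth
table, so the whole pipeline can be exercised end-to-end against known
ground truth.

The package is written for regulatory-genomics analysts working with
ChIP-on-chip promoter arrays (e.g. SMAD3 occupancy in TGFβ1-stimulated
epithelial cells, hybridised against a mock-IP channel) combined with
one-colour expression time courses under a pathway inhibitor such as
SIS3.

## The model

Sheared chromatin fragments (200–700 bp) spread the signal of a single
binding event across neighbouring probes. With fragment-length mass
m(L), the expected relative coverage at distance d from the bound site is

    s(d) = Σ_L m(L) · max(0, 1 − |d|/L),

a symmetric tent with s(0) = 1. A promoter's IP/mock probe ratios r_i at
offsets x_i are fitted with the single-event model

    r_i = b + (f − 1) · b · s(x_i − c)

over a 25 bp grid of candidate centres c, giving the binding position,
the fold enrichment f over the background ratio b, and a
log-likelihood-ratio statistic with an empirical p-value from a
resampling null. A gene is called bound when p < 0.01 in at least two of
three replicates and the consensus (median) height exceeds 1.5; the
±100 bp around the consensus centre is extracted and scanned for motif
matrix hits above a type-I cutoff calibrated by scoring 10 000 random
background sequences at alpha = 0.05. Expression arrays are cyclic-loess
normalized, probe-averaged, referenced to the 0 h geometric mean, and
tested between timepoints with an exact permutation test; binding and
expression meet in an integrated per-gene table and one-tailed
hypergeometric (Fisher's exact) gene-set enrichment.

## Worked example

`examples/01_peak_calling.py` simulates 200 promoters with fold-3 binding
events planted in 10% of them and calls peaks:

```
planted events : 20
called bound   : 20
true positives : 20  (sensitivity 1.00)
  G00011: centre   -1652 bp (true -1653), height 3.07 (true 3.0)
  G00022: centre      +7 bp (true    -4), height 2.96 (true 3.0)
  G00031: centre    +201 bp (true  +204), height 2.75 (true 3.0)
```

Each line is one called gene: the fitted binding-site position relative
to the transcription start site (against the planted truth), and the
fitted fold enrichment over the background ratio (planted fold 3). All
20 planted events are recovered with no false calls.

The other examples cover motif scanning (`02`), expression normalization
and differential testing (`03`), integration and enrichment (`04`), and
the full benchmark (`05`). The same benchmark is available from the
shell:

```bash
promchip run-all --seed 1 --outdir out/
promchip simulate --n-genes 200 --outdir sim/
promchip callpeaks --layout sim/layout.tsv --tables sim/chip_stimulated_rep*.tsv \
    --permutations 199 --seed 1 --out peaks.tsv
```

Subcommands `scanmotifs`, `normalize`, `detest`, `integrate` and `enrich`
expose the remaining stages; a YAML config can replace flags.

## Layout

```
src/promchip/
  peaks.py        fragment-length shape model, peak fitting, empirical p-values
  chip.py         replicate filters, condition comparison, bound regions
  motifs.py       PWM scoring, cutoff calibration, strand-aware scanning
  expression.py   cyclic loess, probe summarisation, permutation tests, ddCt
  integration.py  integrated table, top-k ranking, gene-set enrichment
  synthetic.py    generators with truth tables for every input
  validation.py   ground-truth experiments used by tests and acceptance
  io.py           TSV/FASTA/GMT/TRANSFAC/UniPROBE readers and writers
  cli.py          thin click interface incl. the run-all benchmark
```
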