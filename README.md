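# gisaq

**Gradient internal-standard absolute quantification for amplicon sequencing.**

Amplicon sequencing reports *relative* abundances: a taxon's share of reads can
rise while its actual population collapses. `gisaq` implements a spike-in
workflow that converts read counts into **absolute abundances (copies per
gram)**: a set of synthetic internal standards is added to each sample at a
10× concentration gradient (10⁴–10⁸ copies g⁻¹ by default) *before* DNA
extraction, their reads are recognised after sequencing, and each sample gets
its own log–log standard curve

```
log₁₀(reads) = a·c · log₁₀(copies g⁻¹) + b·d
```

which is inverted to quantify every community member. The coefficients *c*
and *d* calibrate the spike-in curve against microbial genomes: plasmid
standards and real genomes extract with similar efficiency slopes but
systematically different intercepts, so *d* is the ratio of mean qPCR
intercepts (microbes / spike-ins) and *c* is 1 unless a one-way ANOVA finds
the slopes to differ.

The package is aimed at microbial-ecology researchers who run 16S rRNA
(V3–V4) and/or ITS2 amplicon surveys and need absolute dynamics across time
series or treatments — fermentations, soils, guts — without re-sequencing the
same sample at several spike-in levels.

## What is in the box

| module | purpose |
|---|---|
| `gisaq.standards` | design/validate 472-bp internal standards: universal primer anchors (336F/806R, ITS3/ITS4) around GC-matched random stuffers with homopolymer/repeat/self-complement guards, plus specific recognition primers |
| `gisaq.spikein` | detect spike-in reads (Hamming-bounded, strand-aware) and split feature tables into spike-in and community parts |
| `gisaq.calibrate` | qPCR standard curves, slope/intercept ANOVA, calibration coefficients (c, d), plasmid copy-number arithmetic, recovery rates |
| `gisaq.quantify` | per-sample gradient curves, absolute/relative abundance tables with below-detection and extrapolation flags, detection limits, single-spike-in perturbation mode |
| `gisaq.simdata` | staggered mock communities, noisy qPCR dilution series and error-bearing reads, reproducible from one seed |
| `gisaq.io` / `gisaq.cli` | FASTA/FASTQ/TSV/YAML round trips and the `gisaq` command line |

Five ready-made 472-bp internal standards (IS1–IS5, GC 45.4–46.9%) ship as
package data and load with `gisaq.load_reference_standards()`.

## Worked example

Simulate a staggered mock community with spike-ins, fit the gradient curve
and quantify:

```python
import warnings
from gisaq import (SimulationConfig, simulate_mock_community, GradientDesign,
                   fit_gradient_curve, absolute_abundance, detection_limit)
from gisaq.simdata import DEFAULT_GRADIENT

cfg = SimulationConfig(seed=11)           # sigma = 0.1 log10 read noise
truth, community, std_counts = simulate_mock_community(cfg)
print(std_counts["mockA"])                # spike-in reads along the gradient
design = GradientDesign(concentrations=dict(DEFAULT_GRADIENT))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")       # IS5 (1e4 copies/g) drew 0 reads
    curves = {s: fit_gradient_curve(std_counts[s].to_dict(), design, sample=s)
              for s in community.columns}
result = absolute_abundance(community, curves)
```

Output (seed 11):

```
IS1    3975        # spiked at 1e8 copies/g
IS2     315        #           1e7
IS3      33        #           1e6
IS4       4        #           1e5
IS5       0        #           1e4 — below detection, excluded from the fit

curve mockA: a=0.997  b=-4.427  r=0.9991  p=8.7e-04  n=4

taxon                 reads   estimate   truth    flag
B_amyloliquefaciens    3056   8.6e+07    1e+08    ok
L_fusiformis            353   9.9e+06    1e+07    ok
N_castellii             439   1.2e+07    1e+07    ok
H_osmophila              40   1.1e+06    1e+06    ok
```

The fitted slope is near 1 and Pearson *r* ≈ 0.999, so read counts track the
spiked copy numbers log-linearly; inverting the curve recovers each organism's
true concentration well within the read-noise envelope.
`detection_limit(curves["mockA"])` reports 2.8 × 10⁴ copies g⁻¹ — one read on
this sample's curve — inside the expected 10⁴–10⁵ working floor.

The same steps are available from the shell:

```sh
gisaq simulate --scenario mock --seed 11 --outdir sim/
gisaq detect sim/standard_reads.fasta --out sim/detected.tsv
gisaq quantify sim/community.tsv --standard-counts sim/standard_counts.tsv \
      --design sim/gradient.yaml --out sim/absolute.tsv
```

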