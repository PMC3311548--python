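# mockbench

Benchmark DNA-extraction/sequencing protocols against mock microbial
communities. Given a community specification (taxon names, 16S rRNA gene
copy numbers, relative cell numbers), taxon × replicate read-count tables
and DNA-yield tables, the package answers four questions:

1. **Representation** — do observed read compositions match the
   copy-number-weighted expectation?  Scored per replicate by Euclidean
   distance, and tested formally with a likelihood-ratio test under a
   Dirichlet-multinomial sampling model (concentration θ captures
   replicate-level overdispersion) whose null distribution is estimated by
   parametric bootstrap.
2. **Reproducibility** — how far does each replicate sit from its method's
   pooled ("grand") proportions, and do methods differ in spread
   (Fligner–Killeen), across experimenters or days (Wilcoxon)?
3. **Yield** — log-scale split-plot ANOVA (method = whole plot, species =
   split plot, experimenter = random block), per-species Tukey HSD with
   compact letter displays, and top-vs-best-other fold-ratio summaries.
4. **Read QC** — barcode demultiplexing by Hamming distance,
   IUPAC-degenerate primer matching, and length/ambiguity/homopolymer
   filters for raw amplicon reads.

A synthetic-data module generates count tables, yield tables and barcoded
reads with the statistical structure the analyses assume, so the whole
pipeline is testable without any external data.  The package ships the
eleven-strain reference community and the published per-method summary
tables as plain-TSV fixtures; per-replicate counts rebuilt from those
summaries are reconstructions (the underlying raw data were never released)
and are labelled as such.

## Library at a glance

```python
from mockbench import (
    load_community, expected_proportions,      # community model
    read_count_table, observed_proportions, grand_proportions,
    lrt_gof,                                   # bootstrapped DM goodness of fit
    compare_methods,                           # distances + pairwise tests
    YieldTable, splitplot_anova, tukey_hsd_per_sample, yield_summary,
)
from mockbench.datasets import load_default_community
from mockbench.synthetic_data import SimulationConfig, simulate_counts

community = load_default_community()
expected = expected_proportions(community)
table = read_count_table("counts_method1.tsv", community)
result = lrt_gof(table, expected, n_bootstrap=999, seed=17)
print(result.lrt_stat, result.p_value)
```

## CLI

```sh
mockbench gof      --community c.tsv --counts x.tsv --bootstrap 999 --seed 17 --out gof.json
mockbench evaluate --community c.tsv --counts-dir counts/ --yields y.tsv --out report.json
mockbench yields   --in y.tsv --alpha 0.05 --out yield_report.json
mockbench readqc   --fastq in.fastq --barcodes bc.tsv --out-dir demux/ --log rejects.tsv
mockbench simulate counts --community c.tsv --seed 7 --out sim/
```

File formats are plain TSV: community (`name  copy_number  cell_fraction`),
counts (taxon rows, replicate columns, `#meta` header lines carrying
method/experimenter/day), yields
(`method  sample  replicate  experimenter  day  concentration`).

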