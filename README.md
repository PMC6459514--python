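# ligatyper

A toolkit for multiplex ligation-detection genotyping — the assay family in
which each targeted SNP or small deletion is interrogated by two
allele-specific 5' probes (each carrying a dye-routing tag) and one common
3' probe, so that a double ligation produces one fluorescently labelled
fragment per allele. All loci are read out together on a capillary
sequencer as peaks on four dye channels, and the pair *(dye, fragment
size)* uniquely addresses one allele of one locus.

`ligatyper` covers the full computational side of such an assay:

* **panel** — the domain model of a panel (variants, products, dye/size
  layout) with collision checking, JSON/TSV I/O, and a built-in 32-variant,
  10-gene hereditary hearing-loss panel (`builtin_panel_hl32`) spanning
  *GJB2*, *GJB3*, *SLC26A4*, *MT-RNR1*, *COCH*, *POU3F4*, *PAX3*, *MITF*,
  *SOX10* and *CEACAM16*, with gene-specific inheritance annotations
  (AR / AD / X-linked / mitochondrial) and 18 multiplex-PCR amplicon groups.
* **design** — probe construction from flanking sequence (nearest-neighbor
  melting-temperature model, deletion-junction probes) and a first-fit
  solver that assigns every ligation product a collision-free
  (dye, size-slot) address using stuffer-length shifts.
* **synth** — synthetic cohorts: generators that expand published
  per-variant zygosity counts into per-sample genotype truth sets (49
  validation cases, 50 controls, a 171-patient cohort with
  compound-heterozygous pairs), and a peak-level electropherogram simulator
  with a configurable noise model.
* **caller** — decoding: local-Southern size calling against the co-run
  ladder, peak-to-product matching, allele-ratio zygosity calls (including
  mitochondrial homoplasmy fractions), and truth-vs-call concordance.
* **interpret** — inheritance-aware diagnosis per sample (recessive
  homozygote, possible compound het with unknown phase, dominant/X-linked
  positive, carrier) and cohort summary tables (per-variant frequencies,
  per-gene counts, detection rate, diagnostic yield).
* **cli** — a thin `ligatyper` command with `validate`, `simulate`, `call`,
  `summarize`, `design` and `export-panel` subcommands.

The zygosity call at a nuclear locus uses the allele ratio
r = h_alt / (h_ref + h_alt) of the two product peak heights: heterozygous
for r in [0.25, 0.75], homozygous beyond r < 0.1 or r > 0.9, and a no-call
in the ambiguous bands between. Mitochondrial loci report r as the
homoplasmy fraction, with homoplasmic calls at r ≥ 0.95.

## Worked example

Simulate the built-in 171-patient cohort fixture, decode it, and summarise:

```
$ ligatyper simulate --fixture table5 --seed 7 --out-dir run
INFO ligatyper: simulated 171 samples
$ ligatyper call run/peaks.tsv --ladder run/ladder.tsv --out run/calls.tsv
INFO ligatyper: called 171 samples x 32 loci
$ ligatyper summarize run/calls.tsv --out-tsv run/summary.tsv --out-json run/report.json
n=171 detection=33.33% yield=12.87%
$ grep "c.235delC" run/summary.tsv
GJB2	13	c.235delC	12	4	9.36%
```

Reading the output: of 171 patients, 33.33% carry at least one panel
variant entry (57 variant-carrier entries), and in 12.87% the genotype
alone explains the hearing loss (a recessive homozygote or a homoplasmic
mitochondrial variant). The *GJB2* frameshift c.235delC was decoded as
homozygous in 12 and heterozygous in 4 samples — a 9.36% carrier
frequency — exactly the counts the fixture encodes, because the decoding
step recovers every simulated genotype.

The same pipeline is available as a library:

```python
import ligatyper as lt

panel = lt.builtin_panel_hl32()
truths = lt.validation_samples_from_table1(panel, seed=1)
tables = lt.simulate_cohort(panel, truths, lt.NoiseModel(rng_seed=1))
calls = lt.call_batch(panel, tables)
r = lt.concordance(lt.truth_to_matrix(panel, truths), calls)
print(r["sensitivity"], r["specificity"])   # 100.0 100.0
```

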