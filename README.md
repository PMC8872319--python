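# sweepkit

Selection-signature scanning for phased, biallelic SNP panels.  The package
implements a complete desk-scale pipeline:

- **SNP QC** — minor-allele-frequency, call-rate and exact Hardy-Weinberg
  filters (`sweepkit.qc`), with VCF 4.2 input/output (`sweepkit.vcfio`).
- **Diversity** — windowed nucleotide diversity (π), windowed Tajima's D,
  runs of homozygosity by the consecutive method, and F_ROH with
  0–2 / 2–4 / 4–8 / >8 Mb length classes (`sweepkit.diversity`).
- **LD and Ne** — pairwise haplotype r², LD-decay profiling with a
  threshold-crossing decay distance, and an LD-based historical effective
  population size trajectory via Ne = (1/(4c))(1/r²_adj − α), dated to
  t = 1/(2c) generations (`sweepkit.ld`).
- **Haplotype scan** — EHH curves, integrated haplotype homozygosity, and
  per-SNP iHS standardized within derived-allele-frequency bins, summarized
  as per-window mean |iHS| (`sweepkit.ihs`; hot loops are numba-compiled in
  `sweepkit._ihs_kernel` and verified against the pure-Python reference).
- **DCMS** — the de-correlated composite of multiple signals: genome-wide
  rank p-values per statistic, a robust (FAST-MCD) correlation of the
  statistics, logit-weighted combination, robust-normal calibration, and
  significance calls at p < 0.01 (`sweepkit.dcms`).
- **Annotation** — extension of significant windows by the LD-decay
  distance (or a fixed amount, default 200 kb), interval merging, and
  gene/QTL overlap reporting from GFF3/BED (`sweepkit.annotate`).
- **Synthetic data** — a founder-mosaic simulator with a neutral site
  frequency spectrum, realistic LD decay, and injectable sweeps, ROH tracts,
  missingness and genotype errors, so the whole pipeline is testable
  without external data (`sweepkit.simulate`).

## Command line

A `sweepkit` console script exposes each stage:

```bash
sweepkit sim --out panel.vcf --samples 25 --chrom-length 5000000 --snps 3500 --seed 1
sweepkit qc --in panel.vcf --out filtered.vcf --report qc.tsv
sweepkit stats --in filtered.vcf --out windows.tsv --window-size 100000
sweepkit roh --in filtered.vcf --out roh.tsv --summary froh.tsv
sweepkit ne --in filtered.vcf --out ne.tsv --mapping haldane
sweepkit ihs --in filtered.vcf --out ihs.tsv --windows-out wihs.tsv
sweepkit dcms --stats windows_with_ihs.tsv --out dcms.tsv --bed-out significant.bed
sweepkit annotate --windows significant.bed --genes genes.gff3 --qtl qtl.bed --out regions.tsv
```

`sweepkit pipeline --config run.conf --outdir out/` chains
qc → stats → ihs → dcms → annotate from one plain `key: value` config file
(keys: `vcf`, `window_size`, `seed`, `maf`, `call_rate`, `hwe_p`,
`ihs_maf`, `ihs_bins`, `alpha_mcd`, `sample_rows`, `p_threshold`,
`extension`, `extension_from_ld`, `genes`, `qtl`).

## Conventions

- Genotypes are held as an (samples × variants × 2) array of allele codes
  (0 = REF, 1 = ALT, −1 = missing); positions are 1-based and strictly
  increasing per chromosome.
- Windows are non-overlapping, anchored at position 1; reported tables use
  1-based inclusive coordinates, BED output is 0-based half-open.
- QC thresholds are strict (`remove if value < threshold`); MAF is computed
  over non-missing alleles.
- Physical distance maps to genetic distance at 1 cM/Mb unless stated; the
  `sved` Ne mapping currently aliases Haldane with a logged warning.
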