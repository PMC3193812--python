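# mitorec

Detection and analysis of repeat-mediated recombination in circular
mitochondrial genomes from short paired-end reads.

The package implements two pipelines plus the synthetic-data generator that
feeds them:

* **Recombination analysis** (wild type vs. mutant generations):
  self-alignment discovery of repeat pairs (50–556 bp, ≥85 % identity),
  circular-genome read mapping, clustering of discordant read pairs whose
  ends map >1,000 bp apart, a strict ">10 supporting reads in every mutant
  library after wild-type subtraction" filter, junction-to-repeat
  assignment, flank-coverage–based strand-invasion polarity, class I/II
  fate calling, and gene-conversion analysis (per-site donor/recipient
  resolution at nonidentical repeats).
* **Ecotype panel analysis**: strict-threshold SNP calling (> 5× depth,
  > 80 % allele fraction), NHEJ/REC/DEL structural-variant typing,
  substoichiometric-form labelling, TN93 + neighbor-joining phylogeny with
  column bootstrap, tree-based group assignment, and SV-by-group
  concordance.
* **Synthetic data** (`mitorec.synthetic_data`): a packaged 47-pair repeat
  catalog (14 flagged novel, 50–250 bp), reference genomes with planted
  repeats and decoys, asymmetric single-product recombinant molecules with
  donor-allele repair, 36-bp paired-end libraries with 220 ± 20 bp inserts
  at configurable per-repeat recombinant stoichiometry, and a 72-ecotype
  panel with tree-structured SNPs and planted structural variants — all
  with complete truth tables and byte-identical output per seed.

## Command line

```bash
# write a complete synthetic fixture (genome, truth tables, FASTQ libraries)
mitorec simulate --seed 1 --out fixture/

# repeat catalog only
mitorec repeats --genome fixture/genome.fasta --out catalog/

# full recombination analysis (FASTQ or SAM input per condition)
mitorec recombination --genome fixture/genome.fasta \
    --reads WT=fixture/WT_1.fastq,fixture/WT_2.fastq \
    --reads msh1_gen1=fixture/msh1_gen1_1.fastq,fixture/msh1_gen1_2.fastq \
    --reads msh1_adv=fixture/msh1_adv_1.fastq,fixture/msh1_adv_2.fastq \
    --out results/

# cross-ecotype analysis (one paired library per ecotype, >= 3 ecotypes)
mitorec panel --genome ref.fasta --reads E01=e1_1.fq,e1_2.fq ... --out panel/

# re-render plain-text summaries from a results directory
mitorec report --results results/
```

Exit codes: 0 success, 2 configuration error, 3 data error.  Thresholds and
library geometry live in a YAML config (`--config`); every run serializes
its effective configuration into the output directory.

Internally all coordinates are 0-based half-open; TSV reports are 1-based
inclusive and BED stays 0-based half-open.

## Layout

```
src/mitorec/
  formats_io.py     FASTA/FASTQ/SAM/BED/VCF/newick IO, coordinate types
  synthetic_data.py reference, recombinant and library generators, panel
  align_core.py     affine-gap local/global alignment, repeat discovery
  mapper.py         seeded circular-genome paired-end mapper, coverage
  junction_detect.py discordant-pair clustering, support filter, calls
  polarity_class.py flank-coverage polarity and class I/II fate
  conversion.py     inter-copy polymorphisms, recombinant consensus
  ecotype_phylo.py  SNP calling, SV typing, TN93/NJ/bootstrap, groups
  pipeline.py       end-to-end orchestration of both analyses
  cli.py, config.py command-line interface and run configuration
```
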