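# mtrkit

Regional missense-constraint scoring for protein-coding transcripts.

For every amino-acid position of an in-frame CDS, `mtrkit` compares the
*observed* proportion of missense (vs. missense + synonymous) single-nucleotide
variants within a truncated sliding window against the proportion *expected*
under neutrality from the exhaustive enumeration of all possible
single-nucleotide changes. The ratio of the two proportions (the missense
tolerance ratio, MTR) is 1 under neutrality and < 1 where missense variation
is depleted by purifying selection. Each codon's window counts are tested with
a two-sided exact binomial test; p-values are Benjamini–Hochberg adjusted in
one joint family across all tested codons, and maximal runs of codons with
q < 0.1 and MTR < 1 are reported as intolerant regions.

## Package layout

| module | contents |
| --- | --- |
| `mtrkit.cds_model` | `Transcript`, genetic-code translation, consequence classification, exhaustive possible-variant enumeration, observed-variant annotation (CDS or genomic coordinates, strand-aware) |
| `mtrkit.variant_io` | VCF/TSV observed-variant readers with PASS/SNV filtering and multi-allelic splitting, variant-query parsing, FASTA I/O, flat-file / score-table / BED writers |
| `mtrkit.core` | window bounds, window summation, the ratio itself, per-transcript profiles, population-stratified profiles |
| `mtrkit.stats` | exact binomial test (minimum-likelihood two-sided), BH adjustment, region calling, Mann–Whitney comparison, low-score enrichment odds ratios |
| `mtrkit.synthetic` | ground-truth simulator: random transcripts, Bernoulli observation model with depleted regions, truth evaluation |
| `mtrkit.cli` | `mtrkit compute / query / simulate / plot` |

## CLI

```sh
# generate a synthetic dataset (FASTA + observed TSV + truth TSV)
mtrkit simulate --scenario scenario.yaml --out-dir sim/

# score transcripts against observed variants
mtrkit compute sim/cds.fasta sim/observed.tsv --out-dir results/ --window 31

# query computed tables
echo "7-140453136-A-T" | mtrkit query - --results-dir results/

# render the line graph (red = FDR-significant depleted segments)
mtrkit plot results/mtr_table.tsv --out profile.png
```

`compute` writes four files to `--out-dir`:

* `flat.tsv` — one row per possible variant: `transcript_id chromosome
  position ref alt codon_index consequence mtr raw_p fdr_q`. With a genomic
  map (`--genomic-map`, TSV of `transcript_id cds_pos chrom genomic_pos
  [strand]`) positions are genomic; otherwise `chromosome` is `NA` and
  `position` is the CDS position.
* `mtr_table.tsv` — one row per codon: `transcript_id codon_index mtr obs_mis
  obs_syn exp_mis exp_syn raw_p fdr_q significant`.
* `regions.bed` — intolerant regions, 0-based half-open, in protein
  coordinates (`transcript_id start-1 end`) or genomic coordinates when a map
  is present.
* `run_summary.json` — per-stage counters (rows read / kept / dropped by
  reason, tests performed, regions called).

Configuration precedence is flags > `--config` YAML > defaults
(window 31 of {21, 31, 41}; FDR threshold 0.1, joint scope;
population-stratified profiles need ≥ 15 000 declared exomes and windows
{31, 41}; genomic positions documented as GRCh37).

### Input formats

* **CDS FASTA** — one record per transcript, header `transcript_id` or
  `transcript_id|gene_symbol`; sequence must be in-frame, unambiguous ACGT; a
  terminal stop codon is excluded from amino-acid positions.
* **Observed variants** — VCF 4.x (multi-allelic rows are split; only
  single-nucleotide PASS records are kept) or a TSV dialect with columns
  `chrom pos ref alt filter population` (`#` comments; last two columns
  optional). In CDS mode (`--mode cds`, the default) the first column holds
  the transcript id and `pos` is a 1-based CDS position; in genomic mode
  positions resolve through the genomic map and minus-strand alleles are
  reverse-complemented into coding-strand space.
* **Variant queries** — one per line: `chrom-pos-ref-alt`, `chrom-pos`, or
  `transcript:protein_pos` (`-` also accepted); case-insensitive; unmatched
  or unparseable lines are reported in the results table, never dropped.
* **Scenario YAML** (for `simulate`) — keys `seed`, `n_transcripts`,
  `length_codons: [min, max]`, `pi_obs`, optional `depleted_regions` (list of
  `{transcript_index, start_codon, end_codon, rho}`) and `populations`
  (label → mixture proportion summing to 1).

## Method conventions

* Coordinates are 1-based inclusive; codon `i` covers CDS positions
  `3i-2..3i`; windows are `[max(1, i-(w-1)/2), min(L, i+(w-1)/2)]` with odd
  `w`.
* Observed variants are counted as distinct `(cds_pos, alt)` changes; every
  possible change is weighted equally in the expectation; only missense and
  synonymous changes enter either tally (stop-gained and stop-codon-context
  changes are labelled but excluded).
* Windows with zero observed variants have an undefined score (`NA`) and are
  excluded from testing and FDR ranking.
* The exact test is two-sided with the minimum-likelihood tail; region
  calling additionally requires MTR < 1, so only depletion is reported.

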