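# neonovelty

Peptide-novelty metrics for tumor neoepitope prioritization, as a tested
library and CLI:

- **Binding novelty** — the tumor-vs-normal binding affinity difference
  (in nM, from externally predicted affinities) and a *novel binding
  change* classifier: tumor affinity strictly below 500 nM, normal
  affinity at least 500 nM and at least 5-fold weaker (thresholds
  configurable).
- **Anchor-masked similarity** — BLOSUM62 similarity between a
  neoepitope and a comparator peptide, with MHC anchor residues
  (position 2 and the last position) masked, self-normalized to a
  percent scale (score against the comparator divided by the query's
  self-score).
- **Closest-peptide homology** — an exact, exhaustive, fixed-length,
  ungapped search for the closest human / bacterial / viral peptide
  window, with full tie retention and gene-of-origin match status. This
  is an exact equivalent of an ungapped blastp protocol at fixed
  alignment length: for a fixed query length and database, the E-value
  is a monotone function of the raw BLOSUM62 score, so highest-raw-score
  selection reproduces lowest-E-value selection without a BLAST binary.
- **Population metrics** — cross-patient neoepitope recurrence counts
  and overlap spectra of random six-allele HLA sets (two A, two B,
  two C, sampled without replacement).
- **Immunogenicity model** — per-study immune-response binarization, a
  linear probability model (OLS on the 0/1 response, with logistic
  regression as an option), a reduced four-predictor full-factorial
  multiplicative model, and rank-based AUROC.
- **Synthetic data** — deterministic generators (random proteomes,
  random single-substitution neoepitopes, a pseudo-affinity hash, and
  cohorts with known generative coefficients) so the entire pipeline is
  testable offline. The pseudo-affinity function is not a biological
  model.

## CLI

One subcommand per pipeline stage, composable via TSV/FASTA files
(tab-separated, header row, `.` for missing values). Every subcommand is
deterministic given its inputs and seed, writes a `*.manifest.json` with
input checksums next to its main output, and logs to stderr. Exit codes:
0 success, 2 usage error, 3 data error.

```sh
# synthetic fixtures: proteome FASTA, simulated neoepitopes, pseudo-affinities
neonovelty simulate --seed 1 --n-proteins 20 --alleles 'HLA-A*02:01' \
    --out-proteome proteome.fasta --out-neoepitopes sims.tsv --out-affinities aff.tsv

# tumor/normal epitope windows from missense variants
neonovelty enumerate --variants variants.tsv --proteome proteome.fasta \
    --lengths 8,9,10,11 --out pairs.tsv

# all four novelty metrics per (pair, allele)
neonovelty profile --pairs pairs.tsv --affinities aff.tsv \
    --human human.fasta --bacterial bact.fasta --viral viral.fasta \
    --alleles 'HLA-A*02:01' --out profiles.tsv

# HLA-set overlap spectra and recurrence accounting
neonovelty overlap --affinities aff.tsv --allele-frequencies freq.tsv \
    --n-sets 1000 --seed 1 --out spectrum.tsv
neonovelty recur --patients patients.tsv \
    --out-sequences seq_counts.tsv --out-patients patient_fracs.tsv

# immunogenicity model (terms: full | reduced | comma list, a:b = product)
neonovelty fit-model --cohort cohort.tsv --terms reduced \
    --out-model model.json --out-scores scores.tsv
neonovelty score --model model.json --records new.tsv --out scored.tsv
```

Variant TSV columns: `gene`, `protein_position` (1-based),
`ref_aa`, `alt_aa`, and either `protein_seq` or `protein_id` (resolved
against `--proteome`). Affinity TSV columns: `peptide`, `allele`,
`affinity_nm`. FASTA description lines may carry a `gene=<id>` token;
otherwise the record id doubles as the gene id.

## Notes

- Positions are 1-based; windows are closed intervals.
- The anchor mask `{2, last}` is stated for 9mers and generalized to all
  lengths; override per length via `PipelineConfig.anchor_overrides`.
- The bundled BLOSUM62 is the standard NCBI half-bit integer matrix
  (`src/neonovelty/data/blosum62.txt`), symmetry-checked at load time and
  verified against Biopython's copy in the test suite. Diagonal dominance
  (and hence the ≤ 100 % similarity bound) holds over the 20 standard
  letters; ambiguity letters B/Z/X are accepted in sequences but scored
  with their standard rows.
- Missing affinities raise errors; they are never imputed.
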