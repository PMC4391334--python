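# methylaudit

Privacy audit toolkit for Illumina HumanMethylation450-style beta-value
matrices. A CpG-destroying SNP at an ordinarily fully methylated site leaves
a tri-modal fingerprint in the beta values (~1.0 / ~0.5 / ~0.0 by genotype),
so a "non-genetic" methylation matrix quietly carries genotypes.
`methylaudit` extracts them and quantifies the resulting re-identification
risk:

- **Informative-probe discovery** — bin beta values (X > 0.7,
  0.3 < Y < 0.7, Z < 0.25), keep probes with ≥ 95% of samples binned and
  ≥ 4 samples in each homozygote bin, screen by a Hardy-Weinberg
  equilibrium chi-square test (P > 0.01), rank by observed heterozygosity.
- **Genotype calling** — X → CC, Y → CD, Z → DD (D = the unidentified
  non-C allele); boundary/gap values become missing calls.
- **Fingerprint matching** — per-sample genotype vectors, cross-dataset
  concordance ranking, and a forensic product-rule random-match probability
  (log10, under HWE and locus independence).
- **PHI flagging** — beta extraction at trait CpGs (default panel:
  cg05575921 / AHRR, smoking, lower-in-positive; no default threshold
  ships — you must supply one).
- **Redaction** — remove informative probes from a matrix before sharing.
- **MspI assay design** — in-silico check of which candidate CpGs sit
  inside a CCGG tetramer and predicted digest fragment lengths per genotype.
- **Synthetic data** — a seeded simulator planting SNP probes (HWE
  genotypes, tri-modal betas), background probes, missingness, and a
  smoking-dependent probe, with complete truth tables.

## CLI

```sh
# discover informative probes and call genotypes
methylaudit audit --beta betas.tsv --format tsv --out-dir audit_out \
    --min-binned-fraction 0.95 --min-homozygotes 4 --hwe-p 0.01
# optional: compare observed vs reference heterozygosity
methylaudit audit --beta betas.tsv --out-dir audit_out --reference-het ref_het.tsv

# match samples between two genotype call matrices
methylaudit match --query audit_out/genotypes.tsv \
    --reference other/genotypes.tsv --min-overlap 30 \
    --freqs audit_out/informative_probes.tsv --out matches.tsv

# redact the informative probes before data sharing
methylaudit redact --beta betas.tsv --probes audit_out/informative_probes.tsv \
    --out redacted.tsv

# flag smoking status (threshold must be supplied in the panel file)
methylaudit phi-report --beta betas.tsv --panel panel.tsv --out phi_report.tsv

# which probes are genotypable by MspI digest
methylaudit mspi-design --annotation probes.csv --probes cg10695549,cg21028319

# generate synthetic data with truth tables
methylaudit simulate --config sim.yaml --out-prefix sim
```

Beta matrices are plain TSV (first column probe IDs, header row sample IDs;
missing as empty/`NA`/`NaN`) or GEO series-matrix text files (`--format geo`).
Exit code 2 signals an input-format problem.

## Layout

| module | contents |
| --- | --- |
| `methylaudit.io_methylation` | beta-matrix / annotation / genotype-call readers and writers |
| `methylaudit.genotype_inference` | binning, candidacy filter, genotype calls, probe selection |
| `methylaudit.popgen_stats` | allele frequencies, heterozygosity, HWE test, reference comparison |
| `methylaudit.privacy_fingerprint` | fingerprints, matching, random-match probability, redaction |
| `methylaudit.phi_traits` | trait-CpG extraction and substance-use flagging |
| `methylaudit.assay_design` | MspI site scan, assayability, digest fragment prediction |
| `methylaudit.synthetic_data` | seeded simulator + truth tables |
| `methylaudit.cli` | `methylaudit` console entry point |
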