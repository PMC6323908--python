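# mitotier

Enumeration, disease scoring and pathogenicity tier assignment for human
mitochondrial DNA substitutions.

## The problem

The human mitochondrial genome is a 16,569 bp circular molecule numbered
1-based against the revised Cambridge Reference Sequence (rCRS,
NC_012920.1). Excluding indels, its complete substitution space is finite —
three alternative alleles per site, 3L = 49,707 variants — so mitochondrial
variant annotation can be exhaustive: every *potential* substitution can be
enumerated, classified and scored, and a variant becomes *observed* the
moment its allele frequency in a cohort of complete genomes rises above
zero.

`mitotier` implements that workflow for researchers and diagnostic
laboratories triaging mtDNA variants:

- **Enumeration** of the full substitution space against a reference and a
  CDS/tRNA/rRNA/regulatory locus map, with functional-effect calling under
  the vertebrate mitochondrial genetic code (translation table 2).
- **Cohort statistics** from health-stratified complete genomes: per-variant
  allele frequencies AF (overall, healthy, pathologic; genomes are haploid
  consensus sequences) and per-site variability scores `nt_var`/`aa_var` in
  [0, 1] (0 = fully conserved).
- **Disease scores (DS)** in [0, 1]: for tRNA variants, a weighted sum of
  nine literature-derived criteria whose raw weights (2,1,1,2,2,2,2,5,3) are
  normalized by their total — e.g. cybrid/steady-state functional evidence
  contributes 5/20 = 0.25; for non-synonymous variants, a configurable
  consensus (default: weighted mean) of external predictor probabilities.
  Stop-gain, stop-loss and frameshift variants are never scored.
- **Tier assignment** from the (DS, AF) quadrant, with inclusive boundaries:

  | tier | DS | AF |
  |---|---|---|
  | Polymorphic        | DS < DS_T | AF > AF_T |
  | Likely Polymorphic | DS < DS_T | AF ≤ AF_T |
  | Likely Pathogenic  | DS ≥ DS_T | AF > AF_T |
  | Pathogenic         | DS ≥ DS_T | AF ≤ AF_T |

  with DS_T = 0.43, AF_T = 0.003264 for non-synonymous variants and
  DS_T = 0.35, AF_T = 0.005020 for tRNA variants. A tRNA variant with no
  functional-study evidence at all is VUS regardless of DS; an unassigned DS
  gives Unclassified. AF_T can be re-estimated from data as an empirical
  quantile of the allele frequencies of high-scoring variants.

A synthetic-study generator plants variants at exact per-stratum allele
frequencies with chosen evidence patterns, emitting cohort FASTA, status
manifest, evidence tables and a truth table, so the full pipeline is testable
end to end without external data. The bundled full-length reference is a
deterministic *synthetic* sequence carrying the real rCRS length and the
standard 37-gene locus coordinates.

## Worked example

```
mitotier simulate --outdir demo --seed 7
mitotier annotate --reference demo/reference.fa --loci demo/loci.tsv \
    --cohort demo/cohort.fa --manifest demo/manifest.tsv \
    --trna-evidence demo/trna_evidence.tsv --predictors demo/predictors.tsv \
    --out demo/annotated.tsv --vcf demo/annotated.vcf
mitotier summarize --annotated demo/annotated.tsv
```

The simulated study plants 22 variants in a 500-genome cohort (400 healthy,
100 pathologic) over a 600 bp toy genome; `annotate` reports
`1800 annotated substitutions` (3 × 600) and the summary prints:

```
| tier | count |
|---|---|
| Pathogenic | 6 |
| Likely Pathogenic | 4 |
| Likely Polymorphic | 4 |
| Polymorphic | 3 |
| VUS | 2 |
| Unclassified | 3 |
```

exactly matching the expected tiers in `demo/truth.tsv`. A single variant
card shows every annotation panel:

```
mitotier card --annotated demo/annotated.tsv --variant "m.61C>A"
```

```json
{
  "variant": {"position": 61, "ref": "C", "alt": "A", "hgvs": "m.61C>A"},
  "main_info": {"locus": "TOY-TX", "locus_type": "tRNA",
                "functional_class": "tRNA", "status": "observed"},
  "variability": {"af_total": 0.004, "af_healthy": 0.0,
                  "af_pathologic": 0.02, "nt_var": 0.0188, "aa_var": null},
  "pathogenicity": {"disease_score": 1.0, "tier": "Pathogenic",
                    "vus": false, "ds_threshold": 0.35,
                    "af_threshold": 0.00502}
}
```

This variant satisfies all nine tRNA criteria (DS = 1.0 ≥ 0.35) and sits at
AF 2/500 = 0.004 ≤ 0.005020, carried only by pathologic genomes — hence
Pathogenic.

Library use mirrors the CLI: `enumerate_potential`, `compute_cohort_stats`,
`trna_disease_score` / `nonsyn_disease_score`, `assign_tier` and
`annotate_cohort` compose the same chain in Python.

## Documentation

See `docs/methods.md` for the scoring model, its assumptions, parameter
defaults and known limitations.
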