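# cncpipe

A tested, reusable pipeline for integrative lncRNA/mRNA analysis of
two-group expression microarrays: detection-flag filtering and quantile
normalization, two-group differential expression with validation-candidate
selection and qPCR concordance, coding/non-coding (CNC) co-expression
networks, cis nearby-gene pairing, ceRNA (lncRNA–miRNA–mRNA) triad
inference by canonical seed matching, Fisher-exact gene-set enrichment,
and MCODE-style dense-module detection on PPI edge tables — all
exercisable end-to-end on seeded synthetic data with planted ground truth.

## Layout

| module | role |
| --- | --- |
| `cncpipe.io_formats` | validated readers/writers: expression TSV with paired flag columns, annotation, design, GMT, FASTA, PPI edge table, TSV/SIF edge output |
| `cncpipe.preprocess` | flag filter (≥ k of n samples Present/Marginal), quantile normalization, log2 transform |
| `cncpipe.diffexpr` | pooled/Welch t-tests, linear fold changes, DE calling (FC ≥ 1.5, p < 0.05), validation-candidate selection (FC > 2, p < 0.05, intensity > 500, top 10 per direction), concordance rate, hierarchical leaf ordering |
| `cncpipe.coexpression` | Pearson edges with \|r\| ≥ 0.9 and p ≤ 0.005 between lncRNAs and mRNAs |
| `cncpipe.cis_nearby` | genomic nearest-edge distances, 200 kb window pairing, CNC ∩ cis overlap |
| `cncpipe.cerna` | seed-site scan (8mer / 7mer-m8 / 7mer-A1 / 6mer), miR-number filter (< 1000), direction-concordant triad construction, pathway restriction |
| `cncpipe.enrichment` | one-sided Fisher exact over-representation with −log10(p) scores |
| `cncpipe.ppi_mcode` | score-thresholded PPI graph (≥ 0.7), degree hubs (≥ 5), MCODE clusters (density × size) |
| `cncpipe.group_stats` | mean/(population) SD summaries, uncorrected 2×2 chi-square, Shapiro–Wilk, two-group comparison tables |
| `cncpipe.synthetic_data` | seeded generator with planted DE features, correlated pairs, cis neighbors straddling the window, seeded transcripts and a PPI clique; per-stage recovery reports |
| `cncpipe.datasets` | bundled 8-subject reference cohort and 20+20 qPCR validation outcomes |
| `cncpipe.cli` | `cncpipe` command-line orchestrator |

## CLI

```sh
# full synthetic run: simulate -> preprocess -> de -> cnc -> cis -> overlap
#                     -> cerna -> enrich -> ppi -> truth recovery
cncpipe all --seed 7 --outdir out/

# single stages (each reads the previous stage's outputs from --outdir)
cncpipe simulate --seed 7 --outdir out/
cncpipe preprocess --outdir out/
cncpipe de --outdir out/

# demographic comparison table from a per-subject TSV
cncpipe stats --subjects subjects.tsv --continuous age,surgery_duration \
              --binary cvd=yes,chd=yes --outdir out/
```

Thresholds live in a flat `key = value` config file (`--config`); defaults
are the study values (flag min 4/8, FC 1.5, p 0.05, |r| 0.9, p 0.005,
window 200 kb, validation FC 2 / intensity 500 / top 10, PPI 0.7, hub
degree 5, MCODE score cutoffs 4 and 5, enrichment p 0.05, miR id < 1000).
Every stage writes a manifest with input/output hashes; identical seeds
reproduce byte-identical outputs.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria. One test
(`TestAccessionCounts`) is an integration check against the deposited GEO
series GSE163943 and fails unless that dataset is staged locally under
`scratch/GSE163943/` — it is intentionally red in offline environments.

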