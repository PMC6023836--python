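# devmir

Integrative analysis of paired mRNA / miRNA developmental time-course
expression: empirical-Bayes moderated differential expression against a
reference stage, fuzzy c-means clustering of standardized temporal profiles,
multi-resource miRNA-target collation, Kendall anti-correlation networks at
the cluster level (M_all / M_neg), and miRNA prioritization (DETG/DETGNC
statistics, regulator counting, a stringent candidate filter, and template
matching). A synthetic-data generator with planted repressive miRNA→gene
interactions makes every stage testable without external downloads.

## Layout

| module | contents |
| --- | --- |
| `devmir.simulate` | synthetic paired dataset generator (archetypal temporal profiles, planted repression, decoy interactions, annotations, ground truth) |
| `devmir.io` | expression matrix / sample sheet TSV I/O, probe collapsing, the expression filter (max per-stage mean > 5), stage-mean profiles |
| `devmir.de` | moderated t with digamma/trigamma variance-prior estimation, BH adjustment, DE calling (p_adj ≤ 1e-5, \|log2FC\| ≥ 2), paired sex contrast, sex fold-change counts |
| `devmir.clustering` | profile standardization, fuzzy c-means (m = 2), Dmin curve, cluster ordering, overlap tables |
| `devmir.targets` | per-resource interaction reading, score cutoffs, percentile conversion, expression restriction, resource merging |
| `devmir.network` | Kendall tau-b (full series and embryonic-only), anti-correlation flagging (τ < −0.4), M_all/M_neg link matrices, dominant links |
| `devmir.prioritize` | DETG/DETGNC counts, anti-correlated regulator shortlist, stringent filter, template matching |
| `devmir.enrichment` | one-sided hypergeometric overrepresentation with BH FDR |
| `devmir.pipeline` / `devmir.cli` | end-to-end orchestration from a flat YAML config, JSONL manifest, `devmir` CLI |

## CLI

Each stage is a subcommand (`devmir <cmd> --help` for options):

```bash
devmir simulate --out sim/ --seed 1            # synthetic dataset + truth tables
devmir filter   --matrix sim/genes.tsv --samples sim/gene_samples.tsv --out expressed.tsv
devmir de       --matrix sim/genes.tsv --samples sim/gene_samples.tsv \
                --reference young --out de.tsv
devmir cluster  --matrix sim/genes.tsv --samples sim/gene_samples.tsv --c 6 --out clusters.tsv
devmir integrate --interactions resA=a.tsv --interactions resB=b.tsv --out merged.tsv
devmir correlate --interactions merged.tsv --gene-matrix ... --mode dev --out corr.tsv
devmir prioritize --correlated corr.tsv --de-genes de.tsv --de-mirnas de_mir.tsv \
                  --annotations ann.tsv --out prio.tsv
devmir enrich   --query q.txt --categories cats.tsv --universe u.txt --out enr.tsv
devmir run      --config pipeline.yaml --out out/ --seed 1   # everything end to end
```

`devmir run` with no config executes the full pipeline on the default
synthetic dataset and writes all tables plus `manifest.jsonl` (seeds,
thresholds, row counts, checksums). Reruns with the same config and seed are
byte-identical.

## Tests and acceptance

```bash
python -m pytest tests/            # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-verifies every acceptance criterion from scratch
(oracle equivalence for Kendall tau, BH and the hypergeometric test,
moderated-t limiting behavior and null calibration, fuzzy c-means
correctness and planted-archetype recovery, link-matrix conservation,
end-to-end planted-repressor recovery over ten seeds, and determinism) and
prints a pass/fail summary. The analysis is validated by these properties
rather than numeric targets, so the JSON target report it writes is an
empty object.
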