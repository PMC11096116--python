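# cladescope

Comparative-genomics and co-expression analyses over genomes grouped into
clades, exercisable end to end on synthetic data with planted ground truth.

The toolkit covers five analysis stages plus a simulator:

- **`cladescope.synthetic`** — generators for every input the pipeline
  consumes: per-genome domain hit tables (TSV and hmmscan-domtblout dialect)
  with planted clade-exclusive families and planted abundance expansions,
  orthogroup tables mirroring the same presence pattern, expression matrices
  with planted co-expressed modules carrying functional-category labels, and
  paralog CDS pairs evolved by synonymous-only substitutions to a known
  synonymous divergence (optionally with a duplication-burst mixture
  component). Every generator is seeded and byte-reproducible.
- **`cladescope.domains`** — domain hit parsing (6-column TSV or hmmscan
  `--domtblout`), E-value filtering, greedy overlap resolution, per-protein
  architectures and unordered domain combinations, per-genome feature count
  tables.
- **`cladescope.cladesets`** — presence/absence algebra over a genome→group
  partition: group presence, Venn-region partitioning of features,
  clade-exclusive feature extraction under `any_genome` / `all_genomes`
  universality, Jaccard repertoire similarity between groups.
- **`cladescope.stats`** — exact Wilcoxon rank-sum two-group abundance
  (expansion) tests with midrank tie handling (full permutation enumeration
  for groups of ≤10 genomes, tie-corrected normal approximation beyond),
  one-sided hypergeometric (Fisher) enrichment, Benjamini–Hochberg FDR.
- **`cladescope.coexpression`** — highest-reciprocal-rank (HRR) co-expression
  networks from Pearson correlation ranks, neighborhood-chiseling module
  detection, per-module functional-category counts and category
  co-occurrence frequencies.
- **`cladescope.wgd`** — reciprocal-best-hit paralog pairing, protein-guided
  codon alignment back-translation, NG86 Ks/Ka, raw and composition-corrected
  4dtv at fourfold-degenerate sites, zero-filtered Gaussian-KDE divergence
  distribution summaries with peak calling.

## CLI

All stages are exposed through one entry point:

```bash
# generate a synthetic fixture set (see tests/test_cli.py for a config example)
cladescope simulate --config config.yaml --out fixtures/ --seed 1

# per-genome domain and combination count tables
cladescope domains --hits 'fixtures/hits_*.tsv' --dialect tsv --out features/

# Venn regions, exclusives, repertoire similarity
cladescope cladesets --features features/domain_counts.tsv \
    --partition fixtures/partition.tsv \
    --region Zygnematophyceae+Embryophyta --out cladesets/

# two-group expansion test / foreground enrichment
cladescope expand --features features/domain_counts.tsv \
    --partition partition2.tsv --alternative greater --out expand.tsv
cladescope enrich --foreground fg.txt --universe universe.txt \
    --map gene2term.tsv --out enrich.tsv

# HRR network + modules + category co-occurrence
cladescope coexpress --matrix fixtures/expression.tsv --cutoff 30 \
    --categories fixtures/gene_categories.tsv --out coexpr/

# Ks / 4dtv screening (RBBH from sequences, or --paired for aligned pairs)
cladescope wgd --cds fixtures/paralog_pairs.fasta --paired --out wgd/
```

## Notes on defaults

- Domain overlap resolution: E-value ≤ 1e-5, greedy by ascending E-value,
  drop on >50% overlap of the shorter hit. Configurable; declared defaults.
- HRR cutoff 30, chiseling step size 3, module size bounds [3, 100].
- Ks estimator: NG86 with Jukes–Cantor correction. Note the estimator's
  documented upward bias at Ks ≳ 1 (twofold-degenerate sites saturate faster
  than the JC model assumes).
- 4dtv correction: HKY-style transversion distance using the observed
  purine/pyrimidine composition at fourfold-degenerate third positions.
- KDE: Scott's-rule bandwidth, 512-point grid on [0, 5], peaks require ≥5%
  of the maximum density.
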