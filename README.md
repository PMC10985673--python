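# lshtax

Taxonomic classification of short reads and abundance profiling of
metagenomic samples via locality-sensitive hashing (LSH) of k-mers.

Reference 32-mers are packed 2 bits/base into 64-bit words and indexed in
`l` bucketed hash tables whose rows are bit-samples of `h` fixed base
positions, so near-identical k-mers (low Hamming distance) collide with
high probability while lookups follow at most `b*l` pointers and compute
true distances — no false-positive matches. Each stored k-mer carries a
single 2-byte taxon label assigned by a probabilistic *soft LCA* rule that
resists label inflation from rare outlier genomes. At query time every read
k-mer votes for its best match's taxon with mass `(1 - hd/k)**k`; votes are
aggregated bottom-up over the taxonomy, and the read is assigned at the
lowest rank whose total exceeds half the root total. Sample-level profiles
normalize votes twice (per read, then per sample), optionally carry an
explicit *unclassified* component, and can be genome-size-corrected from
read fractions to cell fractions.

Everything is exercisable on fully synthetic data: `lshtax synth` builds a
seeded world (taxonomy, genomes evolved by substitutions, error-bearing
reads at controlled novelty), so no external databases are needed.

## CLI

```sh
# synthetic world: 24 reference genomes + query read sets at two novelties
lshtax synth --outdir world --seed 1 --novelty 0.0 --novelty 0.1

# build the reference library (h=11 is the desk-scale default; h=15 is
# the documented production setting for ~8G k-mer libraries)
lshtax build --reference-list world/references.tsv \
             --nodes world/nodes.dmp --names world/names.dmp \
             --out library --h 11 --seed 1

# classify reads and score against the truth
lshtax classify --library library --reads world/queries/<q>.fastq --out calls.tsv
lshtax evaluate --library library --truth world/queries/<q>.truth.tsv \
                --predictions calls.tsv --out metrics.tsv

# per-rank abundance profiles (CAMI/Bioboxes + TSV mirror)
lshtax profile --library library --reads world/queries/<q>.fastq --out-prefix prof

# analytic match-probability tables and parameter suggestions
lshtax params --L 150 --d 0.25 --num-kmers 8589934592
```

Key defaults: `k=32, h=15, l=2, b=7, p=3, d_max=5, w=4, s=5,
min_total_vote=0.03`.

## Layout

- `src/lshtax/seqcodec.py` — 2-bit k-mer codec, canonicalization, Hamming distance
- `src/lshtax/lsh.py` — bit-sampling LSH index + analytic match model
- `src/lshtax/taxonomy.py` — rank-annotated tree, LCA, lineage, genome lengths
- `src/lshtax/build.py` — library construction and soft-LCA labeling
- `src/lshtax/classify.py` — distance-weighted voting and rank selection
- `src/lshtax/profiling.py` — two-level normalized profiles, CAMI writer
- `src/lshtax/metrics.py` — per-rank contingency scores, Bray-Curtis, Shannon, L1
- `src/lshtax/synthgen.py` — seeded synthetic worlds
- `src/lshtax/cli.py` — `lshtax` subcommands
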