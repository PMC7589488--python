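# mutsig

Mutational-signature analysis in Python: from somatic single-nucleotide
variants (SNVs) to pyrimidine-oriented mutation-type catalogs, de novo
signature extraction by bootstrapped non-negative matrix factorization
(NMF), deconvolution of mutation counts against known signatures, and
cosine-distance signature matching — plus a synthetic-data generator
that makes the whole pipeline testable end to end without downloads.

## Who this is for

Cancer-genomics analysts who have somatic SNV calls (VCF or MAF-style
tables) and a reference genome (any species, FASTA) and want to know
which mutational processes shaped them: extraction of de novo
signatures from a cohort, quantification of known signatures (e.g. the
COSMIC catalog) in individual samples, and downstream comparison of
signature activities.

## The model

Let `V` be an `m × n` matrix of mutation counts — `m` mutation types
(96 for the standard tri-nucleotide context, 384 for the 5′-extended
tetra-nucleotide context; always oriented so the mutated base is a
pyrimidine, per the COSMIC convention) by `n` samples. De novo
extraction solves

```
V ≈ W × H,    W ≥ 0 (m × k),   H ≥ 0 (k × n)
```

where the `k` columns of `W` are mutational signatures (probability
vectors over mutation types) and the rows of `H` are per-sample
signature activities ("exposures", in mutation units). Because a single
NMF run is unreliable, the extraction repeats a **multinomial bootstrap**
of each sample's counts followed by an NMF run (Brunet's
multiplicative updates for the Kullback–Leibler divergence, or Lin's
convergent variant for the Frobenius objective), pools all per-run
signature columns, clusters them under cosine distance, and reports the
cluster centroids; **silhouette widths** measure how reproducible each
signature is across replicates. Samples with extreme burden
(hyper-mutators) dominate raw-count extraction; the optional `freq`
normalization rescales every sample to the cohort's median total so all
samples weigh equally.

When signatures are known, exposures solve the non-negative
least-squares problem `min ‖V − WH‖_F, H ≥ 0`, via the fast
combinatorial (Van Benthem–Keenan) active-set strategy that groups
samples sharing a passive set.

## Worked example

Simulate a cohort with three planted signatures, extract, and compare:

```bash
cat > spec.json <<'EOF'
{"n_chrom": 2, "chrom_length": 8000, "k": 3, "n": 20,
 "mutations_per_sample": 400, "seed": 7}
EOF
mutsig simulate --spec spec.json --out-dir sim
mutsig extract --counts sim/counts.tsv --k 3 --iterations 30 --seed 11 --out-prefix demo
mutsig match --sig-a demo.signatures.tsv --sig-b sim/planted_signatures.tsv --out match.tsv
```

which prints

```
wrote 8206 variants across 20 samples to sim
mean silhouette: 0.9862
signature_01 -> planted_01 (distance 0.0097, MATCH)
signature_02 -> planted_03 (distance 0.0034, MATCH)
signature_03 -> planted_02 (distance 0.0054, MATCH)
```

Mean silhouette near 1 says the 30 bootstrapped solutions cluster into
three tight, well-separated groups — the extraction is stable. Each
extracted signature sits at cosine distance < 0.01 from one planted
signature (0 = identical profile, 1 = unrelated), i.e. the planted
processes are recovered essentially exactly. Exposures for the cohort,
in mutation counts per sample, come from

```bash
mutsig deconvolute --counts sim/counts.tsv --signatures demo.signatures.tsv --out exposures.tsv
mutsig mc-null --exposures exposures.tsv --nsim 2000 --seed 3 --out null.tsv
# observed min Spearman: -0.5897  p = 0.6735
```

The Monte-Carlo null says an anti-correlation of −0.59 between relative
activities is unremarkable (p = 0.67) once the sum-to-one constraint is
accounted for.

The same workflow applies to real data: `mutsig count --maf cohort.maf
--fasta hg19.fa --out-prefix cohort` builds the 96-type catalog, and
`--n-up 2` switches to tetra-nucleotide types, which
`mutsig.simplify_context` can later bin back onto the 96 types for
comparison with standard catalogs.

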