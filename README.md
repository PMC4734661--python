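# farmscan

Genome-wide association scanning by iterative use of two models: a
fixed-effect single-marker regression that carries a set of "pseudo QTNs"
(associated markers standing in for unknown causal variants) as covariates,
and a random-effect REML model whose kinship is built solely from those
pseudo QTNs and is used to reselect them through a bin-based grid search.
The package also ships the companion phenotype simulator (geometric or equal
QTN effects, calibrated residual variance) and the power / FDR / Type-I /
enrichment evaluation machinery, plus a synthetic-genotype fixture generator
with controllable LD blocks so everything runs without external data.

## Algorithm sketch

1. Optionally seed the pseudo-QTN set with known candidate markers
   (otherwise start empty).
2. Test every marker by least squares against
   `[intercept | covariates | pseudo-QTN dosages]` (QR factorized once,
   rank-one update per marker — cost linear in markers and samples).
3. **Substitution**: pseudo QTNs are collinear with the design and get no
   test of their own; each one's sentinel P value is replaced by a summary
   (default: minimum = most significant) of the P values its coefficient
   attained across all single-marker tests.
4. Stop if no marker passes the Bonferroni-corrected threshold (default 1%).
5. Bin the genome (500 kb / 5 Mb / 50 Mb), let each bin's most significant
   marker represent it, and pick the (bin size, top-bin count ∈ 10..100)
   pair maximizing the restricted log-likelihood of `y = μ + u + e` with
   `Var(u) = 2Kσa²`, K from the candidate pseudo QTNs (low-rank spectral
   evaluation, linear in n). The set size is capped at `n / log10(n)`.
6. Prune candidates whose dosage columns have |Pearson r| > 0.7 with a more
   significant kept candidate.
7. Repeat from step 2 until no new pseudo QTNs appear or the iteration
   budget is exhausted.

## CLI

```bash
# generate a synthetic dataset with planted QTNs
farmscan simulate --n 500 --m 3000 --n-qtn 10 --heritability 0.7 \
    --seed 1 --out sim

# run the iterative scan
farmscan run --geno sim.geno.tsv --map sim.map.tsv --pheno sim.pheno.tsv \
    [--covar covar.tsv] [--maf 0.05] [--threshold 0.01] [--max-iter 10] \
    [--bin-sizes 5e5,5e6,5e7] [--bin-counts 10:100:10] [--substitution min] \
    [--ld-prune 0.7] [--qtn-threshold 0.01] [--seed-qtns ids.txt] \
    --out results

# score one or more scans against the simulation truth
farmscan evaluate --assoc results.assoc.tsv --truth sim.truth.tsv \
    --window 50000 --out curves.tsv
```

`run` writes `<prefix>.assoc.tsv` (per-marker effect, se, t, P,
pseudo-QTN flag), `<prefix>.pseudoqtns.tsv` (per-iteration trace) and
`<prefix>.log` (run metadata).

File formats are plain delimited text: genotypes as samples x markers
dosage tables (0/1/2, fractional allowed, `NA` missing), a
`marker_id / chrom / pos` map, two-column phenotypes, and covariate tables
with a header row.

## Library use

```python
import farmscan as fs

genotypes = fs.generate_fixture_genotypes(500, 3000, seed=1)
phenotype, truth = fs.simulate_phenotype(
    genotypes, fs.SimulationConfig(n_qtn=10, heritability=0.7, seed=2)
)
result = fs.run_farmcpu(genotypes, phenotype, config=fs.RunConfig())
hits = fs.classify_hits(result.scan, truth, threshold=0.01 / genotypes.n_markers)
```

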