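# phylopop

Population-divergence analysis of short mitochondrial DNA alignments, built
for the classic phylogeographic question: are two regional samples of a
widespread marine species one connected population, or two isolated ones?
The motivating system is the pronghorn spiny lobster (*Panulirus
penicillatus*), whose Eastern Pacific and Central/Western Pacific samples are
separated by the East Pacific Barrier; the toolkit applies to any
two-population mtDNA survey of the same shape (a few hundred bp of COI or 16S
rDNA, tens of individuals, locality labels).

From an aligned FASTA file — or directly from a published polymorphic-site
haplotype table in dot notation — `phylopop` computes:

- **Haplotype statistics**: collapsing identical sequences, counts per
  population, and Nei's unbiased haplotype diversity
  *h = n(1 − Σ pᵢ²)/(n − 1)*;
- **Site classification**: variable columns, indel columns, and
  parsimony-informative columns (≥2 states each carried by ≥2 individuals);
- **Diagnostic substitutions**: fixed differences (columns where the two
  populations share no state) and nearly fixed differences (diagnostic after
  excusing at most *t* exception individuals);
- **Kimura two-parameter distances** with pairwise deletion of gap/ambiguous
  columns, *d = −½ ln[(1 − 2P − Q)√(1 − 2Q)]*, with within/between-group
  means and site-bootstrap standard errors;
- **Neighbor-joining trees** (Saitou–Nei, Studier–Keppler criterion) with
  nonparametric bootstrap supports and monophyly tests, written as Newick;
- **Molecular-clock dating** from an isthmian calibration: a rate
  *r = d_cal/T_cal* of total pairwise divergence per MY, and a split age
  *T = d_obs/r*;
- **A matching simulator**: two populations diverged for time *T* under an
  exact continuous-time K2P process with transition bias, plus
  within-population polymorphism, for end-to-end validation and
  parameter-recovery experiments.

## Worked example

The package ships a transcription of a published 16S rDNA polymorphic-site
table (14 haplotypes over 17 variable columns of a 535 bp fragment, observed
in 20 lobsters from 8 Pacific localities) as
`src/phylopop/fixtures/table3_16s.tsv`, with the locality→population map in
`groups_16s.tsv`. Running the full pipeline:

```python
from importlib.resources import files
import phylopop as pp

fx = files("phylopop") / "fixtures"
config = pp.RunConfig(
    table=str(fx / "table3_16s.tsv"),
    groups=str(fx / "groups_16s.tsv"),
    outdir="out", bootstrap=1000, seed=0,
    d_cal=12.4, T_cal=3.1,   # isthmian COI calibration, % and MY
    d_obs=3.8,               # observed COI between-group distance, %
)
results = pp.run_all(config)
print(results["summary_table"].to_string(index=False))
```

prints:

```
                   quantity value
              n_individuals    20
           alignment_length   535
               n_haplotypes    14
         n_haplotypes_CP+WP    11
            n_haplotypes_EP     3
        haplotype_diversity 0.937
             variable_sites    17
                indel_sites     1
parsimony_informative_sites     8
          fixed_differences     4
   nearly_fixed_differences     1
       mean_K2P_between_pct   1.0
  mean_K2P_within_CP+WP_pct   0.5
     mean_K2P_within_EP_pct   0.1
            monophyly_CP+WP  True
    split_bootstrap_support  97.0
          clock_rate_per_MY     4
         divergence_time_MY  0.95
```

Reading: the 7 Eastern Pacific (EP) and 13 Central/Western Pacific (CP+WP)
individuals share no haplotype; mean K2P divergence between the regions
(1.0%) is several-fold larger than within either (0.1%, 0.5%); the NJ tree
splits the regions into reciprocally monophyletic clades with ~97% bootstrap
support; and a 4%/MY isthmian rate dates the 3.8% COI divergence at 0.95 MY
— consistent with long-term isolation across the East Pacific Barrier.

The same stages are available as CLI subcommands (`phylopop haplotypes |
sites | diagnostic | distances | njtree | clock | simulate | run`), e.g.

```sh
phylopop distances --table table3_16s.tsv --groups groups_16s.tsv \
    --mode between --percent
# between  EP vs CP+WP  91 pairs  1.0291 ± 0.3934 %
```

## Layout

- `src/phylopop/io.py` — FASTA and haplotype-table I/O, table expansion
- `src/phylopop/haplotypes.py` — haplotypes, site classes, diversity, diagnostics
- `src/phylopop/distances.py` — K2P, distance matrices, group means, bootstrap SEs
- `src/phylopop/njtree.py` — NJ, bootstrap supports, Newick, monophyly, rooting
- `src/phylopop/clock.py` — calibration and divergence dating
- `src/phylopop/simulate.py` — two-population K2P simulator, recovery experiments
- `src/phylopop/pipeline.py`, `cli.py` — end-to-end runs and the `phylopop` CLI

See `docs/methods.md` for the models, conventions and known limitations.
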