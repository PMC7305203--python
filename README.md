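# phasekit

Detection of compound heterozygotes (two variant alleles in trans at one
locus) in population-phased and family cohorts, with the downstream
statistics used to interpret them: case/control enrichment (two-sided
Fisher exact, Yates-corrected chi-square, rounded frequency ratios),
Mendelian segregation expectation and depletion tests for intercross
litters, per-column conservation scoring of protein alignments, and a
ground-truthed synthetic-cohort generator so every stage is testable
without external downloads.

## Modules

| module | purpose |
| --- | --- |
| `phasekit.io_formats` | GT-only VCF v4.x, 6+ column PED, aligned FASTA |
| `phasekit.transcript_annotation` | isoform-aware SNV consequences, domain classification |
| `phasekit.comphet` | cis/trans phasing (population `\|` phase, trio enumeration, diploidy-forced hom-trans) and individual-level counting |
| `phasekit.enrichment_stats` | 2x2 Fisher exact (log-space hypergeometric), Yates chi-square, MAF, ratio labels |
| `phasekit.segregation` | expected counts under a cross ratio (half-to-even rounding), goodness-of-fit, exact binomial depletion tails |
| `phasekit.conservation` | sequence-logo information content, reference mapping, PDB B-factor projection |
| `phasekit.synthetic_cohorts` | haplotype-pool population/trio/case-control/intercross simulators with ground truth |
| `phasekit.cli` | `phasekit` command-line entry points and the pipeline driver |

## CLI

```sh
# simulate cohorts with known truth (seed is stamped into every output)
phasekit simulate --config sim.cfg --out simdir/

# classify compound heterozygotes
phasekit comphet --vcf cohort.vcf --ped cohort.ped --sites 16:1000,16:2000

# enrichment statistics from individual-level counts
phasekit enrich --cases 3/128 --controls 2/2504

# segregation expectation and fit for an intercross litter column
phasekit segregate --observed 58,70,28 --ratio 1:2:1

# conservation track from an aligned FASTA, optionally onto a structure
phasekit conserve --alignment msa.fa --reference ref_id \
    --pdb model.pdb --chain A --pdb-out scored.pdb

# end-to-end: comphet counting on both cohorts, then the enrichment row
phasekit pipeline --case-vcf cases.vcf --control-vcf controls.vcf \
    --sites 16:1000,16:2000,16:3000 --out report/
```

Exit codes: 0 success, 2 validation error, 1 runtime error. A `sim.cfg`
is flat `key = value` text, e.g.

```
seed = 7
n_cases = 128
n_controls = 2504
mafs = 0.01,0.01,0.01
enrichment_rho = 29
```

## Conventions worth knowing

- VCF positions are 1-based at the boundary; all internal interval
  arithmetic is 0-based half-open. Phase flags come solely from the
  `|` / `/` GT separator.
- Compound-het counting is individual-level; hom-alt plus het counts as
  trans (diploidy forces one alt per haplotype) but is flagged
  `hom_trans` so the stricter tally is recoverable
  (`include_hom_trans=False`).
- Ambiguous pairs never enter the numerator but their carriers stay in
  the denominator.
- Expected segregation counts round half-to-even; frequency-ratio
  labels round half away from zero.
- Only SNVs get protein consequences; anything else raises an explicit
  unsupported-variant error.
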