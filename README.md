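# fgfr2axis

Integrated copy-number, promoter-methylation and splice-isoform analysis
of *FGFR2* and its splicing regulator *ESRP1* in gastric cancer cohorts.

*FGFR2* encodes two mutually exclusive splice isoforms — epithelial
FGFR2-IIIb and mesenchymal FGFR2-IIIc — whose balance is controlled by
the epithelial splicing regulatory protein 1 (*ESRP1*). In gastric
tumors, amplification and promoter demethylation of both loci reshape
this balance, and IIIc expression above the normal-stomach median marks a
poor-prognosis subgroup of diffuse-type tumors. `fgfr2axis` implements
the full analysis chain for anyone working with TCGA-style or in-house
gastric cancer multi-omics:

- **Copy number** — per-gene calls from SNP-array segment means
  (amplified > 0.1, deleted < −0.1, normal in between, with
  probe-concordance filtering) or from gene-level GISTIC 2.0 integers.
- **Promoter methylation** — mean promoter beta-value classification
  (demethylated ≤ 0.33 ≤ hemimethylated ≤ 0.66 ≤ methylated) and paired
  tumor/normal RRBS methylated-CpG ratios (hyper ≥ 1.5, hypo ≤ 0.66).
- **Isoform-surrogate expression** — RPKM of the IIIb-specific exon
  (NM_022970 exon 8) and IIIc-specific exon (NM_001144916 exon 6),
  dichotomized against normal-median thresholds, plus 2^−ΔΔCt qRT-PCR
  quantification and tumor/normal ratio categories.
- **Integration** — per-tumor joined states and the
  ESRP1^amp^–FGFR2^norm^–FGFR2-IIIc^high^ axis flag.
- **Association & survival** — chi-square contingency layer
  (Yates-corrected for 2×2), Wilcoxon/t tests for continuous contrasts,
  Kaplan–Meier curves and overall/pairwise log-rank tests.
- **Synthetic cohorts** — a seeded generator that writes paired
  tumor/normal segment, GISTIC, beta-value, RRBS, expression and clinical
  TSVs with a latent truth table, so the entire pipeline runs and
  validates offline.

See `docs/methods.md` for the statistical model, every threshold, and the
generator's design.

## Worked example

```sh
fgfr2axis simulate --out demo --seed 5
fgfr2axis cnv --seg demo/segments.tsv --derive-cutoff --out demo/cn.tsv
fgfr2axis methylation --betas demo/beta_values.tsv --manifest demo/probe_manifest.tsv --out demo/meth.tsv
fgfr2axis expression --table demo/expression.tsv --out demo/expr.tsv
fgfr2axis integrate --cn demo/cn.tsv --meth demo/meth.tsv --expr demo/expr.tsv \
    --clinical demo/clinical.tsv --out demo/states.tsv
fgfr2axis survive --states demo/states.tsv --group lauren --split iiic_cat
```

The simulated cohort (27 pairs + 311 unpaired tumors by default) carries
a hazard ratio of 2 for diffuse-histotype tumors with above-median IIIc;
the survival command recovers exactly that contrast:

```
overall log-rank chi-square = 14.35, df = 5, p = 0.0136
         group_a          group_b  statistic  p_value
   Diffuse/above    Diffuse/below   9.053302 0.002622
   Diffuse/above Intestinal/above   5.798593 0.016039
   Diffuse/above Intestinal/below   6.878629 0.008723
   ...
```

The diffuse/IIIc-above arm separates from every other arm, while e.g. the
intestinal above-vs-below comparison does not — the injected biology, read
back out by the pipeline. (`cnv --derive-cutoff` printed
`derived segment-mean cutoff: 0.05`: the generator's normal-tissue noise,
sd 0.02, needs only half the default ±0.1 cutoff.)

The same library surface is available in Python
(`simulate_cohort`, `run_on_cohort`, `recover_truth`,
`fgfr2axis.stats.build_table1`, ...); `fgfr2axis.reference` carries the
published 198-tumor association tables as fixed inputs, e.g.

```python
>>> from fgfr2axis.reference import LAUREN_BY_ESRP1
>>> from fgfr2axis.stats import contingency_test
>>> contingency_test(LAUREN_BY_ESRP1).p_value
3.135474868803254e-10
```

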