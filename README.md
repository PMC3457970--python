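# metkinsig

Kinetic expression signatures, anchored protein-interaction pathways and
survival stratification for receptor-activity cell models.

## The problem

A receptor tyrosine kinase (the motivating case is the Met/HGF-SF axis in
breast cancer) is stimulated in a panel of cell lines with high and low
receptor activity, and genome-wide expression is measured over a short time
course (0, 10, 30 minutes and 24 hours). `metkinsig` implements the full
downstream analysis:

1. **Kinetic signature derivation.** Per gene and post-baseline time point,
   a paired two-sided t-test of within-cell-line log-ratios against zero,
   pooled over cell lines, with Benjamini-Hochberg FDR per time point
   (default threshold q ≤ 1e-4). Responders are partitioned into six groups
   by the time and direction of their initial response
   ({up, down} × {10, 30, 1440} min); each group's genes are used to
   cluster all samples (1 − Pearson distance, average linkage, two-cluster
   cut) and the split is scored against the high/low labels with a
   two-sided Fisher exact test. The group that best separates the
   receptor-activity classes is the *kinetic signature*.
2. **Whole-pathway expression scoring.** A gene set's score in a sample is
   the mean of the member genes' z-scores (per-gene normalization to mean
   0, sd 1 within each dataset).
3. **Patient stratification and survival.** Patients are clustered on the
   signature into two groups; the group with the higher canonical-pathway
   score is labelled `HighSig`. Kaplan-Meier / log-rank, Cox proportional
   hazards, chi-square / Welch phenotype associations, PPV/NPV against
   good/bad prognosis (bad = disease death or metastasis during follow-up;
   good = event-free with ≥ 5 years of follow-up).
4. **Anchored pathway inference.** On a confidence-weighted PPI graph the
   receptor (anchor) is connected to each signature gene by the
   maximum-confidence path (edge weight −ln confidence, deterministic
   Dijkstra; manual directionality overrides and node removals are
   configuration). Pathways contiguously contained in another drop the
   longer chain. Each pathway gets a differentiation p (high vs low
   samples), per-cohort good-vs-bad prognosis p-values, a *prognosis
   ranking* (log10 of the worst p across cohorts), and a *coherency*
   (mean Pearson correlation of consecutive gene pairs on per-gene,
   per-cell-line z-normalized cell-model data); coherency and prognosis
   ranking are compared by Spearman correlation.
5. **Null models.** Size-matched random signatures, randomized anchored
   networks, the 95%-of-null significance rule, rank of the real signature
   among random ones (worst log-rank p across cohorts), and upper-tail
   hypergeometric annotation enrichment with BH correction.
6. **Synthetic data.** Generators for every input — cell-model time course
   with planted response groups and a planted high/low contrast, PPI
   graphs with planted anchor paths, patient cohorts with
   proportional-hazards survival tied to the signature score, and an mRNA
   half-life table with a shorter-lived signature — each with ground-truth
   sidecars, so the entire pipeline is testable without external data.

## Worked example

```python
import metkinsig as mk

cfg = mk.SimulationConfig(seed=1)            # 2000 genes, 131-gene planted signature
matrix, truth = mk.simulate_cell_model(cfg)
results = mk.derive_signature(matrix)        # KineticSignatureModel(...).fit()
print(results.summary())
```

```
Kinetic signature derivation
============================================================
genes tested:        2000
responders (q<=0.0001): 255

           n_genes  separation_p  perfect_separation
group
down@10        129       6.2e-14                True
down@30         27       6.5e-06               False
down@1440       25             1               False
up@10           24         0.371               False
up@30           26         0.564               False
up@1440         24         0.556               False

selected signature:  down@10 (129 genes, separation p = 6.2e-14)
```

The planted world has 131 genes down-regulated at 10 minutes that also
carry a high-vs-low baseline contrast; the derivation recovers 129 of them
and only that group splits the 48 samples perfectly (Fisher p = 2/C(48,24)
≈ 6.2e-14). Continuing with network inference and a simulated cohort:

```python
ppi, _ = mk.simulate_ppi(cfg, "MET", sorted(results.signature.genes))
net = mk.AnchoredNetworkModel(ppi, "MET", sorted(results.signature.genes)).fit()
net.attach_differentiation(matrix)
print(net.summary())
```

```
Anchored network inference
============================================================
anchor:              MET
terminals requested: 129
pathways inferred:   129 (containment-pruned)
terminals left out:  0
subnetwork size:     361 nodes / 360 edges
differentiating pathways (p<0.05): 106/129
```

106 of 129 anchored pathways differentiate high- from low-activity samples
— far above the ~5% null expectation, because the planted paths end at
signature genes. On a simulated 300-patient cohort (hazard coefficient 1.0),
stratification gives `HighSig n=157, LowSig n=143`, log-rank
χ² = 78.98 (p ≈ 6e-19), PPV 0.93 / NPV 0.46; the simulated half-life table
reproduces the shorter signature half-life (7.52±2.89 h vs 9.87±5.37 h,
Welch p ≈ 2e-14).

## Command line

```bash
metkinsig simulate  --config cfg.yaml --seed 3 --out sim/
metkinsig derive-signature --expr sim/cell_expression.tsv --meta sim/cell_samples.tsv --out sig/
metkinsig score     --expr sim/cell_expression.tsv --geneset sig/signature_genes.txt --out scores.tsv
metkinsig stratify  --expr sim/cohort_expression.tsv --clinical sim/cohort_clinical.tsv \
                    --signature sig/signature_genes.txt --out strat/
metkinsig survival  --labels strat/labels.tsv --clinical sim/cohort_clinical.tsv --out surv/
metkinsig network   --ppi sim/ppi_edges.tsv --anchor MET --terminals sig/signature_genes.txt \
                    --expr sim/cell_expression.tsv --meta sim/cell_samples.tsv --out net/
metkinsig run       --config pipeline.yaml --seed 5 --out run/   # full pipeline + manifest
```

All intermediates are flat TSV/SIF; `run` writes a `manifest.json` with
parameters, seeds and SHA-256 hashes of every output, and reruns with the
same config are byte-identical.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the null calibration of
the pathway-differentiation rate: it simulates cell models with no
high/low group effect, infers anchored pathways from size-matched random
signatures over simulated PPI graphs, t-tests every pathway's expression
score between the two label-only sample groups, and reports the
percentage significant at α = 0.05 (the random expectation that a real
network model is judged against):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical model, conventions,
synthetic-data assumptions and known limitations.
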