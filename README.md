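# lungsig

Genomic-signature analysis for whole-genome-sequenced NSCLC cohorts.

Lung tumors accumulate somatic alterations whose patterns record the
mutagenic processes at work: APOBEC activity, tobacco carcinogens, and —
prominently in East-Asian, never-smoker adenocarcinoma — a diffuse process
associated with inflammatory tumor-infiltrating lymphocytes and *EGFR*
mutations. `lungsig` implements the cohort analysis that quantifies these
processes from somatic SNVs and structural rearrangements, aimed at
analysts working with per-sample VCF + BEDPE call sets and cohort
phenotype tables.

## What it computes

**Mutational signatures.** Somatic SNVs are collapsed onto the pyrimidine
strand and counted into the 96 trinucleotide channels (6 substitution
classes × 16 flanking contexts), giving a catalog **M** (96 × samples).
`lungsig` factorizes **M ≈ W H** by non-negative matrix factorization
under the generalized Kullback–Leibler divergence (the Poisson likelihood
for count data), with multiplicative updates and best-of-restarts. Columns
of **W** are signature profiles (probability over channels); columns of
**H** are per-sample exposures (mutations attributed). The factorization
rank is selected by restart stability: the largest rank whose signatures
are all reproducible across restarts (mean matched cosine ≥ 0.9) and
mutually distinct. A sample is *dominant* for a signature when that
signature's share of its exposures strictly exceeds 0.5.

**Rearrangement signatures.** Intra-chromosomal rearrangements
(deletion / duplication / inversion) are sub-classified by segment size
(1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, >10 Mb) into a 15-category
catalog and decomposed with the same NMF. Each event is attributed to the
signature *s* maximizing the posterior ∝ P(category | s) · exposure(sample, s),
assigned only when that posterior exceeds 0.5.

**Breakpoint hotspots.** Both ends of every rearrangement are breakpoints;
each gets an inter-rearrangement distance (IMD) to its predecessor on the
sorted chromosome. Piecewise-constant fitting — the exact dynamic-program
minimizer of Σ SSE + γ·(#segments) with segments of at least k_min
breakpoints (defaults γ = 8, k_min = 8) — segments log10(IMD). A segment
is a hotspot when its breakpoint density is at least twice the genome-wide
level (mean IMD ≤ half the genome-wide mean) and its breakpoint count
exceeds the expectation of a negative-binomial background regression over
0.5-Mb genomic bins with z-normalized feature tracks:

    b_i = exp(m + Σ_k w_k f_ik)

**Cohort statistics.** Cochran–Armitage trend tests of driver-mutation
status over exposure deciles, Fisher's exact test with the
conditional-MLE odds ratio, Wilcoxon rank-sum, Spearman (partial) rank
correlation, Benjamini–Hochberg FDR, and the SPM cell-type specificity
score (SPM_t = x_t / ‖x‖₂, with SPM > 0.9 defining type-specific genes).

**Synthetic cohorts.** `lungsig.simulate` generates complete cohorts with
known ground truth — reference FASTA, per-sample VCFs drawn from signature
mixtures, BEDPE rearrangements with a size split around 1 Mb, breakpoint
backgrounds with planted hotspot clusters, and phenotypes coupled to
exposures — so every stage is testable without access-controlled data.

## Worked example

```python
import numpy as np
from lungsig.simulate import default_ms_profiles, draw_exposures, simulate_catalog
from lungsig.signatures import extract_signatures, match_signatures, dominance_labels

truth = default_ms_profiles()                    # 96 x 3 ground-truth profiles
rng = np.random.default_rng(1)
exposures = draw_exposures(rng, n_samples=92, events_per_sample=2000)
catalog = simulate_catalog(truth, exposures, seed=2)   # 96 x 92 counts

model = extract_signatures(catalog, rank=3, restarts=5, seed=0)
model.signature_names = ["MS1", "MS2", "MS3"]
for i, j, cos in match_signatures(truth, model.profiles):
    r = np.corrcoef(exposures[:, i], model.exposures[j])[0, 1]
    print(f"signature {i + 1}: cosine to truth = {cos:.4f}, exposure r = {r:.4f}")
print(dominance_labels(model).value_counts().to_dict())
```

prints

```
signature 1: cosine to truth = 0.9993, exposure r = 0.9996
signature 2: cosine to truth = 0.9993, exposure r = 0.9971
signature 3: cosine to truth = 0.9951, exposure r = 0.9950
{'MS1': 29, 'MS3': 25, 'MS2': 24, 'none': 14}
```

Each extracted signature matches its generating profile (cosine ≥ 0.995)
and its per-sample exposures track the truth (r ≥ 0.995); 25/92 samples
(27%) are dominated by the diffuse third signature, with 14 samples having
no signature above the 0.5 contribution threshold.

The fusion-enrichment check from printed cohort counts — 6 fusion carriers
among 90 patients with expression data, 3 of them in the 10-patient top
decile of the diffuse signature's contribution:

```python
from lungsig.stats import ContingencyTable2x2, fisher_exact
odds_ratio, p = fisher_exact(ContingencyTable2x2(3, 7, 3, 77))
# -> OR = 10.43, p = 0.017 (reported as 0.02)
```

A command-line interface mirrors the stages
(`lungsig simulate | catalog | signatures | rearr | hotspots | stats | run-all`);
see `lungsig --help`.

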