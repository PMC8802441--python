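# codefactors

Matched case-control screening of diagnosis codes and factor-based
phenotyping of injury events, with sex-difference correlation analysis.

Given a 1:1 matched cohort (cases and references matched on sex, age,
rurality, and income quintile) and a long-format table of dated ICD-style
diagnosis codes, the pipeline:

1. derives index dates (cases: first case-coded visit; references: visit
   midpoint) and detects the **event window** from the visit-offset
   histogram (peak at the index date, settling to baseline);
2. **binarizes** three-character code categories over the window
   (provisional categories U98/U99 excluded);
3. screens every code with a **matched McNemar test**, controls the FDR
   with the **Benjamini–Yekutieli** step-up procedure (harmonic-sum
   constant), filters on matched odds ratio > 1, and retains only codes
   surviving in both the training and validation splits;
4. builds **factor phenotypes** by principal-components decomposition of
   the retained-code correlation matrix (factor membership at the 0.2
   absolute-loading cutoff; binary any-of factor scores);
5. designates each factor as **host / agent / environment** (or a
   combination) from an editable code-prefix map;
6. estimates per-factor odds ratios with **conditional logistic
   regression** for 1:1 pairs (with covariate adjustment and matched
   concordance AUC);
7. compares factor correlation structure between sexes with **Fisher
   z-tests** (within-sex and female-minus-male families, BY-masked), and
8. clusters factors with **Ward linkage** on correlation distance for
   heatmap and word-cloud exports.

A synthetic cohort generator with planted ground truth (latent factor
blocks, case-vs-reference odds ratios, sex-specific between-factor
correlations via a Gaussian copula, and index-date-peaked visit
histograms) makes every stage testable without restricted data.

## CLI walkthrough

```bash
# generate a synthetic fixture (see tests/test_cli.py for a config example)
codefactors simulate --config config.yaml --out fixture/ --seed 1

# detect the event window from the visit-offset histogram
codefactors window --patients fixture/patients.csv --visits fixture/visits.csv

# binarize codes over the window
codefactors binarize --patients fixture/patients.csv --visits fixture/visits.csv \
    --out matrix/ --window-before 30 --window-after 30

# McNemar + BY + OR screening over a pair-preserving train/validation split
codefactors screen --patients fixture/patients.csv --matrix matrix/ \
    --out screen.csv --q 0.05

# factor phenotypes from the retained codes
codefactors factors --matrix matrix/ --codes retained.txt \
    --out factors.json --n-factors auto --criteria kaiser,scree_breakpoint

# Haddon designation, per-factor conditional-logistic ORs, sex differences
codefactors designate --factors factors.json
codefactors associate --patients fixture/patients.csv --matrix matrix/ \
    --factors factors.json --out fits.csv
codefactors sexdiff --patients fixture/patients.csv --matrix matrix/ \
    --factors factors.json --out sexdiff/

# Ward-ordered heatmap export and word-cloud weight tables
codefactors cluster --corr sexdiff/masked_F.csv --out heatmap/
codefactors report --patients fixture/patients.csv --matrix matrix/ \
    --factors factors.json --fits fits.csv --out weights/
```

## Layout

| module                    | contents                                                  |
| ------------------------- | --------------------------------------------------------- |
| `codefactors.synthetic`   | cohort generator, ground truth, visit-offset shapes       |
| `codefactors.cohort`      | data model, index dates, window detection, binarization, splits |
| `codefactors.screening`   | discordant counts, McNemar, BY procedure, dual-set screen |
| `codefactors.factors`     | PCA factor model, factor-count criteria, definitions, scoring |
| `codefactors.haddon`      | host/agent/environment designation maps                   |
| `codefactors.association` | 1:1 conditional logistic regression, matched AUC          |
| `codefactors.sexdiff`     | phi matrices, Fisher z machinery, FDR masking             |
| `codefactors.structure`   | Ward linkage, cause/severity profiles, heatmap/word-cloud exports |
| `codefactors.experiments` | simulation experiments behind the acceptance checks       |
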