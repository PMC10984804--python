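# xtissue

Cross-tissue co-expression network communities and their statistics: a
pipeline for asking whether exercise (or any paired intervention) regulates
shared transcriptional programs *differently* in skeletal muscle (SM) and
subcutaneous adipose tissue (SAT), and whether those programs track clinical
traits.

The analysis flow, for transcriptomicists and exercise-physiology groups
with paired two-tissue designs:

1. **Preprocess** — TMM normalization, log2CPM, expression filtering
   (mean log2CPM >= 4), optional protein-evidence filtering, and candidate
   intersection across datasets and tissues.
2. **Shared network** — per-tissue gene-pair edges (Pearson r > 0.30 at
   Benjamini–Hochberg FDR < 1%), intersected across tissues with sign
   concordance, then partitioned into communities with the Louvain
   modularity algorithm.
3. **Exercise statistics** — each community is summarized by its
   *eigengene* (first principal component of standardized member-gene
   expression) and tested with a fully within-subject 2x2 repeated-measures
   ANOVA in the form Time x Tissue; a significant interaction with
   opposite-sign per-tissue fold changes flags tissue-discordant regulation.
4. **Trait models** — Pearson correlation of eigengenes with clinical
   traits, plus OPLS regression (continuous traits) and OPLS-DA (binary
   traits) of community expression with VIP scores, Monte-Carlo
   cross-validated Q², a permutation q-value, and AUROC.

A synthetic-cohort generator (`xtissue.simulate`) stands in for the
controlled-access cohorts such designs rely on: it plants known community
structure, tissue-discordant time effects and trait links on a
negative-binomial count model, so every downstream stage can be scored
against ground truth.  See `docs/methods.md` for the model and all
statistical conventions.

## Worked example

The numbered drivers under `analysis/` run the full synthetic study
(seed 1) and write their tables under `results/`:

```
python analysis/01_simulate_cohorts.py 1
python analysis/02_preprocess.py
python analysis/03_build_network.py 1
python analysis/04_exercise_interaction.py
python analysis/05_trait_models.py 1
```

Step 3 builds the shared network and recovers the planted communities:

```
SM: 60395 edges of 12457536 tested pairs
SAT: 60859 edges of 12457536 tested pairs
shared network: 802 genes, 60133 edges, mean r = 0.40
Louvain: 8 communities, modularity Q = 0.702
recovery of planted communities: ARI = 1.000
```

All eight planted communities come back exactly (adjusted Rand index 1.0);
only genes with planted co-expression survive the edge intersection, so the
network has 802 nodes out of 5000 simulated genes.

Step 4 runs the Time x Tissue ANOVA per community (detected community 3 is
the planted discordant one: 147 genes shifted +0.8 SD in SM, -0.8 SD in SAT):

```
           n_genes   fc_sm    p_sm  fc_sat   p_sat  p_interaction
community
1              232  0.0330  0.4547  0.0430  0.1852         0.8276
2              178  0.0504  0.2283  0.0081  0.8243         0.3913
3              144  0.1063  0.0004 -0.0512  0.1342         0.0017
...
community 3: tissue-discordant regulation (fc_sm=+0.106, fc_sat=-0.051, interaction p=0.0017)
```

The eigengene rises in muscle and falls in adipose within the same 16
subjects — the discordance signature the pipeline is built to detect (the
weaker single-tissue shifts planted on other communities sit below the
power of a 16-subject design, as intended).  Step 5 then ties that
community to the traits (planted slope -1.0 on the BMI-like trait,
log-odds +2.0 on the T2D-like trait):

```
eigengene-trait correlations with p < 0.05 (pre-training SAT):
 community        trait       r      p  n
         3     bmi_like -0.7914 0.0003 16
         3     t2d_like  0.6491 0.0065 16
         1 fatmass_like  0.5368 0.0320 16

OPLS models for community 3 (144 genes), reference SAT:
  BMI-like: R2Y = 0.62, Q2 = 0.37, q-value = 0.000999, 71 genes with VIP > 1
  T2D-like (OPLS-DA): R2Y = 0.51, AUROC = 0.94 (142 cases / 258 controls)
```

A negative eigengene–BMI correlation with a cross-validated, permutation-
significant OPLS model, and class separation for the binary trait — the
planted clinical links, recovered end to end from counts.

The same machinery is scriptable (`xtissue --help`: `simulate`,
`preprocess`, `network`, `communities-test`, `opls`, `run`, `validate`) or
drivable from one YAML config via `xtissue run --config cfg.yaml`.

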