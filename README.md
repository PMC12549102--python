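# fetalcwas

Connectome-wide association analysis (CWAS) for resting-state fMRI
cohorts, built around multivariate distance matrix regression (MDMR) with
permutation inference, modularity-based community detection, and
network-pair enrichment of edge–behavior correlations. The package targets
the study design used in fetal/perinatal imaging — small cohorts (~59
scans), a fixed 100-ROI parcellation, short scans (~110 volumes at TR 3 s),
heavy motion — and ships a synthetic-cohort generator with planted ground
truth so every stage is testable without access to any imaging data.

## Who this is for

Researchers relating a continuous behavioral measure (here: maternal
anxiety, stress and depression questionnaires — SSAI, STAI, PSS, EPDS) to
whole-brain functional connectivity, when edge-wise mass-univariate testing
is underpowered and a multivariate, permutation-based approach is wanted.

## The method

For each scan, BOLD series from `n` ROIs are censored for motion
(frame-to-frame translation > 1 mm or rotation > 1.5° removes the volume
and its preceding frame; a MAD-based signal rule removes further volumes;
scans keep ≥ 4 minutes of data or are excluded), correlated pairwise
(Pearson), Fisher-z transformed, and vectorized into the
`C(n,2)`-dimensional edge vector (4950 edges for 100 ROIs).

Between-subject dissimilarity of connectivity profiles is measured with the
Manhattan (L1) distance, giving an `n_subjects × n_subjects` matrix `D`.
With Gower's double-centering `G = -½ C (D∘D) C`, `C = I − 11ᵀ/n`, and hat
matrix `H` of a design `X` (intercept + retained volumes + behavior
scores), MDMR tests

```
pseudo-F  = [tr(HGH)/m] / [tr((I−H)G(I−H))/(n−m−1)]
pseudo-R² = tr(HGH)/tr(G)
```

with significance from permutations: raw relabeling for the omnibus test
and Freedman–Lane residual permutation for per-factor tests, so each score
is tested conditional on the other covariates. When `D` is the Euclidean
distance on a univariate response this reduces *exactly* to classical
regression F/R² — the implementation's primary oracle (also cross-checked
against `vegan::adonis2`).

Significant associations are then localized: ROIs are partitioned into
modules by consensus signed-Leiden modularity maximization on the
group-average connectome; each edge is screened by the Pearson correlation
of its connectivity with the behavior score (two-tailed t test, p < .05);
and a one-sided 1-df χ² per network pair asks whether significant edges
concentrate in that pair beyond a uniform spread, with inference from a
null that re-runs the whole screen on permuted scores.

## A worked example

`examples/03_connectome_and_mdmr.py` simulates 59 scans of 30 ROIs with a
trait-anxiety (STAI) effect planted on 12 edges, censors motion, builds the
edge matrix and runs the covariate-adjusted MDMR:

```
edge matrix: 59 subjects x 435 edges (C(30,2) = 435)

whole-connectome MDMR:
            unit           factor  pseudo_F  pseudo_R2  p_perm  n_perm
whole_connectome          omnibus    1.4434     0.0730   0.001     999
whole_connectome retained_volumes    0.7315     0.0123   0.988     999
whole_connectome             ssai    1.1076     0.0187   0.194     999
whole_connectome             stai    2.4341     0.0410   0.001     999
```

The planted STAI effect is the only factor with a small conditional
permutation p; pseudo-R² is the share of distance variance it explains.
The other examples cover cohort simulation, motion QC, module detection
plus enrichment, and the end-to-end pipeline; each prints what its numbers
mean. A thin CLI mirrors the stages
(`fetalcwas simulate | qc | connect | mdmr | communities | enrich | report | all`).

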