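# Methods

## Scope and model

`cernet` infers circRNA-associated ceRNA networks from a small two-group
transcriptome design: circRNA and mRNA count matrices (RNA-seq), a miRNA
log-intensity matrix (microarray), FASTA sequences for DE features, GMT
annotation, and optionally qPCR Ct tables. The inference is a conjunction
of evidence — differential expression, sequence-level binding potential,
sign-constrained coexpression, and a shared-partner enrichment statistic —
rather than a single model fit. All thresholds live in `PipelineParams`
and are echoed into each run's manifest.

## Differential expression

Counts are normalized with median-of-ratios size factors: for sample *j*,
the median over all-nonzero features of count<sub>ij</sub> divided by the
feature's geometric mean, rescaled to geometric mean 1 (which makes the
estimator idempotent: re-estimating on the normalized matrix returns unit
factors). Values are transformed y = log2(x+1) and each feature is tested
with a two-sided **pooled-variance t-test** (Student); log2FC is the
difference of group means of y. Microarray intensities skip normalization
(any pre-normalized log2 table is accepted) and are tested the same way.

The pooled test was chosen over Welch deliberately: at three samples per
group the Welch–Satterthwaite degrees-of-freedom approximation is markedly
conservative (attained type-I error ≈ 0.033 at nominal 0.05 even on ideal
Gaussian nulls, measured directly), while the pooled test attains ≈ 0.048;
with one generative noise model per molecule class, equal group variances
are also the natural assumption. Degenerate features (zero variance in both
groups) get p = 1 with a log notice. BH q-values are computed per class;
the default filter is the study-wide |FC| ≥ 1.5 **and** raw p < 0.05 (the
boundary is inclusive, with a 1e-9 tolerance on log2(1.5) so an exactly
1.5-fold change passes), with `use_q` switching the significance clause to
q < α. This is an intentionally simple, documented stand-in for a
moderated count model: with n = 3 per group, dispersion shrinkage changes
little, and the package's contribution is downstream of this step.

## MRE prediction

Candidate sites are anchored by exact complementarity to miRNA seed
positions 2–7 (1-based), graded 6mer / 7mer-m8 (position 8 paired) /
7mer-A1 (target A opposite position 1) / 8mer. Coordinates are 0-based
half-open on the target, 5'→3'; the target base opposite miRNA position 1
sits at the 3' end of the site.

Each anchor, extended 30 nt toward the target 5' end (where miRNA
3'-supplementary pairing lands), is scored by an affine-gap Smith–Waterman
(Gotoh) alignment of the miRNA 3'→5' against the window: Watson–Crick +5,
G:U +2, mismatch −3, gap open −8, gap extend −2, and pair scores doubled
for the seed-proximal miRNA region. The doubled region is positions 1–8:
position 1 is included so that an 8-nt perfect duplex at the miRNA 5' end
scores exactly 8 × 5 × 2 = 80, keeping the weighting contiguous with the
A1 convention. A crude additive pair energy (GC −3, AU −2, G:U −1,
mismatch/gap +0.5 kcal/mol) stands in for nearest-neighbor thermodynamics —
it is a monotone stability filter, not a physical prediction; ViennaRNA
integration is out of scope. Sites are kept at score ≥ 140 and energy ≤
−20, defaults sized so that a full reverse-complement site of a 22-nt
miRNA (score ≥ 150, energy ≤ −44) always passes while chance seed matches
essentially never do; both are config. Sites collapse to (miRNA, target)
pairs carrying n_sites, best score and best energy.

circRNA targets are scanned as linear pseudo-sequences extended by their
first (miRNA length − 1) nt so backsplice-junction-spanning sites are
seen; coordinates are reported modulo the original length, and when a
junction site appears both clipped (near position 0) and complete (in the
extension), the best-scoring representative is kept.

The dynamic program is verified against an exhaustive search over monotone
chains of aligned pairs on ≤ 12-nt instances.

## Coexpression and network assembly

Pearson correlation is computed across all samples, both groups pooled
(the 3-vs-3 design leaves no power for per-group correlation), on
log-scale values; counts are size-factor normalized and log2(x+1)
transformed first. Edges must carry the sponge sign pattern —
miRNA–circRNA and miRNA–mRNA negative, circRNA–mRNA positive — with
|r| ≥ 0.9 and p < 0.05 (t-distribution, n−2 df). r_min = 0.9 is
approximately the |r| needed for p < 0.05 at n = 6; constant features
return (r = 0, p = 1) and never form edges.

Sequence pairs intersected with negative coexpression edges give
*validated pairs*. For every circRNA–mRNA combination, the **ceRNA score**
is the hypergeometric upper tail P(X ≥ k) of sharing k validated miRNA
partners given K (circRNA partners), n (mRNA partners) and the universe
M = all DE miRNAs — the standard shared-MRE sponge statistic. Candidates
need k ≥ 1 and p < 0.05 (BH q reported); those also present among positive
circRNA–mRNA edges expand into one triplet per shared miRNA, and a triplet
survives only if its directions are sponge-consistent (circRNA and mRNA
equal, miRNA opposite). All outputs are sorted lexicographically so files
are byte-stable; networks export as edge TSV, SIF (`sponges`, `targets`)
and GraphML with `cls` / `de_direction` node attributes.

## Enrichment and qPCR

Over-representation only (one-sided hypergeometric), fold enrichment
(k/n)/(K/N), BH across all terms tested, background = the GMT universe
(union of members unless an explicit universe is supplied; the enrichment
background of such studies is typically unstated, so it is left to the
caller). No GO DAG propagation — aspects are separate GMT files prepared
upstream. qPCR tables are reduced per gene: ΔCt = Ct_gene − Ct_ref per
sample, ΔΔCt = mean ΔCt(case) − mean ΔCt(control), fold change = 2^−ΔΔCt,
plus per-sample relative quantities calibrated to the control mean for
plotting/SEM. No amplification-efficiency correction.

## Synthetic data

The generator emulates the target study design, with defaults chosen once:

| parameter | default | meaning |
|---|---|---|
| n_case / n_control | 3 / 3 | animals per group |
| n_circ / n_mirna / n_mrna | 60 / 40 / 600 | features per class (desk scale, same ratios as a real DE table) |
| n_circuits × mirnas_per_circuit | 4 × 3 | planted sponge circuits; real circuits share several miRNAs, and k > 1 keeps the hypergeometric score stable |
| n_de_circ / n_de_mirna / n_de_mrna | 12 / 22 / 60 | total planted DE features incl. circuit members; the extra "decoys" (DE, no binding sites) give the DE-miRNA universe a realistic size M ≈ 22 |
| lfc_de | 1.5 | planted \|log2FC\| (0 allowed for null runs; otherwise ≥ log2 1.5) |
| nb_dispersion | 0.1 | NB α in Var = μ + αμ² |
| base_mean_log / base_sd_log | 8 / 1 | log2 baseline count distribution |
| intensity_sd | 0.25 | residual sd of log2 intensities |
| sponge_sd | 0.5 | sd (log2) of the per-sample latent sponge factor |
| size factors | log-uniform [0.7, 1.4] | library-size variation |
| seed_len / mirna_len | 7 / 22 | seed element length; mature miRNA length |

Counts are NB with group-specific means for DE features (±lfc/2 per
group); intensities are Gaussian in log2. Each circuit adds a shared
latent factor per sample (+ on circRNA and mRNA, − on its miRNAs), the
simplest mechanism producing all three required correlation signs at once;
circuit directions alternate so both sponge orientations occur. Circuit
targets carry the **full reverse complement** of each partner miRNA at a
recorded position — the seed-complement element required of a planted site
is a subsequence of it — because a seed-only 7-nt element (best score
≈ 70, energy ≥ −17.5 under the scoring constants above) cannot pass the
default thresholds, whereas a full-duplex site passes them
deterministically. `plant_site` is also provided for planting bare seed
elements. Everything planted is recorded in a `TruthTable`.

What the generator does **not** emulate: batch effects, isoform structure,
probe-level microarray artifacts, 3'UTR-specific sequence composition,
conservation, or expression-dependent dispersion trends. Passing tests on
synthetic data therefore demonstrate the pipeline's internal logic and
calibration, not performance on any particular real dataset.

## Calibration and the recovery ceiling

`cernet.evaluation` measures (and `scripts/acceptance.py` reports):

* **DE type-I error** on circuit-free, effect-free NB simulations
  (~0.047 at nominal 0.05 over 1500 features).
* **Enrichment null rate** for random queries (~0.04; a discrete one-sided
  test sits at or just under its nominal level).
* **Null specificity**: circuit-free simulations emit zero triplets in
  ~100% of seeds — the conjunction of sequence, correlation, score and
  direction filters makes spurious triplets vanishingly rare.
* **Planted-circuit recovery** at |log2FC| = 2 and default thresholds:
  ~25–35% of circuits per run. This ceiling is a property of the design,
  not of the implementation: with NB dispersion 0.1, each count feature
  carries irreducible log-scale noise (var ≈ 0.21) that caps the true
  circRNA–mRNA correlation near 0.87, while a retained edge needs sample
  r ≥ 0.9 at n = 6; strengthening the latent sponge factor raises the
  correlations but destroys the t-test's power at 3-vs-3 (within-group
  variance), so no parameterization makes both stages near-certain
  simultaneously. Recovered circuits are essentially always genuine
  (zero spurious circRNA–mRNA pairs across the Monte-Carlo runs); absent
  ones fail honestly at the DE or |r| ≥ 0.9 stage. A real study's printed
  cascade of counts should be read with the same asymmetry in mind: high
  precision, modest recall.

## Numerical choices and degenerate inputs

All scoring constants are exact multiples of 0.5, so DP traceback
comparisons are exact in floating point. Ties in alignment traceback
prefer diagonal moves; co-optimal alignments may differ in pairs but not
in score. The hypergeometric tail uses `scipy.stats.hypergeom.sf(k−1, …)`
and is verified against exhaustive enumeration for all universes ≤ 12.
Empty queries, empty gene sets, empty networks and constant features all
degrade to warnings plus empty/neutral results rather than errors; hard
errors are reserved for contract violations (duplicate ids, negative
counts, sample/design mismatches, out-of-range thresholds). Monte-Carlo
procedures derive all child seeds from one `SeedSequence`, so every
reported number is reproducible from a single integer seed. Problem sizes
used by the shipped checks (50-seed recovery, 100-seed null, 1500-feature
type-I, 200-replicate enrichment null) were fixed as the package's own
defaults for a laptop-scale validation run.
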