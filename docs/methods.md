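# Methods

This note documents the models, defaults and numerical choices behind
`mircoreg`, and what the synthetic-data generators do and do not emulate.

## Relative quantification (2^−ΔΔCt)

Ct is treated as a log2-abundance scale: one PCR cycle corresponds to one
doubling of template. Consequences baked into the implementation:

* The "geometric mean of the reference miRNAs" used for normalization is the
  arithmetic mean of their Ct values (geometric mean in linear-abundance
  space). Two reference miRNAs are the default, mirroring common TaqMan
  advanced-card designs.
* Replicate Cts are averaged arithmetically in Ct space after discarding
  undetected replicates. Detection means Ct < 40 cycles (the standard
  instrument cutoff). A target measurement requires at least 2 of 3 detected
  replicates; a reference requires at least 1 per sample (a sample missing a
  reference entirely is a hard error naming the sample). Undetected
  replicates are dropped, not imputed at the cutoff: imputation at Ct = 40
  biases ΔCt toward the censoring point, and at the panel's expression
  levels censoring is rare.
* The calibrator in RQ = 2^−ΔΔCt is the per-miRNA mean ΔCt of the control
  group (an explicit value or mapping is also accepted). With this choice
  the *geometric* mean RQ of the control group is exactly 1 per miRNA; the
  arithmetic mean equals 1 only for noise-free data. `DEResult.fc` always
  equals `2**log2fc` to machine precision, and equals the ratio of the group
  geometric-mean RQs.

Differential expression uses the two-sided Mann–Whitney U test on per-sample
RQ (equivalently ΔCt — the transform is strictly monotone, so U and p are
identical; only the orientation differs). The null is exact when the
combined sample size is ≤ 20 and tie-free, otherwise a normal approximation
with mid-rank tie correction and continuity correction. The headline
significance flag uses raw p < 0.05 (the convention for small confirmatory
panels); BH-adjusted p-values are always reported alongside so the stricter
criterion is available. miRNAs detected in only one group are excluded from
the test and from the BH family rather than assigned a pseudo-p.

Displayed fold changes are rounded to 3 significant figures
(`fold_change_display`).

## ROC analysis

Scores are per-sample RQs (any strictly increasing transform gives the same
AUC). AUC is computed as the tie-aware Mann–Whitney U divided by
n_case·n_control, oriented so that higher expression in cases gives
AUC > 0.5; the curve itself is evaluated at every observed threshold and its
trapezoidal area equals the U-based AUC to machine precision. The standard
error is Hanley–McNeil; the p-value is a two-sided z-test of AUC = 0.5
(MedCalc's default family), with an exact label-permutation alternative
(`method="permutation"`) for small samples. Degenerate inputs: all-tied
scores give AUC 0.5 with p = 1; perfectly separated groups give SE 0, where
the normal p is reported as 0 (the permutation method gives the honest
small-sample value). No optimal-cutoff (Youden) selection is performed.

## Target integration

Identifiers are normalized before any set operation: gene symbols
upper-cased; miRNA names to miRBase-style `miR-…`/`let-…` forms with the
mature-arm suffix (-5p/-3p) kept significant. Pairs are counted at the
(miRNA, gene-symbol) level, collapsing transcript isoforms. The consensus
rule keeps pairs predicted by ≥ 4 of the 5 tools; validated pairs pass an
evidence filter (substring match, default "reporter"). No per-source score
thresholds are applied beyond the consensus count. The
validated ∪ predicted union obeys inclusion–exclusion exactly (asserted at
run time), and a pair in both sets counts once with merged provenance.
`build_bipartite` can exclude miRNAs that share no target with any other
miRNA from the exported network (a common display convention) while keeping
them in the summary.

## Co-regulatory graph and motifs

Nodes are typed miRNA/TF/gene; an entity may hold both TF and gene roles
(e.g. a TF that is itself a miRNA target), and FFL gene slots may be filled
by such dual-role TFs. miRNA-outgoing edges are always repression; TF edges
carry TRRUST-style activation/repression/unknown signs, and conflicting
signs from different sources collapse to unknown with a warning. Motif
detection uses edge presence and direction only — sign never affects counts.
TF → miRNA evidence from multiple datasets is unioned at ≥ 1-source support.

Classification is a partition with composite precedence: a triple
(t, m, x), x ∉ {t, m}, with t → x and m → x is composite-FFL if t → m and
m → t, else TF-FFL if t → m, else miRNA-FFL if m → t. Hence per-kind counts
sum exactly to the FFL total, and every composite-FFL's (t, m) pair is also
a feedback loop (FBLs are all reciprocal TF ↔ miRNA pairs, including those
inside composites). Self-loops are excluded from motif slots. Degree reports
count incident unique directed edges (in + out) on the motif subgraph, with
lexicographic tie-breaking and a default hub list of 5. Motif counts and
edge counts are independent quantities; no counting convention ties them
together. GraphML exports round-trip losslessly (roles and provenance as
attributes); SIF uses activates/represses/regulates relation tokens.

## Over-representation analysis

The hypergeometric upper tail P(X ≥ k) with BH correction and a default
significance threshold of adjusted p < 0.05. The background defaults to the
union of all genes in the loaded GMT collection; query genes outside the
background are dropped with a warning. This is a generic ORA: it does not
reproduce any specific annotation service's EASE-modified statistic,
database snapshot or GO-graph propagation, so term lists from such services
are not comparable item-by-item.

## Synthetic-data generators

**Expression.** Ct noise is Gaussian in Ct space, matching qPCR error
structure (ΔΔCt arithmetic is linear in Ct). Per miRNA a stable abundance
offset (uniform on −3…+4 cycles around a 28-cycle base) sets its level; per
sample a shared technical offset (SD 1 cycle) emulates input-amount
variation and must cancel under reference normalization — the scale-
invariance property tests rely on this. Case samples have their Ct lowered
by the planted log2 fold change. Defaults emulate the study conditions the
package was built around: 58 case vs 20 control samples, a 13-miRNA panel
with six true effects (log2FC 0.58–0.92) and seven nulls, two reference
miRNAs, triplicate wells, replicate SD 0.25 cycles, censoring at Ct 40.
Not emulated: amplification-efficiency differences, plate-position effects,
inter-run batch structure, non-Gaussian outliers. Passing recovery tests
therefore shows correctness of the estimator arithmetic and calibration
under the stated noise model, not robustness to those real-data artefacts.

**Interaction databases.** Motifs are planted on disjoint TF/miRNA/gene
node sets, which makes cross-motif accidental motifs structurally
impossible; feasibility (enough nodes for the requested counts) is checked
up front. Every planted miRNA-target edge draws predictor support from the
configured coverage distribution (default: 4 or 5 of 5 tools, equally
likely) and/or a reporter-assay validation flag, so it survives the
downstream consensus filter unless explicitly overridden; overrides let
tests drop a pair below the threshold and verify that its motifs leave the
recomputed truth. Decoy edges of all kinds (TF→miRNA, TF→gene, and
miRNA→target at both surviving and sub-threshold support, plus non-reporter
"validated" rows) are rejection-sampled against incremental motif checks,
and the final edge set is re-verified by an exhaustive brute-force pair/
triple scan on every draw — the emitted truth list is exact by
construction *and* by verification. Defaults: 12 TFs, 10 miRNAs, 30 genes,
planted {FBL 2, miRNA-FFL 3, TF-FFL 4, composite-FFL 1} (the composite
contributes one further FBL pair), 40 decoys. Realistic genome-scale
database sizes are deliberately out of scope.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in the
configs; fixed seeds give bit-identical outputs. The test suite and the
acceptance script use simulation sizes chosen to make the statistical checks
sharp while staying light: 100 generator draws for exact motif recovery,
200 draws (n = 20/20, 0.3-cycle noise) for log2FC unbiasedness (|mean bias|
< 2·SE), 2000 replicates for the Mann–Whitney null rejection rate
(nominal 0.05, accepted band 0.035–0.065), and 50–100 draws for planted
enrichment detection. `scripts/acceptance.py --seed S --out F` recomputes
every reported quantity from scratch at these sizes.

## Known limitations

* The Mann–Whitney exact branch switches to the tie-corrected normal
  approximation whenever ties are present, even for tiny samples.
* The Hanley–McNeil z-test is anti-conservative for AUC near 1 with small
  n; use the permutation p there.
* `enrich` treats terms independently (no GO-graph propagation), and the
  hypergeometric model assumes genes are exchangeable within the background.
* Graph assembly trusts the supplied id namespaces after normalization; it
  does not resolve gene aliases or miRBase version renames.
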