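# Methods

## Model and rationale

The package screens a bait protein against a candidate panel by running one
heterodimer structure-prediction job per pair and reducing each job's
confidence outputs to a single scalar. A predictor of the AlphaFold-Multimer
family reports, per predicted model,

- **ipTM** ∈ [0, 1]: predicted TM-score of the inter-chain interface;
- **pTM** ∈ [0, 1]: predicted TM-score of the whole complex;
- **pLDDT** ∈ [0, 100] per residue: local fold confidence.

The predictor's own ranking statistic, the model confidence
`0.8·ipTM + 0.2·pTM`, is tuned for structure accuracy. For binding
*detection* its pTM term rewards well-folded chains regardless of whether
they touch. The screening score counteracts that:

```
AISIDscore = max_m [ 1.25 · (0.8·ipTM_m + 0.2·pTM_m) − 0.25 · avp_m ]
```

with `avp_m = mean(pLDDT_m) / 100` taken over **all** residues of both
chains, and the max over the job's models (25 for a stock heterodimer run).
Subtracting a quarter of the average fold confidence cancels the score
inflation that confidently folded but non-interacting chains would otherwise
receive; the 1.25 prefactor rescales so a model with avp equal to its
confidence keeps its confidence as its score. The score is bounded in
[−0.25, 1.25]; in practice a strong binder sits around 0.7–0.9 and a
non-binder well below 0.3.

**avp scale.** "Averaged percentage pLDDT" is stored as a fraction of 1, not
of 100. On the 0–100 scale the penalty term would dominate and drive every
score strongly negative, which is incompatible with the score range the
metric is designed to produce (roughly 0–0.9 on real screens); the fractional
reading is the only self-consistent one and is fixed throughout.

**avp residue set.** All residues of both chains, concatenated in file order,
with no per-chain weighting. Nothing interface-specific enters avp: it is a
fold-quality penalty, not an interface measure.

**Model count.** The max is taken over however many models the job produced.
Fewer than the nominal 25 is accepted with a warning — partial jobs happen in
production — never silently padded or rejected.

**Ties.** If several models share the maximum value, the lexicographically
smallest model id is reported as `best_model_id`; if several candidates share
an AISIDscore, ranking breaks ties by ascending ligand id. Both rules exist
only to make outputs order-independent and reproducible; published scores at
3-decimal precision do not tie in practice.

## Pipeline

1. **prepare** — one two-record composite FASTA per bait–ligand pair, bait
   first (fixed ordering; predictor symmetry is not assumed). Jobs are
   stably sorted by total residue count ascending: prediction wall time grows
   steeply with length, and running short jobs first keeps a small node pool
   saturated over a screening campaign. The hand-off is a TSV manifest
   (`job_id`, `composite_path`, `total_residues`, `output_root`); submission
   itself is site infrastructure and out of scope.
2. **predict** — external. Accessed only through an on-disk contract: a
   directory per job holding per-model records in one of two dialects.
   `confidence-json` is one JSON sidecar per model
   (`model_id`, `iptm`, `ptm`, `plddt[]`); `pdb-bfactor` is one PDB/mmCIF
   model per record with pLDDT in the CA atom's B-factor (first atom as
   fallback — the standard AlphaFold convention) plus a companion JSON for
   ipTM/pTM. Vendor binary archives are deliberately unsupported; the JSON
   schema is the contract a site's harvest glue emits.
3. **harvest & rank** — each job is read into validated per-model records,
   scored, and each bait's candidates ranked descending. Missing jobs are
   absent, never imputed as zero.
4. **report** — per-bait ranking tables; a baits × ligands score matrix (TSV
   at 3 decimals plus heatmap image on a fixed [0, 1] color scale so separate
   runs compare visually); top-k hit statistics and group means when a
   known-pair annotation table is supplied.

**Hit counting.** A bait with several known ligands contributes one rank
entry per annotated pair: three true ligands can occupy three top-5 seats.
This matches how multi-ligand receptor families are scored (33 true pairs
across 24 annotated baits in the motivating screen). The alternative —
counting only each bait's best-ranked true pair — is available via
`best_pair_only=True`. Baits without annotations are skipped from hit
statistics with a log line; group means over an empty subset are reported as
undefined (`None`), never 0.

## Synthetic data generator

`MockScreenSpec` + `generate_mock_outputs` fabricate predictor output trees
so the entire downstream pipeline runs without GPU, weights or databases.
Per model, ipTM is drawn from a truncated normal on [0, 1] — one
distribution for planted true pairs, one for decoys — pTM is the drawn ipTM
plus a fixed offset (clamped), and pLDDT is i.i.d. truncated normal on
[0, 100] per residue, rounded to 2 decimals so both on-disk dialects carry
identical values (the B-factor column holds 2 decimals).

Defaults state a well-separated screen: `iptm_true = (0.85, 0.03)`,
`iptm_decoy = (0.2, 0.05)` — chosen to mirror the strong observed separation
between correct-pair scores (mean ≈ 0.74) and negative-control scores
(mean ≈ 0.15) in the motivating receptor-family screen. `ptm_offset = +0.05`
and `plddt_base = (80, 10)` are not constrained by any published value; they
were fixed once at levels typical of confidently predicted complexes (pTM
usually tracks slightly above ipTM for good models; pLDDT ≈ 80 ± 10 is an
ordinary well-folded prediction) and are not tuned against test outcomes.
The default seed is 20221002.

What the generator does **not** emulate: correlated per-residue pLDDT along
the chain, per-model quality heterogeneity within a job beyond i.i.d. draws,
score dependence on sequence length or homology, PAE matrices, or real
coordinates (mock PDB files carry placeholder geometry; only the B-factor
column is meaningful). A green recovery test therefore establishes that the
harvest–score–rank machinery preserves a planted signal of the stated size —
not that the predictor itself separates binders.

## Numerical choices

- Scores are compared at absolute tolerance 1e-9 in tests; reports round to
  3 decimals, matching the precision of published score tables.
- Input validation is strict: ipTM/pTM outside [0, 1], pLDDT outside
  [0, 100], empty model lists and empty pLDDT vectors are errors naming the
  offending field. Inconsistent pLDDT lengths across one job's models warn
  but do not abort the harvest.
- Sequences are uppercased and restricted to the 20 standard residues plus
  X; the ambiguous codes U/B/Z/J/O map to X with a warning because predictor
  front-ends reject them inconsistently.
- Self-pairing (bait as its own ligand) is excluded by default — the screen
  targets heterodimers — behind an explicit flag.
- Heatmap values outside [0, 1] are clamped for display with a warning; the
  TSV keeps the raw values.

## Limitations

- The full published-scale validation (27 receptor baits × 18 ligands
  through the real predictor, with its 13/24 top-1 and 28/33 top-5 recovery)
  requires GPU inference and is not reproducible here; the package verifies
  its counting rules against hand counts on planted rankings of the same
  shape and will produce the same reports when pointed at real predictor
  outputs.
- The score is a screening prior, not an affinity: no calibration to K_D is
  attempted or implied.
- Pre-combined "model confidence" values without ipTM/pTM are not accepted
  by the JSON dialect; when ipTM/pTM are present the confidence is always
  re-derived from them.
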