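# Methods

## The problem

A phosphopeptide identified with high peptide-level confidence can still
carry its phosphate on the wrong residue: several serine/threonine/tyrosine
(S/T/Y) side chains often sit close together, phosphate is labile during
fragmentation, and the fragment ions that would separate two candidate
sites (the *site-determining ions*) are frequently absent from the
spectrum. `phosflr` attaches an explicit error rate — the false
localization rate, FLR — to site assignments by the same logic that
target-decoy searching attaches an FDR to peptide identifications: score
deliberately wrong candidates alongside the real ones and read the error
rate off the decoy hit rate.

## Data model and mass arithmetic

A `Peptidoform` is a sequence of the 20 canonical residues plus positioned
modifications (1-based positions; 0 is the protein N-terminus) and a
precursor charge. Four modifications are supported: Phospho (+79.96633 Da,
S/T/Y on targets), Oxidation (+15.99491, M), Carbamidomethyl (+57.02146,
C), and protein N-terminal Acetyl (+42.01057). All masses are monoisotopic;
fixed modifications are never implied — a carbamidomethylated cysteine must
be written out, so the data model carries no hidden state. Sequences are
limited to 511 residues. The canonical text dialect is `S[Phospho]TLVLHDLLK`;
the legacy prefix dialect (`pS`, `oxM`, `camC`) is parsed for
interoperability but never emitted. Parsing is permissive about phospho on
non-S/T/Y residues because decoys require it; `strict_targets=True`
restores the target rule.

## Fragment grid

Spectra are represented on a fixed grid of 36 fragment-peak types: series
b/y × neutral-loss class {none, −H2O ("o"), −NH3 ("n"), −H3PO4 ("p"),
−H2O−H3PO4 ("op"), −NH3−H3PO4 ("np"), −2H3PO4 ("2p"), and "o2p"/"n2p"} ×
fragment charge {1, 2}, in a fixed enumeration order so intensity vectors
are comparable coordinate by coordinate. Loss masses: H2O 18.010565, NH3
17.026549, H3PO4 97.976896 Da.

Numerical and structural choices:

- **Feasibility gating.** A loss class removing k phosphates is emitted
  only for fragments that contain at least k phosphate groups, and a loss
  may never drive the fragment mass non-positive. Water/ammonia losses are
  emitted for every fragment without composition gating — no defensible
  composition rule exists that would treat targets and decoys
  asymmetrically, and symmetry between the two is what the FLR estimate
  rests on.
- **Decoy phosphates** (on non-S/T/Y residues) are treated as loss-eligible
  exactly like phospho-S/T: phosphate lability is generic, and again
  asymmetric treatment would bias decoy scores downward and the FLR
  estimate with them.
- **Fragment charge is capped at 2** regardless of precursor charge; the
  grid is exhaustive by construction.
- **b1 ions are emitted**: for adjacent N-terminal candidate sites they are
  sometimes the only site-determining ions.

## Candidate generation

For each identified phosphopeptide with more candidate sites than
phosphates (the only re-localizable case; others pass through untouched),
the target set is all C(c, m) positional isoforms with non-phospho
modifications pinned in place. Identifications with more than two
phosphates are dropped by default (`max_phospho=2`): higher multiplicities
are rare and explode the candidate space.

Decoys, one per (target isoform × phosphate):

- **Method 1 (residue exchange, the default):** the phosphorylated residue
  and a uniformly drawn non-candidate (non-S/T/Y) residue swap positions;
  the phosphate travels with its residue, other modifications travel with
  theirs (an oxidized methionine at the swap position moves along rather
  than stranding on an impossible residue). The decoy is a permutation of
  the target's residues, hence exactly isobaric.
- **Method 2 (phosphate shift):** the sequence is untouched and the
  phosphate alone moves to a uniformly drawn non-candidate residue.

Draws colliding with an existing target or decoy are re-drawn up to the
number of available positions, then accepted with a warning — short
peptides may simply not have enough distinct permutations. The C-terminal
K/R is eligible for swapping by default (`preserve_cterm=True` excludes it
for tryptic realism). Decoy counts are tallied globally across the run
(N_decoy, N_target), which is how the estimator is defined; per-spectrum
tallies would make the correction factor spectrum-dependent.

## Scoring and FLR estimation

The predicted spectrum of every candidate is compared to the experimental
spectrum projected onto the candidate's own theoretical grid: each
theoretical m/z takes the intensity of the closest experimental peak within
25 ppm, or 0 if none is in tolerance (closest-peak matching with
smallest-ppm tie-break — deterministic, and one experimental peak may serve
several theoretical ions). Similarity is the cosine between predicted and
matched intensities; being scale-invariant it needs no prior
normalization. A `normalized_log` option applies the 0–1 max-normalization
followed by log2(x+1) to both vectors first — the transform used when
model-training data are ingested — but raw-intensity scoring is the
default for the matching step. Pearson correlation is available as an
alternative diagnostic metric.

The best candidate wins; exact cosine ties resolve to the decoy
(conservative). The **delta score** is the winning cosine minus the cosine
of the nearest-scoring *target* isoform other than the winner; when no
other target exists (a defensive edge — such spectra are filtered upstream)
the delta equals the best cosine itself and the record is flagged. Spectra
whose candidates all match zero experimental intensity are unscorable and
excluded from ranking with a logged count.

Sweeping the delta-ranked list (ties grouped atomically, all-in or
all-out) gives at each cutoff

    FLR_estimated = (N_decoy + N_target) / N_decoy * #D / (#T + #D)

capped at 1.0 (values above 1 are meaningless; the cap is our choice). The
prefactor corrects for decoys being only a fraction of the wrong
candidates competing for each spectrum. With ground truth,
FLR_real = FP / (TP + FP), where a hit is TP only if the full modified
sequence including sites matches and decoy hits are FP.

Repeat analyses quantify decoy-draw randomness: the 95% confidence
half-width is coef·√(Σ(xᵢ−x̄)²/(n(n−1))) with coef = 2.26 at the default
n = 10 (9 degrees of freedom, two-sided); other repeat counts use the
Student-t 97.5% quantile, and a cutoff with a single valid value gets
half-width 0 by convention.

## The predictor contract

The machinery is predictor-agnostic. `BaselinePredictor` is a deterministic
rule-based model of HCD phosphopeptide fragmentation: backbone b/y
intensities follow a unimodal (Gaussian) profile over the cleavage index
peaking mid-sequence (width 0.35·L), y ions stronger than b (1.0 vs 0.6),
neutral-loss satellites as fixed fractions of their parent ion (water 0.2,
ammonia 0.2, phosphoric acid 0.5 when the fragment holds phospho-S/T or a
decoy phosphate, 0.1 for phospho-Y, combined losses multiplying and double
losses squaring), charge-2 ions at 0.3× — all constants in a config
dataclass, spectrum renormalized to max 1. It distinguishes positional
isoforms through both fragment masses and loss eligibility.
`LibraryPredictor` does exact (peptidoform, charge) lookup in a spectral
library; duplicates keep the highest-scoring entry, and a miss raises
rather than returning silent zeros so callers control the fallback. Users
with access to a trained neural predictor can adapt its output to the
library TSV and plug it in unchanged.

## Synthetic benchmark

`synthetic_data` emulates a synthetic-phosphopeptide benchmark with known
ground truth. Peptides are tryptic-like (terminal K/R, no internal K/R),
8–18 residues, ~25% S/T/Y content, mono:di-phosphorylated 0.9:0.1, charge
2:3 at 0.7:0.3, sites drawn uniformly among candidates, and every emitted
peptide has more candidate sites than phosphates so the whole set is
re-localizable. Spectra start from the predictor's spectrum of the *true*
isoform and are degraded: 20% peak dropout, log-normal intensity noise
(σ = 0.5 in log space), 5 ppm Gaussian m/z jitter, and 5 uniform-m/z
contaminant peaks at up to 20% of the base peak. The emulated search-engine
report mislocalizes 10% of sites (localization itself is re-derived
downstream, so this rate only exercises the relocalization bookkeeping).
All randomness flows through one seeded generator; a fixed seed reproduces
the MGF and TSV outputs byte for byte.

The noise defaults delimit a deliberately *mild* regime chosen so that the
benchmark exhibits both behaviors a localization benchmark must show: most
spectra remain confidently localizable (mean true-site recovery ≈ 99% at
estimated FLR ≤ 0.01 across ten 500-peptide runs), while ~1% of spectra —
those whose site-determining peaks were dropped or distorted — produce
genuine false localizations, so the ranked list sweeps through a nonzero
real-FLR range and decoy hits have false hits to trace. By default the
simulator uses the same predictor as the scorer (the favorable case);
`perturb_predictor` adds log-normal noise to the predictor constants to
emulate model/experiment mismatch.

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: chimeric co-isolation, real fragmentation
chemistry beyond the rule-based profile, intensity-dependent detection
limits, retention-time structure, isotope envelopes, and prediction error
of a trained model against real spectra. Calibration results here show the
estimator's internal consistency, not instrument-grade performance.

## DIA libraries

Accepted PSMs (typically estimated FLR ≤ 0.01) are exported one fragment
per row in a vendor-neutral TSV. Three modes differ only in intensity
provenance: `predicted` (predictor everywhere), `hybrid` (predictor only
where the re-analysis moved the site relative to the engine's call,
experimental otherwise), and `relocalized_experimental` (experimental
intensities with the re-analyzed identification). Retention times are
always experimental. Decoy hits are never exported; duplicate precursors
keep the highest-cosine entry; entries with fewer than 4 annotated
fragments are dropped (standard library hygiene — the threshold is
configurable).

## Problem sizes and reproducibility

The shipped statistical checks run the benchmark at 500 peptides × 10 seeds
(calibration, recovery, confidence intervals) and one 2000-peptide run
(decoy-trace comparison); the library provenance checks use a ~55-PSM run.
These sizes give the binomial checks 3σ headroom while keeping a full run
on one CPU around a minute each. `scripts/acceptance.py --seed N --out f`
re-derives every reported number from scratch; all random draws descend
from the single `--seed`.

## Known limitations

- The estimator's prefactor assumes decoys and wrong-site targets are
  comparably competitive for ambiguous spectra; decoy constructions that
  perturb the sequence more strongly (method 1 with distant swaps) are
  slightly less competitive, which makes the estimate mildly conservative
  in the deep tail.
- Only b/y ions with the listed losses are modeled — no a/c/x/z ions,
  internal fragments, immonium ions, or isotope peaks.
- Peptide-level FDR is assumed controlled upstream; `phosflr` re-localizes
  sites, it does not re-identify sequences.
- Average masses, profile-mode spectra, and mzML input are out of scope
  (MGF only).
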