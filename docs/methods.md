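# Methods

This note documents the models, parameter choices and numerical decisions
behind `fgf21stab`, and what the synthetic-data generators do and do not
emulate.

## Coordinates and fixtures

All positions use precursor numbering: the 209-residue human FGF21
sequence (UniProt Q9NSA1) including the 28-residue signal peptide, so the
mature hormone spans residues 29–209. `apply_mutations` takes a
`numbering_offset` (0 for the precursor, 28 for the mature chain) and
validates the wild-type residue before substituting, failing loudly on a
mismatch.

The packaged CSV fixtures hold the published per-mutation ΔΔG values,
the single- and multi-point melting temperatures, and the ED50 values the
downstream accounting operates on. These are measured inputs to the
arithmetic, not outputs of this package; nothing here re-predicts ΔΔG or
re-measures a melt curve. One bookkeeping caveat: the five-point variant's
tabulated ΔTm (14.1 °C) is inconsistent with its own Tm column
(58.1 − 44.4 = 13.7 °C); this package always recomputes ΔTm from the Tm
values, so it reports 13.7.

## Evolution arm

Consensus calling uses frequency over *all* aligned rows, gaps counted in
the denominator — the reading of "fraction of all analyzed sequences" we
adopted; the alternative (non-gap denominator) is one flag away in
`column_profile` consumers and is surfaced in output metadata. The cutoff
is inclusive (≥ 0.5), which is what lets a 29/58 column produce a call at
exactly 0.50. Ties at the top frequency (only possible at exactly 0.5)
break to the alphabetically earlier one-letter code — an arbitrary but
deterministic rule; if the winner equals the query residue no call is
emitted.

Conservation is scored per column as `1 − H/ln 20`, with `H` the Shannon
entropy of the 20-residue frequency vector (gaps excluded); invariant
columns score 1, a uniform column scores 0. This is a deliberate,
documented stand-in for empirical-Bayes rate estimation: it preserves the
ranking property the pipeline needs (flagging conserved positions for
exclusion, default threshold 0.9) without an external server. Columns
with more than 50% gaps are flagged unreliable.

Redundancy reduction is greedy incremental clustering: sequences visited
in descending ungapped-length order, joining the first representative
with pairwise identity ≥ threshold (identity = matches over columns where
both rows are non-gap), else founding a new cluster. The query row is
always retained. This reproduces the *effect* of CD-HIT-style filtering
deterministically; it is not CD-HIT's word-filter algorithm.

## Energy arm and merging

Thresholds: stabilizing iff ΔΔG ≤ −1.0 kcal/mol (inclusive),
destabilizing iff ΔΔG > +1.0 (strict); the three classes partition the
line. The energy arm ranks and admits on ΔΔG_Rosetta; ΔΔG_FoldX gates
only the consensus arm (≤ 0.5 kcal/mol). That asymmetry is a design
choice forced by the published candidate table itself, which keeps an
energy candidate with FoldX +1.15 — FoldX cannot have been a hard energy-
arm filter. Both roles are configurable. Missing ΔΔG values fail closed:
the candidate is rejected with a logged reason rather than guessed.
Functional (receptor/β-Klotho-binding) positions are consumed as a
user-supplied mask because no enumeration is available. Merging is a
union keyed by (position, mutant); overlaps carry `source="both"` and
retain every ΔΔG and frequency, so no information is lost. A
best-per-position reduction is deliberately *not* applied by default: all
passing mutations are kept.

## Geometry

Kabsch superposition is the standard SVD construction with the
determinant sign correction, so the returned rotation is always proper;
it needs ≥ 3 paired atoms and equal counts. Ensemble RMSD superposes each
conformer independently over the common (residue, atom) selection
(default Cα, optionally restricted to a residue subset). Salt bridges use
the 6.0 Å charged-atom cutoff published for protein-interaction-calculator
style analysis; His counts as basic by default (protonation unknown) and
can be switched off. Polar contacts are distance-only N/O pairs (3.5 Å,
different residues) — a reproducible proxy chosen because the downstream
use is a qualitative gained/lost comparison, not hydrogen-bond chemistry.
PDB I/O goes through gemmi; alternate locations resolve to the
highest-occupancy copy, and multi-MODEL files become ensembles.

## Thermal stability

Tm is the midpoint of a two-state logistic with linear folded/unfolded
baselines fitted to the 350/330 fluorescence ratio (the ratio is taken as
the canonical readout where several are available). Initialization comes
from the smoothed (Savitzky–Golay, window 5, order 2) first-derivative
maximum; bounds keep Tm inside the temperature grid and the width
positive. A flat ratio (smoothed amplitude below 4× residual noise)
raises a no-transition error; a non-converging fit falls back to the
derivative maximum (quadratically refined) with a warning. ΔTm is
reported to 0.1 °C; full precision is kept internally.

Classification thresholds are package choices that the published counts
pin down: stabilizing means ΔTm > 1.0 °C strict (admits +1.2, excludes
+0.2 and −1.1, giving 8 of 10), selection-for-combination means
ΔTm ≥ 2.0 °C inclusive (giving the 7 combined variants). Both are
configurable. Additivity reports `expected = Σ single ΔTm` against the
observed multi-point ΔTm; the deviation sign convention is
expected − observed, so positive means sub-additive.

## Bioactivity

ED50 comes from an unweighted least-squares 4PL fit,
`bottom + (top − bottom)/(1 + (ED50/x)^h)`, with multi-start
initialization (h ∈ {0.5, 1, 2}, ED50 at the geometric mean of the doses)
and bounds keeping ED50 within [min dose/10, max dose×10]. Weighted
variants were not implemented because the reference calculation is an
unspecified online calculator; unweighted least squares is the documented
default. The `converged` flag is honest: a fitted amplitude below twice
the residual RMSE is reported as a flat, non-converged response.
Densitometry normalization is the pERK/ERK band ratio (each first divided
by its loading control) relative to the negative control. Residual
activity after preincubation calls a condition active when its fitted
dynamic range reaches 20% of the untreated condition's — the published
statements are qualitative, so the fraction is configurable.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

* **Alignments** plant exact column compositions (placement is
  deterministic, then one row permutation), so planted frequencies like
  47/58 are realized exactly, not in expectation. Unplanted columns are
  i.i.d. background — there is no phylogenetic correlation between rows,
  so passing tests show the calling arithmetic is right, not that the
  pipeline is robust to realistic tree-structured homology.
* **Melt curves** use the two-state logistic with linear baselines. The
  default baselines make the 330 channel a flat reference and give the
  350 channel equal folded/unfolded drifts, so the 350/330 ratio is
  itself an exact two-state logistic with its inflection at the planted
  Tm — that is what makes noiseless recovery exact and the planted value
  a valid oracle. Real nanoDSF channels both move; the package's
  extractor does not rely on the simplification, only the oracle does.
  Default grid 20–90 °C in 0.5 °C steps, matching a 1 °C/min ramp
  sampled twice per degree.
* **Dose-response** data are 4PL means with Gaussian replicate noise;
  default 8 log-spaced doses (0.1–1000 ng/ml), triplicates, and 5% of
  the 900-unit dynamic range as noise for the recovery studies —
  mirroring the published assay layout. Single noisy experiments can
  miss the planted ED50 by tens of percent (that is a property of the
  assay, reproduced faithfully); recovery claims are therefore about the
  mean over 50 seeds.
* **Toy structures** place residues 10 Å apart on a zig-zag trace and
  position charged pseudo-atoms so planted salt-bridge distances are
  exact and all unplanted charged pairs stay beyond 7 Å. The geometry is
  a detection fixture, not a physical protein model.
* **Ensembles** are rigid rotations + translations of a model plus
  isotropic coordinate noise; the per-conformer ground-truth RMSD is
  recorded at generation time with scipy's `Rotation.align_vectors` —
  an implementation-independent route from the package's own Kabsch SVD,
  which the tests additionally check against a quaternion-grid
  brute-force minimizer.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 58-row
alignments, ≤ 150-residue toys (≤ 500 atoms for oracle comparisons),
100-seed Tm recovery and 50-seed ED50 recovery studies. These sizes make
every oracle comparison exhaustive while keeping the full suite in the
seconds range.

## Known limitations

Homology modelling, ΔΔG prediction, MD refinement, protonation
assignment and significance testing are out of scope — their outputs are
inputs here. The conservation score is an entropy proxy, not an
evolutionary-rate model. Polar contacts ignore geometry beyond distance.
The 4PL fit reports no confidence intervals; replicate scatter is the
only uncertainty surfaced.
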