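# fgf21stab

Computational stabilization of fibroblast growth factor 21 (FGF21), as a
tested, reproducible pipeline. FGF21 is a 209-residue endocrine hormone
precursor (28-residue signal peptide + 181-residue mature protein) with
therapeutic relevance in metabolic disease, but low intrinsic stability
(wild-type Tm ≈ 44 °C). This package implements the hybrid design
procedure that raised its melting temperature by up to 15 °C, together
with the downstream stability and bioactivity analyses — for protein
engineers who want to rerun, audit or adapt each step.

## What it computes

**Evolution-based arm (back-to-consensus).** Over a multiple sequence
alignment of FGF21 homologues, a position is a consensus-mutation
candidate when the most frequent residue `c` at that column satisfies
`f(c) = n_c / N ≥ 0.5` (inclusive; `N` = all aligned rows, gaps counted
in the denominator) and `c` differs from the wild-type residue.
Column conservation is scored as `1 − H/ln 20` with `H` the Shannon
entropy of the residue frequencies; redundancy is reduced with a greedy
CD-HIT-style identity clustering.

**Energy-based arm.** Per-mutation folding free-energy changes ΔΔG
(kcal/mol) from external predictors (Rosetta, FoldX) are consumed as
tables. A mutation is stabilizing iff ΔΔG ≤ −1.0, destabilizing iff
ΔΔG > 1.0. The energy arm admits ΔΔG_Rosetta ≤ −1.0; consensus calls
are additionally gated by ΔΔG_FoldX ≤ 0.5 and by exclusion masks
(conserved, functional, and salt-bridge positions). Candidates from both
arms are merged keyed by (position, mutant residue).

**Structural geometry.** Kabsch least-squares superposition (SVD with
reflection correction) and Cα RMSD against conformer ensembles;
salt-bridge detection as minimum distance ≤ 6 Å between charged
side-chain atoms (Asp OD1/OD2, Glu OE1/OE2 vs Lys NZ, Arg NH1/NH2/NE,
His ND1/NE2); distance-only polar-contact comparison between structures.

**Thermal stability.** Tm extraction from nanoDSF-style melt curves by
fitting a two-state logistic with linear baselines to the 350/330 nm
fluorescence ratio, `r(T) = b_f(T) + (b_u(T) − b_f(T)) / (1 +
exp((Tm − T)/s))`; ΔTm accounting, stabilizing classification
(ΔTm > 1 °C), selection for combination (ΔTm ≥ 2 °C), and additivity
analysis of multi-point variants.

**Bioactivity.** Four-parameter-logistic dose-response fitting,
`f(x) = bottom + (top − bottom)/(1 + (ED50/x)^h)`, for the median
effective dose ED50; pERK/ERK densitometry normalization; residual
activity profiling after thermal preincubation.

A seeded synthetic-data module generates every input class with planted
ground truth (exact column compositions, planted Tm/ED50/salt-bridge
distances, perturbed ensembles with recorded RMSDs), so the whole
pipeline is testable without wet-lab data.

## Worked example

```python
from fgf21stab import datasets, back_to_consensus
from fgf21stab.synthetic import ColumnSpec, gen_alignment
from fgf21stab.thermal import additivity_report, classify_variants

wt = datasets.wild_type_precursor()                 # 209-aa precursor
aln = gen_alignment(
    [ColumnSpec(104, {"M": 47, "Q": 5, "V": 3, "I": 2, "L": 1})],
    depth=58, seed=11, query_seq=wt,
)
for call in back_to_consensus(aln, cutoff=0.5):
    print(call.mutation, round(call.frequency, 2))  # Q104M 0.81

singles = datasets.single_mutant_variants()
stabilizing, selected = classify_variants(singles)
print(len(stabilizing), len(selected))              # 8 7

by_name = {v.name: v.delta_tm for v in singles}
rep = additivity_report(
    [(m, by_name[f"FGF21-{m}"]) for m in ("Q104M", "A139K", "K150R")],
    observed_delta=10.4,
)
print(rep.expected_sum, rep.deviation)              # 15.2 4.8
```

`Q104M 0.81` means methionine occupies 47 of 58 rows at precursor
position 104 where the wild type has glutamine — a consensus candidate.
Of the ten tested single mutants, 8 are stabilizing (ΔTm > 1 °C) and 7
clear the ≥ 2 °C bar for combination. The triple mutant's observed ΔTm
(10.4 °C) falls 4.8 °C short of the 15.2 °C sum of its three single
contributions: the stabilization is sub-additive.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study on simulated
inputs and write tables to `results/` (simulated raw inputs go to
`scratch/`):

```bash
python analysis/01_simulate_inputs.py     # seeded synthetic inputs
python analysis/02_design_selection.py    # both arms + merged candidates
python analysis/03_structure_validation.py
python analysis/04_thermal_stability.py
python analysis/05_bioactivity.py
```

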