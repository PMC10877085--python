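#!/usr/bin/env python
"""Generate the synthetic study inputs for the whole pipeline.

Emulates the data the downstream analyses consume: a 58-sequence alignment
with the three evolution-arm consensus columns planted at their published
frequencies, nanoDSF-style melt curves planted at each variant's published
Tm, triplicate dose-response tables planted at the published ED50 values,
and a toy structure with known salt bridges plus a perturbed 10-conformer
ensemble.  Everything is seeded and lands under results/inputs/.
"""

from pathlib import Path

import numpy as np

from fgf21stab import datasets, write_alignment, write_structure
from fgf21stab.synthetic import (
    ColumnSpec,
    DoseResponseParams,
    MeltCurveParams,
    gen_alignment,
    gen_dose_response,
    gen_melt_curve,
    gen_toy_structure,
    perturb_ensemble,
)

SEED = 20
OUT = Path("scratch/inputs")

#: planted compositions for the three consensus columns: M 47/58 (0.81),
#: K 29/58 (0.50), R 30/58 (0.52)
PLANTED_COLUMNS = [
    ColumnSpec(104, {"M": 47, "Q": 5, "V": 3, "I": 2, "L": 1}),
    ColumnSpec(139, {"K": 29, "A": 10, "R": 6, "Q": 4, "L": 3, "N": 2, "T": 2,
                     "G": 1, "H": 1}),
    ColumnSpec(150, {"R": 30, "K": 15, "Q": 3, "D": 2, "P": 2, "N": 1, "T": 1,
                     "A": 1, "S": 1, "E": 1, "G": 1}),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    wt = datasets.wild_type_precursor()

    aln = gen_alignment(PLANTED_COLUMNS, depth=58, seed=SEED, query_seq=wt)
    write_alignment(aln, OUT / "alignment.fasta")
    print(f"alignment: {aln.depth} sequences x {aln.length} columns, "
          "3 planted consensus columns")

    tm_tables = [datasets.single_mutant_tm(), datasets.multi_mutant_tm()]
    n_curves = 0
    for table in tm_tables:
        for row in table.itertuples():
            params = MeltCurveParams(tm=row.tm)
            noisy = MeltCurveParams(
                tm=row.tm, noise_sd=0.01 * params.amplitude(350)
            )
            curve = gen_melt_curve(noisy, seed=SEED + n_curves)
            curve.to_frame().to_csv(OUT / f"melt_{row.variant}.csv", index=False)
            n_curves += 1
    print(f"melt curves: {n_curves} variants, planted at published Tm, 1% noise")

    ref = datasets.ed50_reference()
    nih = ref[ref.cell_line == "NIH3T3"]
    for i, row in enumerate(nih.itertuples()):
        params = DoseResponseParams(
            ed50=float(row.ed50_ng_ml),
            doses=tuple(np.geomspace(0.1, 1000.0, 8)),
            replicates=3,
            noise_sd=0.05 * 900.0,
        )
        dr = gen_dose_response(params, seed=SEED + 100 + i)
        dr.to_frame().to_csv(OUT / f"dose_{row.variant}_NIH3T3.csv", index=False)
    print(f"dose-response: {len(nih)} variants (NIH 3T3), triplicates, 5% noise")

    model = gen_toy_structure(150, [(40, 55, 3.8), (90, 101, 5.2)], seed=SEED)
    write_structure(model, OUT / "toy_model.pdb")
    ensemble = perturb_ensemble(model, n_conformers=10, noise_sd=0.8, seed=SEED)
    write_structure(ensemble, OUT / "toy_ensemble.pdb")
    print("structures: 150-residue toy with 2 planted salt bridges; "
          "10-conformer perturbed ensemble (0.8 Å noise)")


if __name__ == "__main__":
    main()
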