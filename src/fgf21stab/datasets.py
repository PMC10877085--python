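"""Packaged reference fixtures: the human FGF21 precursor sequence and the
published per-mutation ΔΔG, melting-temperature and ED50 tables used by
the downstream accounting.

All coordinates are precursor numbering (signal peptide, residues 1-28,
included); the mature hormone is residues 29-209.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from Bio import SeqIO

SIGNAL_PEPTIDE_LENGTH = 28
PRECURSOR_LENGTH = 209


def _data_path(name: str):
    return resources.files("fgf21stab.data").joinpath(name)


def wild_type_precursor() -> str:
    """The 209-residue human FGF21 precursor (UniProt Q9NSA1)."""
    with resources.as_file(_data_path("fgf21_precursor.fasta")) as p:
        record = next(SeqIO.parse(str(p), "fasta"))
    return str(record.seq)


def ddg_table() -> pd.DataFrame:
    """Published per-mutation ΔΔG predictions (Rosetta, FoldX; kcal/mol)
    with consensus frequencies where the evolution arm proposed the
    mutation, and the residue repertoire seen in the alignment column."""
    with resources.as_file(_data_path("ddg_predictions.csv")) as p:
        return pd.read_csv(p)


def single_mutant_tm() -> pd.DataFrame:
    """Melting temperatures of wild type and the ten single-point variants (°C)."""
    with resources.as_file(_data_path("single_mutant_tm.csv")) as p:
        return pd.read_csv(p)


def multi_mutant_tm() -> pd.DataFrame:
    """Melting temperatures of the cumulative 3PM/4PM/5PM variants (°C)."""
    with resources.as_file(_data_path("multi_mutant_tm.csv")) as p:
        return pd.read_csv(p)


def single_mutant_variants():
    """Table of single-point variants as VariantTm objects with ΔTm attached."""
    from .thermal import load_variant_table

    with resources.as_file(_data_path("single_mutant_tm.csv")) as p:
        return load_variant_table(p)


def multi_mutant_variants():
    """Cumulative multi-point variants as VariantTm objects with ΔTm attached."""
    from .thermal import load_variant_table

    with resources.as_file(_data_path("multi_mutant_tm.csv")) as p:
        return load_variant_table(p)


def ed50_reference() -> pd.DataFrame:
    """Published ED50 values (ng/ml) from the proliferation assays on
    NIH 3T3 and Hep G2 cells."""
    with resources.as_file(_data_path("ed50_reference.csv")) as p:
        return pd.read_csv(p)
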