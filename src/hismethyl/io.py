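"""File-format helpers shared across the pipeline.

FASTA handling goes through Biopython; tabular formats are plain TSV
read and written with pandas.  Format-specific readers and writers that
belong to one analysis step live in that step's module (MGF in
``localize``/``synth``, trace tables in ``prm``, area tables in
``stoich``).
"""

from __future__ import annotations

import pandas as pd

from .chem import DigestPeptide
from .diffexpr import AbundanceMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_signal_cleavages",
    "write_peptide_table",
    "read_abundance_matrix",
    "write_abundance_matrix",
]


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences into an accession -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_signal_cleavages(path) -> dict[str, int]:
    """Read a TSV of (accession, signal_cleavage_after) pairs."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"].astype(str), df["signal_cleavage_after"]))


def write_peptide_table(
    peptides: dict[str, list[DigestPeptide]], path
) -> None:
    """Write digestion products with 1-based protein coordinates."""
    rows = [
        {
            "accession": acc,
            "start": pep.start,
            "end": pep.end,
            "sequence": pep.sequence,
            "missed_cleavages": pep.missed_cleavages,
        }
        for acc, peps in peptides.items()
        for pep in peps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_abundance_matrix(matrix_path, design_path, mode: str = "lfq") -> AbundanceMatrix:
    """Read an abundance TSV (first column protein id) and design TSV
    (sample, condition, replicate)."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    design = {
        str(row["sample"]): (str(row["condition"]), int(row["replicate"]))
        for _, row in design_df.iterrows()
    }
    missing = [s for s in data.columns if s not in design]
    if missing:
        raise ValueError(f"samples without design entries: {missing}")
    return AbundanceMatrix(data, design, mode)


def write_abundance_matrix(m: AbundanceMatrix, matrix_path, design_path) -> None:
    m.data.to_csv(matrix_path, sep="\t", index_label="protein")
    pd.DataFrame(
        [
            {"sample": s, "condition": c, "replicate": r}
            for s, (c, r) in m.design.items()
        ]
    ).to_csv(design_path, sep="\t", index=False)
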