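"""Methylation stoichiometry from MS1 precursor isotope areas.

The methylated fraction of an N-terminal peptide is estimated from the
summed MS1 areas of the first three isotopologues (M, M+1, M+2) of the
methylated and unmethylated precursor:

    fraction = sum(methylated areas) / (sum(methylated) + sum(unmethylated))

Replicates are summarized as per-sample fractions, then mean and sample
standard deviation across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeAreas",
    "StoichResult",
    "methylation_fraction",
    "batch_stoichiometry",
]


@dataclass(frozen=True)
class IsotopeAreas:
    """MS1 areas of the M, M+1 and M+2 isotopologues of one precursor form."""

    form: str  # "methylated" or "unmethylated"
    areas: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.areas) != 3:
            raise ValueError("exactly three isotopologue areas required")
        if any(a < 0 for a in self.areas):
            raise ValueError("negative isotopologue area")


@dataclass(frozen=True)
class StoichResult:
    methylated_fraction: float
    meth_sum: float
    unmeth_sum: float
    defined: bool = True


def methylation_fraction(meth: IsotopeAreas, unmeth: IsotopeAreas) -> StoichResult:
    """Methylated fraction from one methylated/unmethylated area pair.

    When both summed areas are zero the fraction is undefined and the
    result is flagged (fraction reported as NaN).
    """
    meth_sum = float(sum(meth.areas))
    unmeth_sum = float(sum(unmeth.areas))
    total = meth_sum + unmeth_sum
    if total == 0:
        return StoichResult(float("nan"), 0.0, 0.0, defined=False)
    return StoichResult(meth_sum / total, meth_sum, unmeth_sum)


def batch_stoichiometry(
    pairs: dict[str, tuple[IsotopeAreas, IsotopeAreas]],
) -> tuple[dict[str, StoichResult], float, float]:
    """Per-sample fractions plus across-replicate mean and sample SD.

    ``pairs`` maps sample id -> (methylated, unmethylated) areas.
    Undefined samples are excluded from the mean/SD.  SD uses ddof=1
    (NaN for a single replicate).
    """
    if not pairs:
        raise ValueError("no samples provided")
    results = {
        sample: methylation_fraction(meth, unmeth)
        for sample, (meth, unmeth) in pairs.items()
    }
    fractions = [r.methylated_fraction for r in results.values() if r.defined]
    mean = float(np.mean(fractions)) if fractions else float("nan")
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else float("nan")
    return results, mean, sd


def read_area_table(path) -> dict[str, tuple[IsotopeAreas, IsotopeAreas]]:
    """Read a TSV of (sample, form, iso_index, area) into paired areas.

    Samples missing either form are dropped with a flag column in the
    returned structure omitted; callers needing strictness can check
    membership.
    """
    df = pd.read_csv(path, sep="\t")
    pairs: dict[str, tuple[IsotopeAreas, IsotopeAreas]] = {}
    for sample, grp in df.groupby("sample", sort=False):
        forms = {}
        for form, sub in grp.groupby("form", sort=False):
            areas = sub.sort_values("iso_index")["area"].to_list()
            forms[str(form)] = IsotopeAreas(str(form), tuple(areas))
        if "methylated" in forms and "unmethylated" in forms:
            pairs[str(sample)] = (forms["methylated"], forms["unmethylated"])
    return pairs


def write_stoichiometry(
    results: dict[str, StoichResult], mean: float, sd: float, path
) -> None:
    rows = [
        {
            "sample": sample,
            "fraction": r.methylated_fraction,
            "meth_sum": r.meth_sum,
            "unmeth_sum": r.unmeth_sum,
            "mean": mean,
            "sd": sd,
        }
        for sample, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
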