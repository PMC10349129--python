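"""Staged elimination of methyltransferase knockout candidates.

Starting from annotation-derived methyltransferase flags and
differential-abundance statistics, candidates are narrowed through a
fixed sequence of rules: annotated methyltransferase, identified in the
proteomics data, significantly more abundant under the cellulose-like
condition, nitrogen (not oxygen) acceptor atom, no homolog in yeasts
incapable of the modification, unique to LPMO-encoding fungi — and
finally the union with manually curated additions.  Acceptor-atom,
homology and uniqueness calls are inputs (they derive from external
annotation and phylogeny resources), not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CandidateRecord",
    "FunnelStage",
    "FunnelReport",
    "DEFAULT_MTASE_KEYWORDS",
    "flag_mtases",
    "attach_diffexpr",
    "run_funnel",
]

DEFAULT_MTASE_KEYWORDS = ("methyltransferase", "sam", "s-adenosyl")


@dataclass(frozen=True)
class CandidateRecord:
    """Per-protein annotation and statistics flowing through the funnel."""

    protein_id: str
    is_mtase: bool = False
    identified: bool = False
    significant_up: bool = False
    acceptor_atom: str = "unknown"  # "N", "O" or "unknown"
    has_yeast_homolog: bool = False
    unique_to_lpmo_fungi: bool = True
    manual_add: bool = False

    def __post_init__(self) -> None:
        if self.acceptor_atom not in ("N", "O", "unknown"):
            raise ValueError(
                f"record {self.protein_id!r}: acceptor_atom must be N, O or unknown"
            )
        if self.significant_up and not self.identified:
            raise ValueError(
                f"record {self.protein_id!r}: significant_up requires identified"
            )


@dataclass
class FunnelStage:
    name: str
    rule: str
    count_in: int
    count_out: int
    removed: list[str] = field(default_factory=list)
    added: list[str] = field(default_factory=list)


@dataclass
class FunnelReport:
    stages: list[FunnelStage]

    @property
    def counts(self) -> list[int]:
        """count_in of the first stage followed by count_out of each stage."""
        if not self.stages:
            return []
        return [self.stages[0].count_in] + [s.count_out for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "rule": s.rule,
                    "count_in": s.count_in,
                    "count_out": s.count_out,
                    "n_removed": len(s.removed),
                    "n_added": len(s.added),
                }
                for s in self.stages
            ]
        )


def flag_mtases(
    annotations: pd.DataFrame,
    keywords: tuple[str, ...] = DEFAULT_MTASE_KEYWORDS,
    protein_col: str = "protein",
    term_col: str = "terms",
) -> pd.Series:
    """Flag proteins whose annotation terms match any keyword.

    Matching is case-insensitive substring search over the (possibly
    semicolon-joined) annotation term string of each protein.  The
    keyword ruleset defaults to SAM/methyltransferase vocabulary and is
    caller-editable.
    """
    if annotations[protein_col].duplicated().any():
        raise ValueError("annotation table must have one row per protein")
    lowered = [k.lower() for k in keywords]
    terms = annotations[term_col].fillna("").str.lower()
    flags = terms.apply(lambda t: any(k in t for k in lowered))
    flags.index = annotations[protein_col]
    flags.name = "is_mtase"
    return flags


def attach_diffexpr(
    records: list[CandidateRecord], volcano: pd.DataFrame
) -> list[CandidateRecord]:
    """Set identified / significant_up flags from a volcano table.

    A protein absent from the table was not identified; one present is
    significant_up when flagged significant with a positive log2 fold
    change toward the condition of interest (the contrast's first
    condition).
    """
    if volcano["protein"].duplicated().any():
        dup = volcano["protein"][volcano["protein"].duplicated()].iloc[0]
        raise ValueError(f"duplicate protein id {dup!r} in volcano table")
    info = volcano.set_index("protein")
    out = []
    for rec in records:
        if rec.protein_id in info.index:
            row = info.loc[rec.protein_id]
            out.append(
                replace(
                    rec,
                    identified=True,
                    significant_up=bool(row["significant"] and row["log2fc"] > 0),
                )
            )
        else:
            out.append(replace(rec, identified=False, significant_up=False))
    return out


def run_funnel(
    records: list[CandidateRecord],
) -> tuple[FunnelReport, list[CandidateRecord]]:
    """Apply the elimination stages in order and account for each.

    Returns the per-stage report and the final shortlist (stage
    survivors plus manual additions).  Deterministic and independent of
    input record order up to shortlist ordering.
    """
    seen = set()
    for rec in records:
        if rec.protein_id in seen:
            raise ValueError(f"duplicate candidate record {rec.protein_id!r}")
        seen.add(rec.protein_id)

    stages_def = [
        ("methyltransferase annotation", "keep annotated methyltransferases",
         lambda r: r.is_mtase),
        ("identified in proteomics", "keep proteins identified in the data",
         lambda r: r.identified),
        ("upregulated on cellulose", "keep significantly upregulated proteins",
         lambda r: r.significant_up),
        ("acceptor atom", "drop predicted O-acceptor methyltransferases",
         lambda r: r.acceptor_atom != "O"),
        ("yeast homologs", "drop candidates with S. cerevisiae / K. phaffii homologs",
         lambda r: not r.has_yeast_homolog),
        ("LPMO-fungi uniqueness", "keep candidates unique to LPMO-encoding fungi",
         lambda r: r.unique_to_lpmo_fungi),
    ]

    current = list(records)
    stages: list[FunnelStage] = []
    for name, rule, keep in stages_def:
        survivors = [r for r in current if keep(r)]
        removed = [r.protein_id for r in current if not keep(r)]
        stages.append(FunnelStage(name, rule, len(current), len(survivors), removed))
        current = survivors

    survivor_ids = {r.protein_id for r in current}
    manual = [
        r for r in records if r.manual_add and r.protein_id not in survivor_ids
    ]
    shortlist = current + manual
    stages.append(
        FunnelStage(
            "manual additions",
            "union with manually curated candidates",
            len(current),
            len(shortlist),
            removed=[],
            added=[r.protein_id for r in manual],
        )
    )
    return FunnelReport(stages), shortlist
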