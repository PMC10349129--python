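"""Synthetic MS data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: b/y fragment
spectra of tryptic peptides with or without N-terminal His methylation
(plus the diagnostic immonium ion), PRM fragment chromatogram panels
across a knockout library with one causal strain, MS1 isotope-envelope
area pairs at a set methylated fraction, and two-condition log-normal
protein abundance matrices with left-censored missingness and a planted
set of upregulated methyltransferases.

All generators are deterministic under a fixed seed, and each returns
(or fills in) a truth record meant for test assertions only — the
analysis modules never see it.

Default parameter choices emulate the acquisition regime the pipeline
is designed for: Orbitrap-class mass accuracy (a few ppm of m/z jitter
against a 20 ppm matching tolerance), minute-scale chromatographic
peaks sampled every ~0.6 s, and log-normal protein intensities with
replicate-level variation on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .chem import ModifiedPeptide
from .diffexpr import AbundanceMatrix
from .localize import Spectrum
from .prm import ChromatogramSet, Form
from .stoich import IsotopeAreas

__all__ = [
    "SpectrumSimParams",
    "PanelTruth",
    "MatrixTruth",
    "simulate_msms",
    "simulate_prm_panel",
    "simulate_blank_traces",
    "simulate_ms1_pair",
    "simulate_abundance_matrix",
    "simulate_funnel_cohort",
    "write_mgf",
    "write_trace_table",
]


@dataclass(frozen=True)
class SpectrumSimParams:
    """Knobs for MS/MS spectrum simulation.

    ppm_jitter_sd is the mass-accuracy noise (Gaussian, in ppm);
    intensity variation is multiplicative log-normal around
    ``base_intensity``; noise peaks are uniform in m/z and intensity.
    """

    ppm_jitter_sd: float = 5.0
    n_noise_peaks: int = 10
    noise_intensity_range: tuple[float, float] = (1.0, 50.0)
    base_intensity: float = 1000.0
    intensity_cv: float = 0.3
    include_immonium: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter_sd < 0:
            raise ValueError("ppm_jitter_sd must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


@dataclass
class PanelTruth:
    """Ground truth of a simulated knockout panel.

    ``meth_fraction`` holds the true methylated fraction per strain;
    strains absent from it default to fully methylated (reference-like).
    """

    strain_ids: list[str]
    causal_strain: str | None = None
    expression_lost_strains: set[str] = field(default_factory=set)
    meth_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.causal_strain is not None and self.causal_strain not in self.strain_ids:
            raise ValueError("causal_strain not in strain_ids")

    def fraction_for(self, strain: str) -> float:
        if strain in self.expression_lost_strains:
            return self.meth_fraction.get(strain, 1.0)
        if strain == self.causal_strain:
            return 0.0
        return self.meth_fraction.get(strain, 1.0)


@dataclass
class MatrixTruth:
    """Planted structure of a simulated abundance matrix."""

    upregulated_set: set[str]
    effect_size: float
    mtase_flags: dict[str, bool] = field(default_factory=dict)
    acceptor_atom: dict[str, str] = field(default_factory=dict)
    homolog_flags: dict[str, bool] = field(default_factory=dict)


def simulate_msms(
    p: ModifiedPeptide, params: SpectrumSimParams = SpectrumSimParams()
) -> Spectrum:
    """Simulate a centroided MS/MS spectrum of a peptide.

    Peaks are placed at every singly charged b/y theoretical m/z with
    log-normal intensity variation and Gaussian ppm jitter; a methylated
    peptide additionally yields the diagnostic immonium peak when
    ``include_immonium`` is set; uniform random noise peaks are added.
    """
    rng = np.random.default_rng(params.seed)
    ions = chem.fragment_ions(p, frozenset({1}))
    mzs = [ion.mz for ion in ions]
    sigma = np.sqrt(np.log1p(params.intensity_cv**2))
    intensities = list(
        params.base_intensity * rng.lognormal(-sigma**2 / 2, sigma, len(mzs))
    )

    is_methylated = any(name == "methyl_his" for _, name in p.mods)
    if is_methylated and params.include_immonium:
        mzs.append(chem.immonium_mz("H", "methyl_his"))
        intensities.append(params.base_intensity * 0.5)

    mzs = [m * (1 + rng.normal(0, params.ppm_jitter_sd) * 1e-6) for m in mzs]

    if params.n_noise_peaks:
        lo, hi = 100.0, max(mzs) + 50.0
        noise_mz = rng.uniform(lo, hi, params.n_noise_peaks)
        noise_int = rng.uniform(*params.noise_intensity_range, params.n_noise_peaks)
        mzs.extend(noise_mz)
        intensities.extend(noise_int)

    order = np.argsort(mzs)
    neutral = chem.peptide_neutral_mass(p)
    return Spectrum(
        mz=np.asarray(mzs)[order],
        intensity=np.asarray(intensities)[order],
        precursor_mz=chem.mz_of(neutral, 2),
        precursor_charge=2,
        id=f"sim|{p.sequence}|{'meth' if is_methylated else 'unmod'}|{params.seed}",
    )


def _gaussian_trace(
    rt: np.ndarray,
    amplitude: float,
    apex: float,
    sigma: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    signal = amplitude * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
    if noise_sd > 0:
        signal = signal + np.abs(rng.normal(0, noise_sd, rt.size))
    return signal


def simulate_prm_panel(
    target_sequence: str = "HTVIVYPGYR",
    truth: PanelTruth | None = None,
    sigma_rt: float = 0.05,
    sampling_step: float = 0.01,
    apex_rt: float = 10.0,
    window_halfwidth: float = 0.4,
    total_amplitude: float = 1000.0,
    baseline_noise_sd: float = 1.0,
    n_fragments: int = 6,
    seed: int = 0,
) -> list[ChromatogramSet]:
    """Simulate per-strain PRM fragment chromatograms for a knockout panel.

    For each strain both precursor forms of the target peptide are
    traced over ``n_fragments`` y-ion fragments as Gaussian peaks with a
    shared retention apex.  The methylated-form amplitude is
    ``total_amplitude`` times the strain's true methylated fraction
    (zero for the causal knockout), the unmethylated form gets the
    complement, and expression-lost strains get neither.
    """
    if truth is None:
        truth = PanelTruth(strain_ids=["reference"])
    rng = np.random.default_rng(seed)
    rt = np.arange(
        apex_rt - window_halfwidth, apex_rt + window_halfwidth + sampling_step / 2,
        sampling_step,
    )
    n_frag_max = len(target_sequence) - 1
    frag_labels = [f"y{i}" for i in range(n_frag_max, n_frag_max - n_fragments, -1)]
    rel_intensity = rng.uniform(0.5, 1.0, n_fragments)

    panel: list[ChromatogramSet] = []
    for strain in truth.strain_ids:
        lost = strain in truth.expression_lost_strains
        frac = truth.fraction_for(strain)
        for form in (Form.METHYLATED, Form.UNMETHYLATED):
            if lost:
                amp = 0.0
            else:
                amp = total_amplitude * (frac if form is Form.METHYLATED else 1 - frac)
            traces = {
                label: (
                    rt.copy(),
                    _gaussian_trace(
                        rt, amp * rel, apex_rt, sigma_rt, baseline_noise_sd, rng
                    ),
                )
                for label, rel in zip(frag_labels, rel_intensity)
            }
            panel.append(ChromatogramSet(strain, form, traces))
    return panel


def simulate_blank_traces(
    n_blanks: int = 10,
    sigma_rt: float = 0.05,
    sampling_step: float = 0.01,
    apex_rt: float = 10.0,
    window_halfwidth: float = 0.4,
    baseline_noise_sd: float = 1.0,
    n_fragments: int = 6,
    seed: int = 0,
) -> list[ChromatogramSet]:
    """Noise-only chromatogram sets, used to calibrate the detection
    threshold (see ``prm.detection_threshold_from_blanks``)."""
    rng = np.random.default_rng(seed)
    rt = np.arange(
        apex_rt - window_halfwidth, apex_rt + window_halfwidth + sampling_step / 2,
        sampling_step,
    )
    blanks = []
    for i in range(n_blanks):
        traces = {
            f"y{j}": (rt.copy(), np.abs(rng.normal(0, baseline_noise_sd, rt.size)))
            for j in range(n_fragments)
        }
        blanks.append(ChromatogramSet(f"blank{i}", Form.METHYLATED, traces))
    return blanks


def simulate_ms1_pair(
    p_base: ModifiedPeptide,
    meth_fraction: float,
    total_area: float = 1e6,
    area_noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[IsotopeAreas, IsotopeAreas]:
    """Simulate MS1 areas of the first three isotopologues of both forms.

    Areas are proportional to (form fraction) x (isotopologue pattern
    from the peptide's elemental composition, normalized over the three
    monitored peaks), with mean-one multiplicative log-normal noise of
    the given CV.  Normalizing per form makes the three-peak sums
    exactly proportional to the form fractions, matching what summing
    the same isotopologues of both precursors measures.
    """
    if not 0 <= meth_fraction <= 1:
        raise ValueError("meth_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    meth_pep = ModifiedPeptide(p_base.sequence, ((1, "methyl_his"),))
    env_u = np.array([a for _, a in chem.isotope_envelope(p_base, 3)])
    env_m = np.array([a for _, a in chem.isotope_envelope(meth_pep, 3)])
    env_u = env_u / env_u.sum()
    env_m = env_m / env_m.sum()

    sigma = np.sqrt(np.log1p(area_noise_cv**2)) if area_noise_cv > 0 else 0.0

    def noisy(base: np.ndarray) -> tuple[float, float, float]:
        if sigma == 0:
            vals = base
        else:
            vals = base * rng.lognormal(-sigma**2 / 2, sigma, 3)
        return tuple(float(v) for v in vals)

    meth = IsotopeAreas("methylated", noisy(total_area * meth_fraction * env_m))
    unmeth = IsotopeAreas(
        "unmethylated", noisy(total_area * (1 - meth_fraction) * env_u)
    )
    return meth, unmeth


def simulate_abundance_matrix(
    n_proteins: int = 1000,
    conditions: dict[str, int] | None = None,
    n_upregulated: int = 50,
    effect_size: float = 2.0,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    replicate_sd: float = 0.5,
    censor_quantile: float = 0.1,
    upregulated_condition: str = "cellulose",
    n_mtases: int = 225,
    seed: int = 0,
) -> tuple[AbundanceMatrix, MatrixTruth]:
    """Two-condition log-normal abundance matrix with left censoring.

    Protein baselines are Normal(baseline_mean, baseline_sd) on the
    log2 scale with replicate noise of ``replicate_sd``; the planted
    upregulated set is shifted by ``effect_size`` log2 units in the
    cellulose-like condition.  Values below each sample's
    ``censor_quantile`` quantile are set missing, producing
    intensity-dependent (left-censored) missingness.  The planted
    upregulated proteins are flagged as methyltransferases in the truth
    record so the candidate funnel can be exercised end to end.
    """
    conditions = conditions or {"glucose": 4, "cellulose": 4}
    if any(r < 2 for r in conditions.values()):
        raise ValueError("each condition needs at least 2 replicates")
    if upregulated_condition not in conditions:
        raise ValueError(f"unknown condition {upregulated_condition!r}")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    design: dict[str, tuple[str, int]] = {}
    for cond, nrep in conditions.items():
        for r in range(1, nrep + 1):
            design[f"{cond}_{r}"] = (cond, r)
    samples = list(design)

    up_idx = rng.choice(n_proteins, size=n_upregulated, replace=False)
    up_set = {proteins[i] for i in up_idx}
    mtase_idx = set(
        rng.choice(n_proteins, size=min(n_mtases, n_proteins), replace=False)
    ) | set(up_idx)

    baseline = rng.normal(baseline_mean, baseline_sd, n_proteins)
    log2 = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        cond = design[s][0]
        shift = np.zeros(n_proteins)
        if cond == upregulated_condition:
            shift[up_idx] = effect_size
        log2[:, j] = baseline + shift + rng.normal(0, replicate_sd, n_proteins)

    # left censoring: drop each sample's low-intensity tail
    if censor_quantile > 0:
        for j in range(len(samples)):
            thr = np.quantile(log2[:, j], censor_quantile)
            log2[log2[:, j] < thr, j] = np.nan

    data = pd.DataFrame(np.exp2(log2), index=proteins, columns=samples)
    truth = MatrixTruth(
        upregulated_set=up_set,
        effect_size=effect_size,
        mtase_flags={p: (i in mtase_idx) for i, p in enumerate(proteins)},
    )
    return AbundanceMatrix(data=data, design=design, mode="lfq"), truth


def simulate_funnel_cohort(
    counts: tuple[int, ...] = (225, 120, 41, 34, 28, 19),
    n_manual: int = 5,
    n_non_mtase: int = 200,
    seed: int = 0,
):
    """Build a candidate cohort realizing a prescribed funnel profile.

    ``counts`` are the survivor counts after each elimination stage:
    annotated methyltransferases, identified, significantly upregulated,
    surviving the O-acceptor drop, surviving the yeast-homolog drop, and
    unique to LPMO-encoding fungi.  ``n_manual`` additional curated
    records (eliminated earlier but lacking yeast homologs) carry the
    manual-addition flag.  Returns a list of ``funnel.CandidateRecord``.
    """
    from .funnel import CandidateRecord

    if len(counts) != 6 or any(
        counts[i] < counts[i + 1] for i in range(len(counts) - 1)
    ):
        raise ValueError("counts must be 6 non-increasing stage survivor counts")
    c_mtase, c_ident, c_sig, c_accept, c_homolog, c_unique = counts
    rng = np.random.default_rng(seed)

    records: list[CandidateRecord] = []
    idx = 0

    def add(n: int, **kw) -> None:
        nonlocal idx
        for _ in range(n):
            records.append(CandidateRecord(protein_id=f"C{idx:04d}", **kw))
            idx += 1

    # non-methyltransferase background
    add(n_non_mtase, is_mtase=False, identified=True)
    # annotated mtases never identified in the proteomics data
    add(c_mtase - c_ident, is_mtase=True, identified=False)
    # identified but not significantly upregulated; n_manual of these are
    # manually curated back in at the final stage
    n_flat = c_ident - c_sig
    add(n_manual, is_mtase=True, identified=True, manual_add=True)
    add(n_flat - n_manual, is_mtase=True, identified=True)
    # significant but eliminated as O-acceptor methyltransferases
    add(
        c_sig - c_accept,
        is_mtase=True,
        identified=True,
        significant_up=True,
        acceptor_atom="O",
    )
    # eliminated for having yeast homologs
    add(
        c_accept - c_homolog,
        is_mtase=True,
        identified=True,
        significant_up=True,
        acceptor_atom="N",
        has_yeast_homolog=True,
    )
    # not unique to LPMO-encoding fungi
    add(
        c_homolog - c_unique,
        is_mtase=True,
        identified=True,
        significant_up=True,
        acceptor_atom="N",
        unique_to_lpmo_fungi=False,
    )
    # final shortlist survivors
    add(
        c_unique,
        is_mtase=True,
        identified=True,
        significant_up=True,
        acceptor_atom="N",
        unique_to_lpmo_fungi=True,
    )
    rng.shuffle(records)  # order independence is part of the contract
    return records


def write_mgf(spectra, path) -> None:
    """Write spectra to an MGF file."""
    from pyteomics import mgf

    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.id,
                    "pepmass": (s.precursor_mz, None),
                    "charge": s.precursor_charge,
                },
            }
        )
    mgf.write(entries, str(path), file_mode="w")


def write_trace_table(panel: list[ChromatogramSet], path) -> None:
    """Write a panel as a long-format TSV (strain, form, fragment, rt, intensity)."""
    rows = []
    for cs in panel:
        for frag, (rt, inten) in cs.traces.items():
            for t, i in zip(rt, inten):
                rows.append(
                    {
                        "strain": cs.strain_id,
                        "form": cs.form.value,
                        "fragment": frag,
                        "rt": t,
                        "intensity": i,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
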