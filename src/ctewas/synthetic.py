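"""Synthetic paired-biopsy methylation cohorts with known ground truth.

The generator emulates the study design this pipeline targets: each subject
donates an inflamed and a clinically uninflamed gingival biopsy, and every
bulk methylome is a weighted mixture of three compartment methylomes
(epithelial, fibroblast, immune) plus slide batch effects and beta-scale
measurement noise.  Inflammation acts through two channels: (i) the immune
fraction is systematically higher in inflamed biopsies (compositional
confounding), and (ii) at planted probes the affected compartment's
methylome itself shifts by a known delta-beta (the biological signal the
EWAS is supposed to recover).

Observed beta for sample j at probe i:

    beta_ij = clip( sum_k w_kj * C_ik(status_j)  [+ slide offset on M scale]
                    + noise,  eps0, 1 - eps0 )

where C(status) is the compartment centroid matrix with planted effects
applied to inflamed samples only, and w_j are the sample's true cell
fractions.  Everything emitted (matrix, sheet, truth tables) is
deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .methcore import beta_to_m, m_to_beta

__all__ = [
    "CellTypeReference",
    "CohortDesign",
    "ProbeEffect",
    "RegionEffect",
    "TruthTable",
    "SimulatedCohort",
    "generate_reference",
    "draw_fractions",
    "plant_effects",
    "synthesize_cohort",
    "simulate_cohort",
    "beta_params_from_moments",
    "UNINFLAMED",
    "INFLAMED",
    "CELL_TYPES",
]

UNINFLAMED = "uninflamed"
INFLAMED = "inflamed"
CELL_TYPES = ("epi", "fib", "ic")

#: Immune/fibroblast fraction moments (mean, SD) per status.  The defaults
#: are the post-gating cohort moments of the study population this pipeline
#: emulates; ``PRE_GATING_IC`` carries the wider pre-gating immune moments.
DEFAULT_IC = {UNINFLAMED: (0.22, 0.06), INFLAMED: (0.58, 0.13)}
PRE_GATING_IC = {UNINFLAMED: (0.28, 0.15), INFLAMED: (0.52, 0.18)}
DEFAULT_FIB = {UNINFLAMED: (0.21, 0.07), INFLAMED: (0.17, 0.07)}

_CLIP = 1e-3  # boundary clip eps0 for emitted betas


@dataclass(frozen=True)
class CellTypeReference:
    """Compartment centroid methylomes with genomic annotation.

    ``manifest`` is indexed by probe id with columns chrom, pos (1-based bp),
    gene (';'-separated symbols, '' for intergenic) and discriminatory
    (bool: probes engineered to separate the cell types).  ``centroids`` is
    probes x (epi, fib, ic) with values in [0, 1], same index.
    """

    manifest: pd.DataFrame
    centroids: pd.DataFrame

    def __post_init__(self):
        if not self.manifest.index.equals(self.centroids.index):
            raise ValueError("manifest and centroids must share the probe index")
        if self.manifest.index.duplicated().any():
            raise ValueError("probe ids must be unique")
        vals = self.centroids.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("centroid betas must lie in [0, 1]")
        if (self.manifest["pos"] < 0).any():
            raise ValueError("positions must be non-negative")
        for _, grp in self.manifest.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")

    @property
    def probe_ids(self) -> pd.Index:
        return self.manifest.index

    @property
    def n_probes(self) -> int:
        return len(self.manifest)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort structure and generative parameters.

    Defaults are the emulated study conditions: 48 subjects each donating a
    paired inflamed/uninflamed biopsy (96 samples), immune and fibroblast
    fractions Beta-distributed at the per-status moments above, slides of 8
    samples with M-scale slide offsets of SD ``batch_sd``, and additive
    Gaussian beta-scale noise of SD ``noise_sd``.
    """

    n_subjects: int = 48
    paired_fraction: float = 1.0
    ic_params: dict = field(default_factory=lambda: dict(DEFAULT_IC))
    fib_params: dict = field(default_factory=lambda: dict(DEFAULT_FIB))
    samples_per_slide: int = 8
    noise_sd: float = 0.03
    batch_sd: float = 0.1
    smoking_rate: float = 0.43
    n_smoking_probes: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must lie in [0, 1]")
        for params in (self.ic_params, self.fib_params):
            for status, (m, s) in params.items():
                if not 0 < m < 1:
                    raise ValueError(f"fraction mean for {status!r} must be in (0,1)")
                if s < 0:
                    raise ValueError("fraction SD must be >= 0")

    # -- deterministic seed fan-out -------------------------------------
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed).spawn(4)[stream])
        )

    def sample_sheet(self) -> pd.DataFrame:
        """Sample sheet: sample_id, subject, status, slide, position, smoker.

        The first ``round(paired_fraction * n_subjects)`` subjects donate
        both biopsies; the remainder alternate between donating only an
        uninflamed or only an inflamed one.
        """
        rng = self._rng(0)
        n_paired = int(round(self.paired_fraction * self.n_subjects))
        rows = []
        for i in range(self.n_subjects):
            subject = f"S{i + 1:03d}"
            if i < n_paired:
                statuses = [UNINFLAMED, INFLAMED]
            else:
                statuses = [UNINFLAMED if (i - n_paired) % 2 == 0 else INFLAMED]
            for status in statuses:
                suffix = "U" if status == UNINFLAMED else "I"
                rows.append((f"{subject}_{suffix}", subject, status))
        sheet = pd.DataFrame(rows, columns=["sample_id", "subject", "status"])
        sheet = sheet.set_index("sample_id")
        # interleave statuses across slides so status is never confounded
        # with slide; assign smoking per subject
        order = sheet.sort_values(["status", "subject"], kind="mergesort")
        interleaved = (
            pd.concat(
                [
                    g.assign(_rank=np.arange(len(g)))
                    for _, g in order.groupby("status", sort=False)
                ]
            )
            .sort_values(["_rank", "status"], kind="mergesort")
            .drop(columns="_rank")
        )
        sheet = sheet.loc[interleaved.index]
        n = len(sheet)
        slot = np.arange(n)
        sheet["slide"] = [f"slide{s // self.samples_per_slide + 1:02d}" for s in slot]
        sheet["position"] = slot % self.samples_per_slide + 1
        smokers = {
            subj: bool(rng.random() < self.smoking_rate)
            for subj in sheet["subject"].unique()
        }
        sheet["smoker"] = sheet["subject"].map(smokers)
        return sheet


@dataclass(frozen=True)
class ProbeEffect:
    """A single planted differential-methylation effect."""

    probe_id: str
    compartment: str  # one of CELL_TYPES
    delta_beta: float


@dataclass(frozen=True)
class RegionEffect:
    """A planted DMR: all probes with start <= pos <= start + span_bp shift."""

    chrom: str
    start: int
    span_bp: int
    compartment: str
    delta_beta: float


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for a simulated cohort.

    ``effects``: per planted probe — compartment, delta_beta, region_id
    ('' for isolated DMPs).  ``batch_offsets``: per-slide true M-scale
    offset.  ``smoking_probes``: probe ids labelled smoking-associated so
    the exclusion logic is exercisable.
    """

    effects: pd.DataFrame
    batch_offsets: pd.Series
    smoking_probes: tuple = ()


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(a, b) of a Beta distribution with the given mean and SD.

    Raises ValueError when the moments are infeasible for a Beta law on
    (0, 1), i.e. when ``sd**2 >= mean * (1 - mean)``.
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError(
            f"moments mean={mean}, sd={sd} are infeasible for a Beta "
            f"distribution (need sd^2 < mean*(1-mean) = {mean * (1 - mean):.4g})"
        )
    t = mean * (1 - mean) / var - 1.0
    return mean * t, (1 - mean) * t


def generate_reference(
    n_probes: int,
    n_chromosomes: int = 3,
    mean_gap: float = 700.0,
    discriminatory_fraction: float = 0.10,
    margin: float = 0.5,
    genes_per_chrom_fraction: float = 0.02,
    seed: int = 0,
) -> CellTypeReference:
    """Generate compartment centroid methylomes on a toy genome.

    Probes are laid down per chromosome with exponential inter-probe gaps
    of mean ``mean_gap`` bp (floor 2 bp).  A random ``discriminatory_fraction``
    of probes is engineered so the maximum pairwise centroid difference is
    at least ``margin`` — the signature probes reference-based deconvolution
    relies on.  Non-discriminatory probes share a bimodal base methylome
    with small compartment-specific jitter.  Consecutive probes are grouped
    into gene territories; ~8% of annotated probes carry two gene symbols
    and ~10% are intergenic, so fractional gene counting is exercisable.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if mean_gap <= 0:
        raise ValueError("mean_gap must be positive")
    rng = np.random.default_rng(seed)

    # genome layout
    counts = np.full(n_chromosomes, n_probes // n_chromosomes)
    counts[: n_probes % n_chromosomes] += 1
    counts = counts[counts > 0]
    chroms, positions = [], []
    for c, cnt in enumerate(counts, start=1):
        gaps = np.maximum(2, rng.exponential(mean_gap, size=cnt).astype(np.int64))
        pos = 1000 + np.cumsum(gaps)
        chroms.extend([f"chr{c}"] * cnt)
        positions.append(pos)
    positions = np.concatenate(positions)
    probe_ids = [f"cg{i:08d}" for i in range(1, n_probes + 1)]

    # bimodal base methylome, kept off the boundaries
    comp = rng.random(n_probes) < 0.5
    base = np.where(
        comp, rng.beta(8, 2, size=n_probes), rng.beta(2, 8, size=n_probes)
    )
    base = np.clip(base, 0.03, 0.97)
    jitter = rng.normal(0.0, 0.03, size=(n_probes, 3))
    cent = np.clip(base[:, None] + jitter, 0.02, 0.98)

    # engineer discriminatory probes: one compartment offset by >= margin
    disc = np.zeros(n_probes, dtype=bool)
    n_disc = int(round(discriminatory_fraction * n_probes))
    if n_disc:
        idx = rng.choice(n_probes, size=n_disc, replace=False)
        disc[idx] = True
        hi = rng.uniform(margin + 0.04, 0.97, size=n_disc)
        lo = rng.uniform(0.02, hi - margin)
        target = rng.integers(0, 3, size=n_disc)
        target_is_hi = rng.random(n_disc) < 0.5
        for row, t, h, l, t_hi in zip(idx, target, hi, lo, target_is_hi):
            cent[row, :] = (l if t_hi else h)
            cent[row, t] = h if t_hi else l

    # gene territories over consecutive probes
    genes = np.empty(n_probes, dtype=object)
    gene_counter = 0
    i = 0
    probe_chrom = np.asarray(chroms)
    while i < n_probes:
        size = int(rng.geometric(max(genes_per_chrom_fraction, 1e-9) * 2.5)) + 1
        size = min(size, 40)
        block = slice(i, min(i + size, n_probes))
        u = rng.random()
        if u < 0.10:
            genes[block] = ""  # intergenic pool
        else:
            gene_counter += 1
            name = f"GENE{gene_counter:04d}"
            if u < 0.18 and gene_counter > 1:
                name = f"GENE{gene_counter - 1:04d};{name}"  # overlapping pair
            genes[block] = name
        i = block.stop

    manifest = pd.DataFrame(
        {
            "chrom": probe_chrom,
            "pos": positions,
            "gene": genes,
            "discriminatory": disc,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    centroids = pd.DataFrame(cent, index=manifest.index, columns=list(CELL_TYPES))
    return CellTypeReference(manifest=manifest, centroids=centroids)


def draw_fractions(design: CohortDesign) -> pd.DataFrame:
    """Draw per-sample true cell fractions (epi, fib, ic).

    ic and fib are Beta draws moment-matched to the design's per-status
    moments; epi is the complement (which structurally reproduces the strong
    Epi–IC anticorrelation seen in gingival biopsies).  If the complement
    goes negative, epi is set to 0 and (fib, ic) renormalised to sum 1.
    Rows sum to 1 exactly.
    """
    sheet = design.sample_sheet()
    rng = design._rng(1)
    ic = np.empty(len(sheet))
    fib = np.empty(len(sheet))
    for status in (UNINFLAMED, INFLAMED):
        mask = (sheet["status"] == status).to_numpy()
        if not mask.any():
            continue
        n = int(mask.sum())
        m_ic, s_ic = design.ic_params[status]
        m_fib, s_fib = design.fib_params[status]
        ic[mask] = (
            np.full(n, m_ic)
            if s_ic == 0
            else rng.beta(*beta_params_from_moments(m_ic, s_ic), size=n)
        )
        fib[mask] = (
            np.full(n, m_fib)
            if s_fib == 0
            else rng.beta(*beta_params_from_moments(m_fib, s_fib), size=n)
        )
    epi = 1.0 - ic - fib
    neg = epi < 0
    if neg.any():
        total = ic[neg] + fib[neg]
        ic[neg] /= total
        fib[neg] /= total
        epi[neg] = 0.0
    frac = pd.DataFrame({"epi": epi, "fib": fib, "ic": ic}, index=sheet.index)
    # enforce exact row sums against float round-off; epi never dips below 0
    frac["epi"] = (1.0 - frac["fib"] - frac["ic"]).clip(lower=0.0)
    return frac


def _expand_region(reference: CellTypeReference, spec: RegionEffect) -> pd.Index:
    man = reference.manifest
    sel = man[
        (man["chrom"] == spec.chrom)
        & (man["pos"] >= spec.start)
        & (man["pos"] <= spec.start + spec.span_bp)
    ]
    if len(sel) < 2:
        raise ValueError(
            f"region {spec.chrom}:{spec.start}-{spec.start + spec.span_bp} "
            f"covers {len(sel)} probe(s); a planted DMR needs >= 2"
        )
    return sel.index


def plant_effects(
    reference: CellTypeReference,
    design: CohortDesign,
    effect_spec: Sequence[ProbeEffect | RegionEffect] = (),
) -> TruthTable:
    """Materialise planted effects and batch offsets into a truth table.

    Probe effects shift the affected compartment's centroid by delta_beta in
    inflamed samples; region effects expand to every probe inside the bp
    span (>= 2 required) under a shared region id.  Effects that would push
    a compartment beta outside [0, 1] are rejected.  Slide offsets are drawn
    N(0, design.batch_sd) on the M scale; smoking-associated labels go to a
    random non-planted probe subset of size ``design.n_smoking_probes``.
    """
    rows = []
    region_counter = 0
    for spec in effect_spec:
        if isinstance(spec, RegionEffect):
            region_counter += 1
            rid = f"region{region_counter:03d}"
            for pid in _expand_region(reference, spec):
                rows.append((pid, spec.compartment, spec.delta_beta, rid))
        elif isinstance(spec, ProbeEffect):
            rows.append((spec.probe_id, spec.compartment, spec.delta_beta, ""))
        else:
            raise TypeError(f"unsupported effect spec: {spec!r}")
    effects = pd.DataFrame(
        rows, columns=["probe_id", "compartment", "delta_beta", "region_id"]
    ).set_index("probe_id")

    for pid, row in effects.iterrows():
        if pid not in reference.probe_ids:
            raise ValueError(f"planted probe {pid!r} not in the reference")
        if row["compartment"] not in CELL_TYPES:
            raise ValueError(f"unknown compartment {row['compartment']!r}")
        shifted = reference.centroids.at[pid, row["compartment"]] + row["delta_beta"]
        if not 0.0 <= shifted <= 1.0:
            raise ValueError(
                f"planted delta_beta {row['delta_beta']:+.3f} at {pid} pushes "
                f"the {row['compartment']} beta to {shifted:.3f}, outside [0, 1]"
            )

    rng = design._rng(2)
    slides = design.sample_sheet()["slide"].unique()
    offsets = pd.Series(
        rng.normal(0.0, design.batch_sd, size=len(slides)) if design.batch_sd > 0
        else np.zeros(len(slides)),
        index=pd.Index(slides, name="slide"),
        name="m_offset",
    )
    smoking: tuple = ()
    if design.n_smoking_probes > 0:
        pool = reference.probe_ids.difference(effects.index)
        smoking = tuple(
            rng.choice(pool, size=min(design.n_smoking_probes, len(pool)),
                       replace=False)
        )
    return TruthTable(effects=effects, batch_offsets=offsets, smoking_probes=smoking)


def synthesize_cohort(
    reference: CellTypeReference,
    fractions: pd.DataFrame,
    truth: TruthTable,
    design: CohortDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mix compartment methylomes into observed betas; return (betas, sheet).

    betas is probes x samples.  Batch offsets are added on the M scale,
    noise on the beta scale, and the result clipped to [1e-3, 1 - 1e-3].
    """
    sheet = design.sample_sheet()
    if not sheet.index.equals(fractions.index):
        raise ValueError("fractions index must match the design's sample sheet")
    cent_u = reference.centroids.to_numpy(copy=True)
    cent_i = cent_u.copy()
    if len(truth.effects):
        rows = reference.probe_ids.get_indexer(truth.effects.index)
        cols = [CELL_TYPES.index(c) for c in truth.effects["compartment"]]
        cent_i[rows, cols] += truth.effects["delta_beta"].to_numpy()

    w = fractions[list(CELL_TYPES)].to_numpy().T  # 3 x samples
    inflamed = (sheet["status"] == INFLAMED).to_numpy()
    beta = np.empty((reference.n_probes, len(sheet)))
    beta[:, ~inflamed] = cent_u @ w[:, ~inflamed]
    beta[:, inflamed] = cent_i @ w[:, inflamed]

    if design.batch_sd > 0:
        m = beta_to_m(beta, epsilon=1e-6)
        m += truth.batch_offsets.reindex(sheet["slide"]).to_numpy()[None, :]
        beta = m_to_beta(m)
    if design.noise_sd > 0:
        rng = design._rng(3)
        beta = beta + rng.normal(0.0, design.noise_sd, size=beta.shape)
    beta = np.clip(beta, _CLIP, 1.0 - _CLIP)
    betas = pd.DataFrame(beta, index=reference.probe_ids, columns=sheet.index)
    return betas, sheet


def auto_effects(
    reference: CellTypeReference,
    n_dmps: int = 50,
    n_dmrs: int = 2,
    dmp_delta: float = -0.2,
    dmr_delta: float = -0.15,
    compartment: str = "epi",
    dmr_probes: int = 5,
    dmr_max_span: int = 1500,
    seed: int = 0,
) -> list:
    """Pick feasible planted effects from a reference, deterministically.

    Isolated DMPs go to non-discriminatory probes whose affected-compartment
    centroid leaves headroom for ``dmp_delta``; DMRs are runs of
    ``dmr_probes`` consecutive probes spanning at most ``dmr_max_span`` bp
    with headroom for ``dmr_delta`` throughout.  DMR probes and DMP probes
    never overlap.
    """
    rng = np.random.default_rng(seed)
    man = reference.manifest
    cent = reference.centroids[compartment]

    def feasible(delta):
        return (cent + delta).between(0.02, 0.98) & ~man["discriminatory"]

    effects: list = []
    used: set = set()
    # regions first: need consecutive feasible probes within the span
    ok = feasible(dmr_delta)
    for _, grp in man.groupby("chrom", sort=False):
        if len(effects) >= n_dmrs:
            break
        pos = grp["pos"].to_numpy()
        for i in range(len(grp) - dmr_probes + 1):
            if len(effects) >= n_dmrs:
                break
            ids = grp.index[i : i + dmr_probes]
            if (
                pos[i + dmr_probes - 1] - pos[i] <= dmr_max_span
                and ok.loc[ids].all()
                and not used.intersection(ids)
            ):
                effects.append(
                    RegionEffect(
                        chrom=grp["chrom"].iloc[i],
                        start=int(pos[i]),
                        span_bp=int(pos[i + dmr_probes - 1] - pos[i]),
                        compartment=compartment,
                        delta_beta=dmr_delta,
                    )
                )
                used.update(ids)
    pool = man.index[feasible(dmp_delta)].difference(used)
    if len(pool) < n_dmps:
        raise ValueError(
            f"only {len(pool)} probes have headroom for delta_beta={dmp_delta}"
        )
    chosen = rng.choice(pool, size=n_dmps, replace=False)
    effects.extend(
        ProbeEffect(p, compartment, dmp_delta) for p in sorted(chosen)
    )
    return effects


@dataclass(frozen=True)
class SimulatedCohort:
    """Bundle of everything a simulated run produces."""

    reference: CellTypeReference
    design: CohortDesign
    fractions: pd.DataFrame
    truth: TruthTable
    betas: pd.DataFrame
    sheet: pd.DataFrame


def simulate_cohort(
    design: CohortDesign,
    reference: CellTypeReference | None = None,
    effect_spec: Sequence[ProbeEffect | RegionEffect] = (),
    n_probes: int = 20_000,
) -> SimulatedCohort:
    """End-to-end convenience: reference -> fractions -> truth -> cohort."""
    if reference is None:
        reference = generate_reference(n_probes, seed=design.seed)
    fractions = draw_fractions(design)
    truth = plant_effects(reference, design, effect_spec)
    betas, sheet = synthesize_cohort(reference, fractions, truth, design)
    return SimulatedCohort(reference, design, fractions, truth, betas, sheet)
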