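"""Synthetic screens and isotopologue data with known ground truth.

The screen generator emulates the dual-condition pooled screen design: a
transporter-scale library (489 genes x 10 sgRNAs + 730 non-targeting
controls by default), two arms (control / treatment media) with replicates,
known population doublings per arm, and negative-binomial sequencing counts.
A planted gene with rho effect ``r`` has its treatment-arm expected
abundance scaled by ``2**(r * dd)`` relative to control, where ``dd`` is the
control-minus-treatment doubling difference — the exponential-growth model
the rho phenotype inverts.

The MID generator is the forward model of natural-abundance correction: true
labeling convolved with a binomial tracer-purity distribution and with the
natural-abundance distribution of every atom in the fragment formula. It is
deliberately written as a direct brute-force convolution so it can serve as
an independent oracle for the matrix-based correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from screentrace.isotope_tracing import MIDVector, natural_abundances, parse_formula
from screentrace.screen_io import ScreenCounts, SgRNALibrary, SgRNARecord

__all__ = [
    "ScreenSimParams",
    "ScreenSimTruth",
    "TracerSimParams",
    "simulate_screen",
    "simulate_mid",
    "simulate_batch_areas",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ScreenSimParams:
    """Study-scale defaults: 489 genes x 10 sgRNAs, 730 NTCs, 2 replicates
    per arm, 8.4 vs 6.4 population doublings (doubling difference 2.0).

    ``reads_per_sgrna`` is the mean sequencing depth per guide (total depth
    per sample = reads_per_sgrna x library size). ``dispersion`` is the
    negative-binomial overdispersion (var = mu + dispersion * mu^2).
    Hit genes receive effect ``hit_effect_size`` (+- hit_effect_sd); each
    targeting sgRNA realizes gene_effect x efficacy with efficacy drawn from
    Normal(1, efficacy_sd) truncated to [0, 1], so efficacy_sd = 0 plants the
    gene effect exactly on every guide.
    """

    n_genes: int = 489
    sgrnas_per_gene: int = 10
    n_ntc: int = 730
    replicates: int = 2
    reads_per_sgrna: float = 300.0
    dispersion: float = 0.05
    doublings_control: float = 8.4
    doublings_treatment: float = 6.4
    fraction_hits: float = 0.0
    hit_effect_size: float = -1.0
    hit_effect_sd: float = 0.0
    efficacy_sd: float = 0.2
    abundance_sd: float = 0.5
    protospacer_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "sgrnas_per_gene", "n_ntc", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.reads_per_sgrna <= 0:
            raise ValueError("reads_per_sgrna must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.doublings_control <= 0 or self.doublings_treatment <= 0:
            raise ValueError("population doublings must be > 0")
        if self.doublings_control == self.doublings_treatment:
            raise ValueError("doubling difference between arms must be non-zero")
        if not 0 <= self.fraction_hits <= 1:
            raise ValueError("fraction_hits must lie in [0, 1]")

    @property
    def delta_doublings(self) -> float:
        return self.doublings_control - self.doublings_treatment


@dataclass
class ScreenSimTruth:
    """Planted effects: per-gene rho and per-sgRNA realized rho (NTCs are 0)."""

    gene_effects: pd.Series
    sgrna_effects: pd.Series
    hit_genes: list[str] = field(default_factory=list)


def _random_protospacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(seqs), length))]
        seqs.update("".join(row) for row in block)
    return sorted(seqs)[:n]


def simulate_screen(
    params: ScreenSimParams,
) -> tuple[SgRNALibrary, ScreenCounts, ScreenSimTruth]:
    """Simulate a dual-condition pooled screen with known planted effects.

    Counts are negative-binomial (gamma-Poisson) around expected abundances;
    per-sample expected totals equal ``reads_per_sgrna x library size``.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(params.n_genes)]
    sgrna_gene: list[tuple[str, str]] = []
    for g in genes:
        for j in range(params.sgrnas_per_gene):
            sgrna_gene.append((f"{g}_sg{j + 1:02d}", g))
    for j in range(params.n_ntc):
        sgrna_gene.append((f"NTC_{j + 1:04d}", "NTC"))
    protos = _random_protospacers(rng, len(sgrna_gene), params.protospacer_len)
    rng.shuffle(protos)
    library = SgRNALibrary(
        [SgRNARecord(sid, tgt, p) for (sid, tgt), p in zip(sgrna_gene, protos)]
    )

    # planted gene effects
    n_hits = int(round(params.fraction_hits * params.n_genes))
    hit_idx = rng.choice(params.n_genes, size=n_hits, replace=False)
    gene_eff = pd.Series(0.0, index=genes, name="rho")
    if n_hits:
        effects = params.hit_effect_size + params.hit_effect_sd * rng.standard_normal(n_hits)
        gene_eff.iloc[np.sort(hit_idx)] = effects
    hit_genes = list(gene_eff.index[gene_eff != 0])

    # per-sgRNA realized effects (gene effect x truncated-normal efficacy)
    sgrna_ids = [sid for sid, _ in sgrna_gene]
    eff = np.zeros(len(sgrna_ids))
    n_targeting = params.n_genes * params.sgrnas_per_gene
    efficacy = np.clip(
        rng.normal(1.0, params.efficacy_sd, size=n_targeting), 0.0, 1.0
    )
    eff[:n_targeting] = np.repeat(gene_eff.to_numpy(), params.sgrnas_per_gene) * efficacy
    sgrna_eff = pd.Series(eff, index=sgrna_ids, name="rho")

    # library composition and per-sample expected counts
    w = rng.lognormal(mean=0.0, sigma=params.abundance_sd, size=len(sgrna_ids))
    depth = params.reads_per_sgrna * len(sgrna_ids)
    dd = params.delta_doublings
    samples = []
    columns = {}
    for arm, doublings in (
        ("control", params.doublings_control),
        ("treatment", params.doublings_treatment),
    ):
        for r in range(1, params.replicates + 1):
            name = f"{arm}_rep{r}"
            weights = w if arm == "control" else w * np.exp2(eff * dd)
            mu = weights / weights.sum() * depth
            lam = rng.gamma(shape=1.0 / params.dispersion, scale=mu * params.dispersion)
            columns[name] = rng.poisson(lam)
            samples.append({"sample": name, "arm": arm, "replicate": r, "doublings": doublings})
    counts = ScreenCounts(
        pd.DataFrame(columns, index=pd.Index(sgrna_ids, name="sgrna_id")),
        pd.DataFrame(samples).set_index("sample"),
    )
    return library, counts, ScreenSimTruth(gene_eff, sgrna_eff, hit_genes)


@dataclass
class TracerSimParams:
    """Forward-model parameters for one measured isotopologue vector.

    ``labeling`` gives the true fractions of molecules carrying 0..k tracer
    atoms (must sum to 1, length at most n_labelable + 1); ``purity`` is the
    probability that a nominally labeled atom is actually heavy (0.99 for the
    13C tracer); natural abundances default to the packaged IUPAC table.
    """

    formula: str | Mapping[str, int] = "C3H7NO3"
    labeling: Sequence[float] = (1.0,)
    n_labelable: int | None = None
    tracer_element: str = "C"
    purity: float = 0.99
    abundance_table: Mapping[str, Sequence[float]] | None = None
    noise_sd: float = 0.0
    total_intensity: float = 1.0
    n_measured: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        comp = parse_formula(self.formula)
        n_tracer = comp.get(self.tracer_element, 0)
        if self.n_labelable is None:
            self.n_labelable = n_tracer
        if self.n_labelable > n_tracer:
            raise ValueError("n_labelable exceeds tracer-element count in formula")
        lab = np.asarray(self.labeling, dtype=float)
        if lab.size > self.n_labelable + 1:
            raise ValueError(
                f"labeling vector of length {lab.size} exceeds "
                f"n_labelable + 1 = {self.n_labelable + 1}"
            )
        if abs(lab.sum() - 1.0) > 1e-9:
            raise ValueError("labeling fractions must sum to 1")
        if (lab < 0).any():
            raise ValueError("labeling fractions must be non-negative")
        if not (0 < self.purity <= 1):
            raise ValueError("tracer purity must be in (0, 1]")
        if self.noise_sd < 0 or self.total_intensity <= 0:
            raise ValueError("noise_sd must be >= 0 and total_intensity > 0")


def _convolve_atoms(dist: np.ndarray, abundance: np.ndarray, n: int) -> np.ndarray:
    for _ in range(n):
        dist = np.convolve(dist, abundance)
    return dist


def simulate_mid(params: TracerSimParams) -> MIDVector:
    """Measured MID from true labeling: brute-force forward convolution.

    For each labeling state j the mass-shift distribution is
    Binomial(j, purity) (over the j nominally labeled atoms) convolved with
    natural abundance for the remaining tracer-element atoms and for every
    other atom in the formula; the output is the labeling-weighted mixture,
    scaled to ``total_intensity`` with optional mean-preserving log-normal
    noise.
    """
    comp = parse_formula(params.formula)
    abund = {
        el: np.asarray(v, dtype=float)
        for el, v in (params.abundance_table or natural_abundances()).items()
    }
    unknown = set(comp) - set(abund)
    if unknown:
        raise ValueError(f"no abundance data for element(s): {sorted(unknown)}")
    lab = np.asarray(params.labeling, dtype=float)
    n_lab = params.n_labelable
    tracer = params.tracer_element
    mix = np.array([0.0])
    for j, frac in enumerate(lab):
        # heavy-atom count among the j labeled positions
        dist = np.array(
            [
                math.comb(j, h) * params.purity**h * (1 - params.purity) ** (j - h)
                for h in range(j + 1)
            ]
        )
        dist = _convolve_atoms(dist, abund[tracer], comp.get(tracer, 0) - j)
        for el, n in comp.items():
            if el != tracer:
                dist = _convolve_atoms(dist, abund[el], n)
        width = max(mix.size, dist.size)
        mix = np.pad(mix, (0, width - mix.size)) + frac * np.pad(
            dist, (0, width - dist.size)
        )
    if params.n_measured is not None:
        out = np.zeros(params.n_measured)
        m = min(params.n_measured, mix.size)
        out[:m] = mix[:m]
        mix = out
    mix = mix * params.total_intensity
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        z = rng.standard_normal(mix.size)
        mix = mix * np.exp(params.noise_sd * z - params.noise_sd**2 / 2)
    return MIDVector(
        metabolite="synthetic",
        formula=comp,
        n_labelable=n_lab,
        intensities=mix,
        units="area",
    )


def simulate_batch_areas(
    n_samples: int,
    n_analytes: int = 20,
    scale_factors: Sequence[float] | None = None,
    norvaline_area: float = 1e4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Peak-area table for batch-normalization tests, with ground truth.

    Each analyte has a fixed baseline area; sample s multiplies every analyte
    (not the norvaline spike-in) by ``scale_factors[s]``, plus optional
    multiplicative log-normal noise. The analyte library has >= 20 members,
    mirroring the batch-normalization design. Returns the table (norvaline
    column included) and ground truth: the raw scales and the mean-normalized
    factors ``scale / mean(scale)`` that the normalization formula recovers.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if n_analytes < 20:
        raise ValueError("analyte library must have >= 20 members")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if norvaline_area <= 0:
        raise ValueError("norvaline_area must be > 0")
    scales = (
        np.ones(n_samples)
        if scale_factors is None
        else np.asarray(scale_factors, dtype=float)
    )
    if scales.size != n_samples or (scales <= 0).any():
        raise ValueError("scale_factors must be positive, one per sample")
    rng = np.random.default_rng(seed)
    analytes = [f"analyte_{i + 1:02d}" for i in range(n_analytes)]
    baseline = rng.lognormal(mean=np.log(1e5), sigma=0.5, size=n_analytes)
    areas = np.outer(scales, baseline)
    if noise_sd > 0:
        areas = areas * np.exp(noise_sd * rng.standard_normal(areas.shape) - noise_sd**2 / 2)
    samples = pd.Index([f"sample_{s + 1:02d}" for s in range(n_samples)], name="sample")
    table = pd.DataFrame(areas, index=samples, columns=analytes)
    table["norvaline"] = norvaline_area
    truth = {
        "scale": pd.Series(scales, index=samples, name="scale"),
        "factor": pd.Series(scales / scales.mean(), index=samples, name="factor"),
    }
    return table, truth
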