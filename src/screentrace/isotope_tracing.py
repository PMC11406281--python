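"""Stable-isotope tracing arithmetic for GC-MS / LC-MS metabolomics.

Covers the quantitative steps downstream of peak integration:

* internal-standard normalization (peak area / norvaline area);
* batch internal normalization: each analyte from a 20+ analyte library
  (excluding the transporter substrates serine, glutamine and threonine) is
  normalized to norvaline and to its across-sample mean; the per-sample mean
  of those ratios is the batch scaling factor;
* labeled fractions of a mass isotopomer distribution (MID), e.g. the M+4
  fraction of the serine m/z 390 fragment;
* natural-abundance and tracer-purity correction of MIDs: a correction
  matrix maps true labeling states to measured mass shifts (binomial tracer
  purity convolved with natural-abundance distributions of every atom in the
  fragment formula, low-resolution mode); the inverse problem is solved by
  non-negative least squares;
* small study utilities: caliper tumor volume and percent reduction in
  population doublings.

Fragment formulas are taken as supplied (e.g. the TBDMS-derivatized serine
fragment); no derivatization chemistry is inferred.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics.mass import Composition
from scipy.optimize import nnls

__all__ = [
    "MIDVector",
    "CorrectionModel",
    "BatchNormalizationModel",
    "natural_abundances",
    "parse_formula",
    "normalize_to_internal_standard",
    "batch_internal_normalization",
    "labeled_fraction",
    "build_correction_matrix",
    "correct_mid",
    "tumor_volume",
    "percent_doubling_reduction",
]

DEFAULT_EXCLUDED_ANALYTES = frozenset({"serine", "glutamine", "threonine"})
NORVALINE = "norvaline"


def natural_abundances() -> dict[str, np.ndarray]:
    """Packaged natural isotope abundance vectors (per element, M+0, M+1, ...)."""
    ref = resources.files("screentrace").joinpath("data/natural_abundance.json")
    table = json.loads(ref.read_text())["abundances"]
    return {el: np.asarray(v, dtype=float) for el, v in table.items()}


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Element -> atom count from a molecular formula string or mapping."""
    if isinstance(formula, Mapping):
        return {el: int(n) for el, n in formula.items() if n}
    return {el: int(n) for el, n in Composition(formula=formula).items() if n}


@dataclass
class MIDVector:
    """Isotopologue intensities M+0..M+N of one metabolite fragment.

    ``n_labelable`` is the number of tracer-atom positions in the fragment;
    the measured vector may extend beyond it (natural-abundance shoulder).
    ``units`` is "area" for raw intensities or "fraction" for a normalized
    distribution (which must sum to 1).
    """

    metabolite: str
    formula: dict[str, int]
    n_labelable: int
    intensities: np.ndarray
    units: str = "area"

    def __post_init__(self) -> None:
        self.formula = parse_formula(self.formula)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise ValueError("MID intensities must be non-negative")
        if self.n_labelable < 0:
            raise ValueError("n_labelable must be >= 0")
        if self.units == "fraction" and abs(self.intensities.sum() - 1.0) > 1e-6:
            raise ValueError("fraction-mode MID must sum to 1")

    def fractions(self) -> np.ndarray:
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("all-zero MID vector")
        return self.intensities / total


@dataclass
class CorrectionModel:
    """Correction matrix mapping true labeling states to measured shifts.

    ``matrix[i, j]`` is the probability that a molecule with j tracer-labeled
    positions is measured at mass shift M+i. Columns sum to <= 1 (mass above
    the measured window is truncated).
    """

    matrix: np.ndarray
    tracer_element: str
    purity: float
    abundances: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("correction-matrix entries must lie in [0, 1]")
        if (m.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("correction-matrix columns must sum to <= 1")
        self.matrix = m

    @property
    def n_labelable(self) -> int:
        return self.matrix.shape[1] - 1


def normalize_to_internal_standard(
    areas: float | Sequence[float] | np.ndarray | pd.Series,
    norvaline_area: float,
):
    """Divide analyte peak area(s) by the sample's norvaline (spike-in) area."""
    if not norvaline_area > 0:
        raise ValueError(f"norvaline area must be > 0, got {norvaline_area}")
    if np.isscalar(areas):
        return float(areas) / float(norvaline_area)
    if isinstance(areas, pd.Series):
        return areas / float(norvaline_area)
    return np.asarray(areas, dtype=float) / float(norvaline_area)


@dataclass
class BatchNormalizationModel:
    """Per-sample scaling factors with the analyte sets that produced them."""

    factors: pd.Series
    analytes_used: list[str]
    excluded: list[str]

    def __post_init__(self) -> None:
        if not (self.factors > 0).all():
            raise ValueError("batch factors must be positive")


def batch_internal_normalization(
    areas: pd.DataFrame,
    excluded: Sequence[str] = tuple(sorted(DEFAULT_EXCLUDED_ANALYTES)),
    aggregate: str = "mean",
) -> tuple[BatchNormalizationModel, pd.DataFrame]:
    """Batch scaling factors from a sample x analyte peak-area table.

    For analyte a and sample s, with norvaline-normalized area
    ``u(a,s) = area(a,s) / norvaline(s)``, the double ratio is
    ``r(a,s) = u(a,s) / mean_s u(a,s)``. The per-sample factor is the mean
    (or median) of r(a,s) over the non-excluded analytes; known substrates
    of the perturbed transporter (serine, glutamine, threonine by default)
    are excluded so real biological changes do not distort the factor.

    Returns the model plus the normalized table u(a,s) / factor(s) for every
    analyte (norvaline column dropped).
    """
    if NORVALINE not in areas.columns:
        raise ValueError(f"area table must contain a {NORVALINE!r} column")
    if len(areas) < 2:
        raise ValueError("batch normalization requires >= 2 samples")
    excluded = [e.lower() for e in excluded]
    analytes = [c for c in areas.columns if c != NORVALINE]
    used = [a for a in analytes if a.lower() not in excluded]
    if not used:
        raise ValueError("all analytes excluded from batch normalization")
    norv = areas[NORVALINE]
    if not (norv > 0).all():
        raise ValueError("norvaline area must be > 0 in every sample")
    u = areas[analytes].div(norv, axis=0)
    r = u / u.mean(axis=0)
    if aggregate == "mean":
        factors = r[used].mean(axis=1)
    elif aggregate == "median":
        factors = r[used].median(axis=1)
    else:
        raise ValueError("aggregate must be 'mean' or 'median'")
    model = BatchNormalizationModel(
        factors=factors.rename("factor"), analytes_used=used, excluded=list(excluded)
    )
    return model, u.div(factors, axis=0)


def labeled_fraction(mid: MIDVector | Sequence[float] | np.ndarray, k: int) -> float:
    """Fraction of the total pool measured at mass shift M+k.

    E.g. the labeled fraction of serine 390 M+4 out of the total serine 390
    pool. Invariant to overall scaling of the vector.
    """
    v = mid.intensities if isinstance(mid, MIDVector) else np.asarray(mid, dtype=float)
    if (v < 0).any():
        raise ValueError("intensities must be non-negative")
    if not 0 <= k < v.size:
        raise ValueError(f"isotopologue index {k} out of range for M+0..M+{v.size - 1}")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero MID vector")
    return float(v[k] / total)


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    k = np.arange(n + 1)
    return np.array([math.comb(n, int(i)) for i in k]) * p**k * (1 - p) ** (n - k)


def _atom_distribution(abundance: np.ndarray, n_atoms: int) -> np.ndarray:
    """Mass-shift distribution of n_atoms i.i.d. atoms (repeated convolution)."""
    dist = np.array([1.0])
    for _ in range(n_atoms):
        dist = np.convolve(dist, abundance)
    return dist


def build_correction_matrix(
    formula: str | Mapping[str, int],
    tracer_element: str = "C",
    n_labelable: int | None = None,
    purity: float = 0.99,
    abundance_table: Mapping[str, np.ndarray] | None = None,
    n_measured: int | None = None,
) -> CorrectionModel:
    """Correction matrix for low-resolution natural-abundance correction.

    Column j is the measured mass-shift distribution of a molecule with j
    tracer-labeled positions: each nominally labeled atom is heavy with
    probability ``purity`` (binomial), the remaining ``n_labelable - j``
    tracer-element atoms plus any tracer-element atoms outside the labelable
    positions follow natural abundance, and every other element of the
    fragment formula contributes its natural-abundance distribution. Rows are
    truncated to the measured window (default M+0..M+n_labelable, the window
    a low-resolution isotopologue scan records).
    """
    if not (0 < purity <= 1):
        raise ValueError(f"tracer purity must be in (0, 1], got {purity}")
    comp = parse_formula(formula)
    abund = {
        el: np.asarray(v, dtype=float)
        for el, v in (abundance_table or natural_abundances()).items()
    }
    unknown = set(comp) - set(abund)
    if unknown:
        raise ValueError(f"no abundance data for element(s): {sorted(unknown)}")
    n_tracer_atoms = comp.get(tracer_element, 0)
    if n_labelable is None:
        n_labelable = n_tracer_atoms
    if n_labelable > n_tracer_atoms:
        raise ValueError(
            f"n_labelable {n_labelable} exceeds {tracer_element} count "
            f"{n_tracer_atoms} in formula"
        )
    # mass-shift distribution of everything except the labelable positions
    rest = np.array([1.0])
    rest = np.convolve(rest, _atom_distribution(abund[tracer_element], n_tracer_atoms - n_labelable))
    for el, n in comp.items():
        if el != tracer_element:
            rest = np.convolve(rest, _atom_distribution(abund[el], n))
    if n_measured is None:
        n_measured = n_labelable + 1
    cols = []
    for j in range(n_labelable + 1):
        col = _binomial_pmf(j, purity)  # heavy count among the j labeled atoms
        col = np.convolve(col, _atom_distribution(abund[tracer_element], n_labelable - j))
        col = np.convolve(col, rest)
        out = np.zeros(n_measured)
        m = min(n_measured, col.size)
        out[:m] = col[:m]
        cols.append(out)
    return CorrectionModel(
        matrix=np.column_stack(cols),
        tracer_element=tracer_element,
        purity=purity,
        abundances=abund,
    )


def correct_mid(
    raw: MIDVector | Sequence[float] | np.ndarray,
    model: CorrectionModel,
) -> tuple[np.ndarray, float]:
    """Recover true labeling fractions from a measured MID.

    Solves ``raw ~ M @ x`` for ``x >= 0`` by non-negative least squares on
    the fraction-normalized measurement, then renormalizes x to sum 1.
    Returns ``(labeling fractions of length n_labelable + 1, residual norm)``.
    """
    v = raw.intensities if isinstance(raw, MIDVector) else np.asarray(raw, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero MID vector")
    v = v / total
    m = model.matrix
    if v.size < m.shape[0]:
        m = m[: v.size, :]
    elif v.size > m.shape[0]:
        pad = np.zeros((v.size - m.shape[0], m.shape[1]))
        m = np.vstack([m, pad])
    if np.linalg.matrix_rank(m) < m.shape[1]:
        raise ValueError("degenerate correction matrix (rank-deficient)")
    x, residual = nnls(m, v)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero labeling vector")
    return x / s, float(residual)


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume in mm^3: 1/2 x width^2 x length."""
    if width <= 0 or length <= 0:
        raise ValueError("width and length must be > 0")
    return 0.5 * width**2 * length


def percent_doubling_reduction(
    doublings_condition: float, doublings_reference: float
) -> tuple[int, float]:
    """Percent reduction in population doublings vs the reference arm.

    Returns ``(rounded percent, raw percent)``; e.g. 8.4 -> 6.4 doublings is
    a 24% reduction, 6.8 -> 1.3 doublings is 81%.
    """
    if doublings_reference <= 0:
        raise ValueError("reference doublings must be > 0")
    raw = 100.0 * (1.0 - doublings_condition / doublings_reference)
    return int(round(raw)), raw
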