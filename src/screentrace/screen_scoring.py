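"""Gene-level scoring of pooled CRISPRi/a growth screens.

The pipeline follows the standard dual-condition design: two arms (control
and treatment media) grown for a known number of population doublings, with
sgRNA abundances read out by sequencing at the end of each arm.

Per sgRNA, the rho growth phenotype is the log2 ratio of depth-normalized
abundances (treatment over control), centered on the median of the
non-targeting control (NTC) sgRNAs and divided by the difference in
population doublings between the arms, averaged over replicate pairs.

Per gene (10 sgRNAs each in the transporter library):

* phenotype — mean of the strongest ``top_k`` (default 7) rho values by
  absolute magnitude, signed;
* p-value — two-sided Mann-Whitney rank-sum test of all the gene's passing
  rho values against the full NTC rho pool;
* volcano score — phenotype x (-log10 p), the single ranking statistic.

Noise is estimated with simulated pseudogenes: random groups of 10 NTC
sgRNAs, one pseudogene per real gene, scored identically. The pseudogene
score distribution yields an empirical FDR per volcano-score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from screentrace.screen_io import ScreenCounts, SgRNALibrary

__all__ = [
    "ScoringConfig",
    "filter_sgrnas",
    "compute_rho",
    "gene_phenotype",
    "gene_pvalue",
    "exact_rank_sum_pvalue",
    "make_pseudogenes",
    "volcano_score",
    "score_screen",
    "empirical_fdr",
    "genes_at_fdr",
]

# Smallest p-value reported, so -log10(p) stays finite.
P_FLOOR = np.finfo(float).tiny


@dataclass
class ScoringConfig:
    """Tunable constants of the scoring pipeline.

    Defaults mirror the transporter-library design: sgRNAs need 100+ counts
    in at least one condition, a pseudocount of 10 is added to all counts,
    gene phenotype averages the strongest 7 of 10 rho values, and one
    pseudogene is simulated per real gene ("match").
    """

    min_count: int = 100
    pseudocount: int = 10
    top_k: int = 7
    sgrnas_per_gene: int = 10
    n_pseudogenes: int | str = "match"
    seed: int = 0
    rpm_normalize: bool = True
    min_passing: int = 3  # genes with fewer passing sgRNAs are excluded
    exact_max_n: int = 25  # exact rank-sum distribution up to this pooled size

    def __post_init__(self) -> None:
        if not (1 <= self.top_k <= self.sgrnas_per_gene):
            raise ValueError("require 1 <= top_k <= sgrnas_per_gene")
        if self.pseudocount < 0 or self.min_count < 0:
            raise ValueError("pseudocount and min_count must be >= 0")
        if isinstance(self.n_pseudogenes, str) and self.n_pseudogenes != "match":
            raise ValueError("n_pseudogenes must be an integer or 'match'")


def filter_sgrnas(counts: ScreenCounts, config: ScoringConfig) -> pd.Series:
    """Flag sgRNAs with >= ``min_count`` raw counts in at least one condition.

    Condition totals are raw counts summed across the replicates of each arm
    before thresholding; the pseudocount plays no role here.
    """
    totals = {
        arm: counts.counts[counts.arm_samples(arm)].sum(axis=1)
        for arm in ("control", "treatment")
    }
    best = pd.concat(totals, axis=1).max(axis=1)
    return (best >= config.min_count).rename("passed_filter")


def _replicate_pairs(counts: ScreenCounts) -> list[tuple[str, str, float]]:
    """Pair control/treatment samples by replicate index -> (ctrl, treat, dd)."""
    s = counts.samples
    pairs = []
    ctrl = s[s["arm"] == "control"]
    treat = s[s["arm"] == "treatment"]
    common = sorted(set(ctrl["replicate"]) & set(treat["replicate"]))
    if not common:
        raise ValueError("no replicate index shared between arms")
    for r in common:
        c_ids = list(ctrl.index[ctrl["replicate"] == r])
        t_ids = list(treat.index[treat["replicate"] == r])
        if len(c_ids) != 1 or len(t_ids) != 1:
            raise ValueError(f"replicate {r!r} must have exactly one sample per arm")
        dd = float(ctrl.loc[c_ids[0], "doublings"]) - float(treat.loc[t_ids[0], "doublings"])
        if dd == 0:
            raise ValueError(f"replicate {r!r}: doubling difference is zero")
        pairs.append((c_ids[0], t_ids[0], dd))
    return pairs


def compute_rho(
    counts: ScreenCounts,
    library: SgRNALibrary,
    config: ScoringConfig,
    passed: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sgRNA rho phenotypes.

    For each replicate pair r:
    ``rho_r = [log2(RPM_treat / RPM_ctrl) - median_NTC(log2 ratio)] / dd_r``
    with ``dd_r`` the control-minus-treatment population-doubling difference.
    The final rho is the mean over replicate pairs, re-centered so that the
    median rho of passing NTC sgRNAs is exactly 0.

    Returns a DataFrame indexed by sgrna_id with columns ``rho``, one
    ``rho_rep<r>`` per replicate pair, and ``passed_filter``.
    """
    counts.validate_against(library)
    if passed is None:
        passed = filter_sgrnas(counts, config)
    pairs = _replicate_pairs(counts)
    c = counts.counts.astype(float) + config.pseudocount
    if config.rpm_normalize:
        c = c / c.sum(axis=0) * 1e6
    ntc_pass = [i for i in library.ntc_ids if i in c.index and passed.get(i, False)]
    if not ntc_pass:
        raise ValueError("no passing NTC sgRNAs; cannot center rho phenotypes")
    per_rep = {}
    for k, (cid, tid, dd) in enumerate(pairs, start=1):
        l2 = np.log2(c[tid] / c[cid])
        l2 = l2 - np.median(l2.loc[ntc_pass])
        per_rep[f"rho_rep{k}"] = l2 / dd
    out = pd.DataFrame(per_rep, index=c.index)
    rho = out.mean(axis=1)
    rho = rho - np.median(rho.loc[ntc_pass])  # exact final NTC centering
    out.insert(0, "rho", rho)
    out["passed_filter"] = passed.reindex(out.index).fillna(False).astype(bool)
    return out


def gene_phenotype(
    rhos: Sequence[float] | np.ndarray,
    top_k: int = 7,
    ids: Sequence[str] | None = None,
) -> float:
    """Mean of the strongest ``top_k`` rho values by absolute magnitude.

    The mean is of the signed values; ties in \\|rho\\| are broken by sgRNA id
    (lexicographic) when ids are given, else by input position, for
    determinism. With fewer than ``top_k`` values, all are used.
    """
    r = np.asarray(rhos, dtype=float)
    if r.size == 0:
        raise ValueError("gene_phenotype requires at least one rho value")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    tie = np.array([str(i) for i in ids]) if ids is not None else np.arange(r.size)
    if ids is not None and tie.size != r.size:
        raise ValueError("ids and rhos must have equal length")
    order = np.lexsort((tie, -np.abs(r)))
    k = min(top_k, r.size)
    return float(r[order[:k]].mean())


def _exact_rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> dict[int, int]:
    """Counts of subsets of size n1 by doubled-midrank sum (shift algorithm).

    Midranks are doubled so all sums are integers even with ties. Runs in
    O(n * n1 * S) time, S = total doubled-rank sum — exact for any tie
    pattern, equivalent to exhaustive enumeration of all C(n, n1) subsets.
    """
    total = int(doubled_ranks.sum())
    # f[k][s] = number of size-k subsets with doubled-rank sum s
    f = [np.zeros(total + 1, dtype=np.int64) for _ in range(n1 + 1)]
    f[0][0] = 1
    for dr in doubled_ranks:
        dr = int(dr)
        for k in range(min(n1, len(doubled_ranks)), 0, -1):
            f[k][dr:] += f[k - 1][: total + 1 - dr]
    return {s: int(c) for s, c in enumerate(f[n1]) if c}


def exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value under the permutation null.

    p = P(\\|W - E[W]\\| >= \\|w_obs - E[W]\\|) where W is the midrank sum of the
    first group over all equally likely regroupings of the pooled values.
    Handles ties via midranks; agrees with exhaustive enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = x.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    doubled = np.rint(ranks * 2).astype(np.int64)
    w_obs = int(doubled[:n1].sum())
    mu = n1 * (n + 1)  # doubled-scale E[W]
    dist = _exact_rank_sum_distribution(doubled, n1)
    n_total = math.comb(n, n1)
    dev = abs(w_obs - mu)
    tail = sum(c for s, c in dist.items() if abs(s - mu) >= dev)
    return tail / n_total


def gene_pvalue(
    gene_rhos: Sequence[float] | np.ndarray,
    ntc_rhos: Sequence[float] | np.ndarray,
    exact_max_n: int = 25,
) -> float:
    """Two-sided Mann-Whitney p-value of a gene's rhos against the NTC pool.

    Uses the exact permutation distribution (tie-aware) when the pooled size
    is at most ``exact_max_n``; otherwise the normal approximation with tie
    and continuity correction. The p-value is floored at the smallest
    positive float so -log10(p) is finite.
    """
    x = np.asarray(gene_rhos, dtype=float)
    y = np.asarray(ntc_rhos, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("gene_pvalue requires two non-empty groups")
    if x.size + y.size <= exact_max_n:
        p = exact_rank_sum_pvalue(x, y)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return float(min(1.0, max(p, P_FLOOR)))


def make_pseudogenes(
    ntc_ids: Sequence[str],
    n_pseudogenes: int,
    group_size: int = 10,
    seed: int | np.random.Generator = 0,
) -> dict[str, list[str]]:
    """Simulated negative-control genes from randomly grouped NTC sgRNAs.

    Each pseudogene is ``group_size`` distinct NTC ids sampled without
    replacement within the group; groups are sampled independently, so ids
    recur across pseudogenes (489 groups of 10 from a pool of 730 requires
    reuse). Deterministic under a fixed seed.
    """
    pool = list(ntc_ids)
    if group_size > len(pool):
        raise ValueError(
            f"group_size {group_size} exceeds NTC pool size {len(pool)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = max(4, len(str(n_pseudogenes)))
    return {
        f"pseudo_{i + 1:0{width}d}": sorted(rng.choice(pool, size=group_size, replace=False))
        for i in range(n_pseudogenes)
    }


def volcano_score(phenotype: float, p: float) -> float:
    """phenotype x (-log10 p); the screen's single ranking statistic."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(phenotype * (-math.log10(p)))


def _score_groups(
    groups: Mapping[str, Sequence[str]],
    rho: pd.Series,
    passed: pd.Series,
    ntc_rho: pd.Series,
    config: ScoringConfig,
    is_pseudogene: bool,
) -> pd.DataFrame:
    rows = []
    for name, ids in groups.items():
        ids_pass = [i for i in ids if passed.get(i, False)]
        n_pass = len(ids_pass)
        if n_pass < config.min_passing:
            continue
        r = rho.loc[ids_pass].to_numpy()
        pheno = gene_phenotype(r, top_k=config.top_k, ids=ids_pass)
        # a pseudogene's own sgRNAs are left out of its reference pool, so
        # every group (real or simulated) is tested against NTCs outside it
        ref = ntc_rho.drop(ids_pass).to_numpy() if is_pseudogene else ntc_rho.to_numpy()
        p = gene_pvalue(r, ref, exact_max_n=config.exact_max_n)
        rows.append(
            {
                "gene": name,
                "phenotype": pheno,
                "p_value": p,
                "volcano_score": volcano_score(pheno, p),
                "n_passing": n_pass,
                "low_support": n_pass < config.top_k,
                "is_pseudogene": is_pseudogene,
            }
        )
    return pd.DataFrame(rows)


def score_screen(
    counts: ScreenCounts,
    library: SgRNALibrary,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Full scoring pipeline: filter -> rho -> gene metrics -> volcano -> rank.

    Returns one row per real gene and per pseudogene, indexed by gene name,
    with columns phenotype, p_value, volcano_score, n_passing, low_support,
    is_pseudogene, rank. Ranks (1 = largest \\|volcano score\\|) are assigned
    within real genes and within pseudogenes separately. Genes with fewer
    than ``min_passing`` passing sgRNAs are excluded.
    """
    config = config or ScoringConfig()
    passed = filter_sgrnas(counts, config)
    pheno = compute_rho(counts, library, config, passed=passed)
    rho = pheno["rho"]
    ntc_pass = [i for i in library.ntc_ids if i in rho.index and passed.get(i, False)]
    ntc_rho = rho.loc[ntc_pass]
    real = _score_groups(
        {g: library.gene_to_sgrnas[g] for g in library.genes},
        rho, passed, ntc_rho, config, is_pseudogene=False,
    )
    n_pseudo = (
        library.n_genes if config.n_pseudogenes == "match" else int(config.n_pseudogenes)
    )
    groups = make_pseudogenes(
        ntc_pass, n_pseudo, group_size=config.sgrnas_per_gene, seed=config.seed
    )
    pseudo = _score_groups(groups, rho, passed, ntc_rho, config, is_pseudogene=True)
    table = pd.concat([real, pseudo], ignore_index=True)
    if table.empty:
        raise ValueError("no gene had enough passing sgRNAs to score")
    table["rank"] = (
        table.groupby("is_pseudogene")["volcano_score"]
        .transform(lambda s: s.abs().rank(ascending=False, method="first"))
        .astype(int)
    )
    return table.set_index("gene")


def empirical_fdr(table: pd.DataFrame) -> pd.DataFrame:
    """Empirical FDR from the pseudogene null, per volcano-score threshold.

    For each threshold s (the \\|volcano score\\| of each real gene),
    ``FDR(s) = #pseudogenes(|score| >= s) / max(1, #real(|score| >= s))``;
    the ``q`` column enforces monotonicity (step-down: the FDR at a gene's
    threshold is the minimum FDR over all thresholds at least as extreme).
    """
    if not table["is_pseudogene"].any():
        raise ValueError("empirical_fdr requires pseudogene rows in the table")
    real = np.sort(np.abs(table.loc[~table["is_pseudogene"], "volcano_score"].to_numpy()))
    pseudo = np.sort(np.abs(table.loc[table["is_pseudogene"], "volcano_score"].to_numpy()))
    thresholds = real[::-1]  # most extreme first
    n_real = real.size - np.searchsorted(real, thresholds, side="left")
    n_pseudo = pseudo.size - np.searchsorted(pseudo, thresholds, side="left")
    fdr = n_pseudo / np.maximum(1, n_real)
    # step-down: q at a threshold is the best FDR over all thresholds that
    # still include it (suffix min over descending thresholds), so q is
    # monotone non-increasing in the threshold value
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "n_real": n_real,
            "n_pseudo": n_pseudo,
            "fdr": fdr,
            "q": q,
        }
    )


def genes_at_fdr(table: pd.DataFrame, alpha: float = 0.1) -> list[str]:
    """Real genes whose \\|volcano score\\| clears the empirical FDR level alpha."""
    fdr = empirical_fdr(table)
    ok = fdr[fdr["q"] <= alpha]
    if ok.empty:
        return []
    cut = ok["threshold"].min()
    real = table[~table["is_pseudogene"]]
    return list(real.index[np.abs(real["volcano_score"]) >= cut])
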