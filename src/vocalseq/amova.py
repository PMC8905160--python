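"""Nested analysis of molecular variance (AMOVA) on a dissimilarity matrix.

Partitions the variation in a matrix of pairwise dissimilarities between
sequences across a two-level hierarchy — individual bird nested within
population — following the distance-based AMOVA framework of Excoffier,
Smouse & Quattro (1992). Sums of squared deviations are computed directly
from the distance matrix,

    SSD(group) = sum over within-group pairs of d_ij^2 / n_group,

and variance components are recovered from the expected mean squares with
the standard unequal-sample-size coefficients:

    E[MSD(within bird)]        = s2_c
    E[MSD(bird within pop)]    = s2_c + n  * s2_b
    E[MSD(among populations)]  = s2_c + n' * s2_b + n'' * s2_a

with

    n   = (N - sum_p (sum_{b in p} n_b^2) / N_p) / (B - G)
    n'  = (sum_p (sum_{b in p} n_b^2) / N_p - sum_b n_b^2 / N) / (G - 1)
    n'' = (N - sum_p N_p^2 / N) / (G - 1)

where N, B, G count sequences, birds and populations, n_b sequences of
bird b and N_p sequences of population p. The fixation-style statistics
are Phi_CT = s2_a / s2_total, Phi_SC = s2_b / (s2_b + s2_c) and
Phi_ST = (s2_a + s2_b) / s2_total, and satisfy the identity
(1 - Phi_ST) = (1 - Phi_SC)(1 - Phi_CT).

AMOVA theory operates on squared (Euclidean-like) distances; a 1 - LSI
dissimilarity is not guaranteed Euclidean, so by default the supplied
dissimilarities are squared before the SSD computation
(``square_distances=True``). Set it False to use them as-is; both modes
are reported by the replication pipeline.

Permutation p-values follow the conventional schemes per statistic:
Phi_CT permutes whole birds among populations, Phi_SC permutes sequences
among birds within populations, Phi_ST permutes sequences among all
birds; p = (#{Phi* >= Phi_obs} + 1) / (n_perm + 1). When fewer than five
distinct arrangements exist at a level, all arrangements are enumerated
exactly instead.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LEVELS = ("population", "bird_within_population", "residual", "total")


@dataclass
class AmovaResult:
    """AMOVA table: df, SSD, MSD per level; variance components; Phi."""

    df: Dict[str, int]
    ssd: Dict[str, float]
    msd: Dict[str, float]
    variance_components: Dict[str, float]
    pct_variance: Dict[str, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: Dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    square_distances: bool = True
    warnings: list[str] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        phi = {"population": self.phi_ct, "bird_within_population": self.phi_sc,
               "residual": self.phi_st, "total": math.nan}
        pname = {"population": "phi_ct", "bird_within_population": "phi_sc",
                 "residual": "phi_st"}
        rows = []
        for lvl in LEVELS:
            rows.append(
                {
                    "source": lvl,
                    "df": self.df[lvl],
                    "SSD": self.ssd[lvl],
                    "MSD": self.msd.get(lvl, math.nan),
                    "VC": self.variance_components.get(
                        {"population": "population",
                         "bird_within_population": "bird_within_population",
                         "residual": "residual", "total": "total"}[lvl], math.nan),
                    "pct_variance": self.pct_variance.get(lvl, math.nan),
                    "phi": phi[lvl],
                    "p_value": self.p_values.get(pname.get(lvl, ""), math.nan),
                }
            )
        return rows


def _label_indices(labels: Sequence) -> Dict[object, np.ndarray]:
    arr = np.asarray(labels, dtype=object)
    return {lab: np.flatnonzero(arr == lab) for lab in dict.fromkeys(labels)}


def _ssd_within(d2: np.ndarray, groups: Dict[object, np.ndarray]) -> float:
    total = 0.0
    for idx in groups.values():
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _components(
    d2: np.ndarray, birds: np.ndarray, pops: np.ndarray
) -> tuple[Dict[str, float], Dict[str, int], Dict[str, float], list[str]]:
    """SSD partition, dfs, variance components for one labelling."""
    n_tot = d2.shape[0]
    bird_groups = _label_indices(birds)
    pop_groups = _label_indices(pops)
    G = len(pop_groups)
    B = len(bird_groups)

    ssd_total = d2.sum() / (2.0 * n_tot)
    ssd_within_bird = _ssd_within(d2, bird_groups)
    ssd_within_pop = _ssd_within(d2, pop_groups)
    ssd_bird = ssd_within_pop - ssd_within_bird
    ssd_pop = ssd_total - ssd_within_pop

    df = {
        "population": G - 1,
        "bird_within_population": B - G,
        "residual": n_tot - B,
        "total": n_tot - 1,
    }
    ssd = {
        "population": ssd_pop,
        "bird_within_population": ssd_bird,
        "residual": ssd_within_bird,
        "total": ssd_total,
    }

    warnings_: list[str] = []
    # per-bird and per-population sizes
    bird_pop = {}
    for b, idx in bird_groups.items():
        bird_pop[b] = pops[idx[0]]
    n_b = {b: len(idx) for b, idx in bird_groups.items()}
    N_p = {p: len(idx) for p, idx in pop_groups.items()}
    sum_nb2_over_Np = sum(
        sum(n_b[b] ** 2 for b in bird_groups if bird_pop[b] == p) / N_p[p]
        for p in pop_groups
    )
    sum_nb2_over_N = sum(v**2 for v in n_b.values()) / n_tot
    sum_Np2_over_N = sum(v**2 for v in N_p.values()) / n_tot

    msd = {lvl: (ssd[lvl] / df[lvl] if df[lvl] > 0 else math.nan) for lvl in LEVELS}
    msd["total"] = ssd["total"] / df["total"] if df["total"] > 0 else math.nan

    s2_c = msd["residual"] if df["residual"] > 0 else 0.0
    if df["bird_within_population"] > 0:
        n_coef = (n_tot - sum_nb2_over_Np) / (B - G)
        s2_b = (msd["bird_within_population"] - s2_c) / n_coef
    else:
        s2_b = 0.0
        warnings_.append(
            "bird level has 0 degrees of freedom (one bird per population); "
            "bird variance component set to 0 and Phi_SC undefined"
        )
    if df["population"] > 0:
        nprime = (sum_nb2_over_Np - sum_nb2_over_N) / (G - 1)
        ndblprime = (n_tot - sum_Np2_over_N) / (G - 1)
        s2_a = (msd["population"] - s2_c - nprime * s2_b) / ndblprime
    else:
        raise ValueError("AMOVA requires at least 2 populations")

    vc = {
        "population": s2_a,
        "bird_within_population": s2_b,
        "residual": s2_c,
        "total": s2_a + s2_b + s2_c,
    }
    if s2_a < 0 or s2_b < 0:
        warnings_.append(
            "negative variance component encountered; retained as estimated"
        )
    return ssd, df, {"msd": msd, **vc}, warnings_


def _phi_from_vc(vc: Dict[str, float], df: Dict[str, int]) -> tuple[float, float, float]:
    s2_a, s2_b, s2_c = vc["population"], vc["bird_within_population"], vc["residual"]
    total = s2_a + s2_b + s2_c
    phi_ct = s2_a / total if total != 0 else math.nan
    phi_st = (s2_a + s2_b) / total if total != 0 else math.nan
    denom = s2_b + s2_c
    if df["bird_within_population"] <= 0:
        phi_sc = math.nan
    else:
        phi_sc = s2_b / denom if denom != 0 else math.nan
    return phi_ct, phi_sc, phi_st


def _phi_stats(d2: np.ndarray, birds: np.ndarray, pops: np.ndarray) -> tuple[float, float, float]:
    ssd, df, packed, _ = _components(d2, birds, pops)
    vc = {k: packed[k] for k in ("population", "bird_within_population", "residual")}
    return _phi_from_vc(vc, df)


def amova_nested(
    dissimilarity: np.ndarray,
    birds: Sequence,
    populations: Sequence,
    *,
    n_perm: int = 999,
    seed: Optional[int] = None,
    square_distances: bool = True,
) -> AmovaResult:
    """Two-level nested AMOVA (bird within population) on a distance matrix.

    Parameters
    ----------
    dissimilarity
        Square symmetric matrix with zero diagonal (e.g. ``1 - LSI``).
    birds, populations
        Per-row labels; every bird belongs to exactly one population.
    n_perm
        Monte-Carlo permutations per Phi statistic (0 skips p-values).
    square_distances
        Square the supplied dissimilarities before the SSD computation
        (default; see module docstring).
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    birds = np.asarray(birds, dtype=object)
    pops = np.asarray(populations, dtype=object)
    if len(birds) != d.shape[0] or len(pops) != d.shape[0]:
        raise ValueError("labels must match matrix size")
    for b in dict.fromkeys(birds):
        bp = set(pops[birds == b])
        if len(bp) != 1:
            raise ValueError(f"bird {b!r} appears in multiple populations: {bp}")

    d2 = d**2 if square_distances else d.copy()
    ssd, df, packed, warns = _components(d2, birds, pops)
    msd = packed.pop("msd")
    vc = {k: packed[k] for k in ("population", "bird_within_population", "residual", "total")}
    phi_ct, phi_sc, phi_st = _phi_from_vc(vc, df)
    total_vc = vc["total"]
    pct = {
        lvl: (100.0 * vc[lvl] / total_vc if total_vc != 0 else math.nan)
        for lvl in ("population", "bird_within_population", "residual")
    }
    pct["total"] = 100.0
    result = AmovaResult(
        df=df,
        ssd=ssd,
        msd=msd,
        variance_components=vc,
        pct_variance=pct,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        square_distances=square_distances,
        warnings=warns,
    )
    for w in warns:
        logger.warning("AMOVA: %s", w)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        result.p_values = {
            "phi_ct": amova_permutation_p(d2, birds, pops, "phi_ct", n_perm, rng, phi_ct),
            "phi_sc": amova_permutation_p(d2, birds, pops, "phi_sc", n_perm, rng, phi_sc),
            "phi_st": amova_permutation_p(d2, birds, pops, "phi_st", n_perm, rng, phi_st),
        }
        result.n_permutations = n_perm
    return result


def _perm_labels(
    level: str, birds: np.ndarray, pops: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if level == "phi_st":
        perm = rng.permutation(len(birds))
        return birds[perm], pops[perm]
    if level == "phi_sc":
        new_birds = birds.copy()
        for p in dict.fromkeys(pops):
            idx = np.flatnonzero(pops == p)
            new_birds[idx] = birds[idx][rng.permutation(len(idx))]
        return new_birds, pops.copy()
    if level == "phi_ct":
        # permute whole birds among populations, preserving per-pop bird counts
        bird_list = list(dict.fromkeys(birds))
        bird_pop = {b: pops[np.flatnonzero(birds == b)[0]] for b in bird_list}
        pop_slots = [bird_pop[b] for b in bird_list]
        shuffled = [bird_list[k] for k in rng.permutation(len(bird_list))]
        new_assignment = dict(zip(shuffled, pop_slots))
        new_pops = np.array([new_assignment[b] for b in birds], dtype=object)
        return birds.copy(), new_pops
    raise ValueError(f"unknown level {level!r}")


def _phi_of(level: str, d2, birds, pops) -> float:
    ct, sc, st = _phi_stats(d2, birds, pops)
    return {"phi_ct": ct, "phi_sc": sc, "phi_st": st}[level]


def amova_permutation_p(
    d2: np.ndarray,
    birds: np.ndarray,
    pops: np.ndarray,
    level: str,
    n_perm: int,
    rng: np.random.Generator,
    observed: float,
) -> float:
    """Permutation p-value for one Phi statistic.

    Monte-Carlo with the +1 convention; exact enumeration over bird-to-
    population assignments when fewer than five distinct arrangements
    exist at the population level.
    """
    if math.isnan(observed):
        return math.nan
    if level == "phi_ct":
        bird_list = list(dict.fromkeys(birds))
        n_arrangements = math.factorial(len(bird_list))
        if n_arrangements < 5 or n_arrangements <= n_perm:
            logger.warning(
                "few exchangeable units at the population level; "
                "using exact enumeration over %d arrangements",
                n_arrangements,
            )
            bird_pop = {b: pops[np.flatnonzero(birds == b)[0]] for b in bird_list}
            pop_slots = [bird_pop[b] for b in bird_list]
            count = 0
            total = 0
            for arrangement in itertools.permutations(bird_list):
                assignment = dict(zip(arrangement, pop_slots))
                new_pops = np.array([assignment[b] for b in birds], dtype=object)
                stat = _phi_of(level, d2, birds, new_pops)
                total += 1
                if not math.isnan(stat) and stat >= observed - 1e-12:
                    count += 1
            return count / total
    count = 0
    for _ in range(n_perm):
        b_p, p_p = _perm_labels(level, birds, pops, rng)
        stat = _phi_of(level, d2, b_p, p_p)
        if not math.isnan(stat) and stat >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
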