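"""Quantification of ring- and finger-type invasion, and group comparison.

The ring front is the outermost radius at which the angular-mean cell
concentration still reaches a fraction ``alpha`` of its peak; ring
invasion length is the front's advance since t = 0.  Finger invasion
length is how far the farthest live discrete cell has advanced beyond the
initial front.  ``L_overall = max(L_ring, L_finger)`` is the headline
measurement; an invaded-area decomposition (annulus swept by the ring
plus one grid cell per agent beyond the front) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import pi

import numpy as np
from scipy import stats

from .config import GridSpec

__all__ = ["InvasionMetrics", "ring_front_radius", "compute_metrics",
           "compare_conditions"]

CM_TO_UM = 1e4


@dataclass
class InvasionMetrics:
    """Ring/finger/overall invasion lengths and invaded area at one time."""

    t: float               # s
    r_front: float         # ring-front radius, cm
    L_ring: float          # r_front(t) - r_front(0), cm
    L_finger: float        # max live-agent radius - r_front(0), cm
    L_overall: float       # max(L_ring, L_finger), cm
    area: float            # invaded area beyond the initial front, cm^2
    pattern: str           # "ring" | "finger" | "mixed"


def ring_front_radius(Cp: np.ndarray, grid: GridSpec,
                      alpha: float = 0.05) -> float:
    """Outermost radius where the angular-mean Cp >= alpha * its peak.

    ``alpha=1`` degenerates to the radius of the profile maximum.
    """
    profile = Cp if Cp.ndim == 1 else Cp.mean(axis=1)
    pmax = float(profile.max())
    if pmax <= 0.0:
        raise ValueError("ring front undefined: cell field is identically 0")
    above = np.flatnonzero(profile >= alpha * pmax)
    return float(above[-1] * grid.dr)


def compute_metrics(Cp: np.ndarray, agent_radii: np.ndarray,
                    grid: GridSpec, r_front0: float, t: float,
                    alpha: float = 0.05,
                    pattern_margin_frac: float = 0.1) -> InvasionMetrics:
    """Fill every invasion metric for one snapshot.

    ``agent_radii`` are the radii (cm) of the *live* agents (may be
    empty).  With no agent beyond the front, the finger length defaults
    to the ring length so L_overall stays well-defined, and the pattern
    is labeled "ring".
    """
    r_front = ring_front_radius(Cp, grid, alpha)
    L_ring = max(r_front - r_front0, 0.0)
    agent_radii = np.asarray(agent_radii, dtype=float)
    beyond = agent_radii[agent_radii > r_front] if agent_radii.size else agent_radii
    if agent_radii.size:
        L_finger = max(float(agent_radii.max()) - r_front0, L_ring)
    else:
        L_finger = L_ring
    L_overall = max(L_ring, L_finger)
    # annulus swept by the ring plus one local grid cell per agent past it
    area = pi * max(r_front ** 2 - r_front0 ** 2, 0.0)
    if beyond.size:
        area += float(np.sum(beyond * grid.dr * grid.dtheta))
    margin = pattern_margin_frac * r_front0
    if L_finger - L_ring > margin:
        pattern = "finger"
    elif beyond.size:
        pattern = "mixed"
    else:
        pattern = "ring"
    return InvasionMetrics(t=t, r_front=r_front, L_ring=L_ring,
                           L_finger=L_finger, L_overall=L_overall,
                           area=area, pattern=pattern)


def _exact_permutation_p(a: np.ndarray, b: np.ndarray,
                         alternative: str) -> tuple[float, float]:
    """Exact permutation test on the difference of group means.

    Enumerates every partition of the pooled sample into groups of the
    original sizes; the p-value is the fraction of partitions whose
    statistic is at least as extreme as the observed one (the identity
    partition counts, so p >= 1/N and identical groups give p = 1).
    """
    pooled = np.concatenate([a, b])
    n_a = len(a)
    obs = a.mean() - b.mean()
    idx = range(len(pooled))
    count = 0
    total = 0
    for pick in combinations(idx, n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(pick)] = True
        stat = pooled[mask].mean() - pooled[~mask].mean()
        if alternative == "greater":
            extreme = stat >= obs - 1e-12 * max(1.0, abs(obs))
        elif alternative == "less":
            extreme = stat <= obs + 1e-12 * max(1.0, abs(obs))
        else:
            extreme = abs(stat) >= abs(obs) - 1e-12 * max(1.0, abs(obs))
        count += bool(extreme)
        total += 1
    return float(obs), count / total


def compare_conditions(table, group_a, group_b, day: int,
                       value: str = "invasion_length",
                       group_col: str = "dose", day_col: str = "day",
                       alternative: str = "two-sided",
                       max_exact_n: int = 5) -> tuple[float, float]:
    """Two-sample comparison of invasion at one day between two conditions.

    Welch's unequal-variance t test for comfortable sample sizes; an
    exact permutation test on the mean difference when either group has
    ``max_exact_n`` or fewer replicates (the usual case for the 3-replicate
    chip experiment).  ``group_a``/``group_b`` may be scalars matched
    against ``group_col`` or sequences thereof (pooled).  Returns
    (statistic, p-value); the statistic is the Welch t or the observed
    mean difference a - b.
    """
    df = table[table[day_col] == day]

    def _vals(g):
        sel = df[group_col].isin(list(np.atleast_1d(g)))
        return df.loc[sel, value].to_numpy(dtype=float)

    a, b = _vals(group_a), _vals(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group "
                         f"(got {len(a)} and {len(b)})")
    if min(len(a), len(b)) <= max_exact_n:
        return _exact_permutation_p(a, b, alternative)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
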