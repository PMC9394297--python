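"""Group comparisons, antagonist-reversal quantification and sample-size bounds.

Treatment groups of per-subject % antinociception are compared by one-way
ANOVA followed by Tukey's HSD. Antagonist pre-treatment is quantified as
percent reversal of the combination effect. Group sizes follow the
resource equation: the error degrees of freedom of a one-way ANOVA with K
treatments and n animals per group, K(n - 1), should fall between 10 and
20, giving n between ceil(10/K) + 1 and ceil(20/K) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("need >= 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValidationError("every group needs >= 2 subjects")
    return gs


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Standard one-way ANOVA: returns (F, df_between, df_within, p)."""
    gs = _check_groups(groups)
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, k - 1, n - k, 1.0
        raise ComputationError(
            "ANOVA undefined: zero within-group variance with distinct means"
        )
    f, p = stats.f_oneway(*gs)
    return float(f), k - 1, n - k, float(p)


def tukey_hsd(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise table: mean_diff, q, p_adj, significant.

    q is the studentized-range statistic |diff| / sqrt(MSW/2 * (1/ni + 1/nj));
    adjusted p values come from the studentized range distribution.
    """
    gs = _check_groups(groups)
    res = stats.tukey_hsd(*gs)
    n_total = sum(len(g) for g in gs)
    df_within = n_total - len(gs)
    msw = sum(np.sum((g - g.mean()) ** 2) for g in gs) / df_within
    if msw <= 0:
        # all groups constant and equal: no variability to test against
        msw = 0.0
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        diff = float(gs[i].mean() - gs[j].mean())
        if msw > 0:
            se_q = sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            q = abs(diff) / se_q
        else:
            q = 0.0 if diff == 0 else float("inf")
        p_adj = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": i,
                "group_b": j,
                "mean_diff": diff,
                "q": q,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParticipationResult:
    """Antagonist reversal of the combination effect.

    ``percent_reversal`` is the fraction of the combination's effect
    abolished by the antagonist, ×100; it exceeds 100 when the residual
    effect is negative (hyperalgesia beyond full reversal), in which case
    ``exceeds_full_reversal`` is set.
    """

    effect_comb: float
    effect_with_antagonist: float
    percent_reversal: float
    exceeds_full_reversal: bool


def antagonist_participation(
    effect_comb: float, effect_with_antagonist: float
) -> ParticipationResult:
    """Percent reversal = (E_comb - E_antag) / E_comb * 100."""
    if not effect_comb > 0:
        raise ComputationError(
            f"combination effect must be positive, got {effect_comb}"
        )
    reversal = (effect_comb - effect_with_antagonist) / effect_comb * 100.0
    return ParticipationResult(
        effect_comb=effect_comb,
        effect_with_antagonist=effect_with_antagonist,
        percent_reversal=reversal,
        exceeds_full_reversal=effect_with_antagonist < 0,
    )


@dataclass(frozen=True)
class SampleSizeBounds:
    """Resource-equation bounds on animals per group for K treatments."""

    K: int
    mnapg: int  # minimum
    MNAPG: int  # maximum


def resource_equation(K: int) -> SampleSizeBounds:
    """Smallest/largest n per group keeping ANOVA error df K(n-1) in [10, 20]."""
    if not (isinstance(K, (int, np.integer)) and K >= 1):
        raise ValidationError(f"K must be a positive integer, got {K!r}")
    mnapg = ceil(10 / K + 1)
    MNAPG = ceil(20 / K + 1)
    return SampleSizeBounds(K=int(K), mnapg=mnapg, MNAPG=MNAPG)
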