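"""Fixed-ratio combination design and isobolographic additivity testing.

Two drugs given by different routes — one systemic (mg/kg), one local
intraplantar (µg/paw) — are combined at the constant ratio of their ED30s
and serially diluted (Tallarida's fixed-ratio method). Because the two
dose units differ, combination totals are expressed on a *fused* scalar
axis: the systemic component plus 1/1000 of the local component,

    fused_total = dose_systemic_mg_per_kg + dose_local_ug_per_paw / 1000

Additivity (Loewe) predicts the combination ED30 at the midpoint T of the
line joining the single-drug ED30s on the isobologram; the experimental
ED30 E comes from the combination's own dose–response curve. The
interaction index

    gamma = ED30_experimental / ED30_theoretical

classifies the interaction: gamma < 1 supra-additive (synergism),
gamma > 1 infra-additive, gamma ≈ 1 additive; significance of T vs E is
a two-sample Student t test on the fused-dose scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt, trunc

from scipy import stats

from .errors import ComputationError, ValidationError

LOCAL_TO_FUSED = 1e-3  # µg/paw contributes at 1/1000 scale on the fused axis

DEFAULT_FACTORS = (1, 4, 16, 32)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (9.885 -> 9.89), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fuse_total_dose(a_mg_per_kg: float, b_ug_per_paw: float) -> float:
    """Combine a systemic (mg/kg) and a local (µg/paw) dose on the fused axis."""
    if a_mg_per_kg < 0 or b_ug_per_paw < 0:
        raise ValidationError(
            f"doses must be non-negative: ({a_mg_per_kg}, {b_ug_per_paw})"
        )
    return a_mg_per_kg + b_ug_per_paw * LOCAL_TO_FUSED


@dataclass(frozen=True)
class DesignRow:
    factor: float
    dose_a: float  # mg/kg, rounded to 2 dp
    dose_b: float  # µg/paw, rounded to 2 dp
    fused_total: float


@dataclass(frozen=True)
class FixedRatioDesign:
    """The ED30-ratio combination dose table (serial dilutions of (edA, edB))."""

    ed_a: float
    ed_b: float
    factors: tuple[float, ...]
    rows: tuple[DesignRow, ...]


def build_fixed_ratio_design(
    ed_a: float, ed_b: float, factors=DEFAULT_FACTORS
) -> FixedRatioDesign:
    """Serial fixed-ratio dilutions of the single-drug ED30s.

    Per dilution factor f: each component is divided by f and rounded
    half-up to 2 decimals *before* fusing — the order that makes the fused
    totals exactly reproducible from the printed component doses.
    """
    if not (ed_a > 0 and ed_b > 0):
        raise ValidationError(f"ED30s must be positive: ({ed_a}, {ed_b})")
    factors = tuple(float(f) for f in factors)
    if not factors or factors[0] != 1 or any(
        b <= a for a, b in zip(factors, factors[1:])
    ):
        raise ValidationError(
            f"factors must be strictly increasing and start at 1: {factors}"
        )
    if any(f <= 0 for f in factors):
        raise ValidationError(f"factors must be positive: {factors}")
    rows = []
    for f in factors:
        da = round_half_up(ed_a / f, 2)
        db = round_half_up(ed_b / f, 2)
        if da <= 0 or db <= 0:
            raise ValidationError(
                f"factor {f:g} dilutes a component dose to zero at 2 dp"
            )
        rows.append(DesignRow(f, da, db, fuse_total_dose(da, db)))
    return FixedRatioDesign(ed_a=ed_a, ed_b=ed_b, factors=factors, rows=tuple(rows))


@dataclass(frozen=True)
class AdditivePoint:
    """T: the additive-prediction ED30 on the fused axis, with its variance."""

    z_add: float
    var: float
    df: int

    @property
    def se(self) -> float:
        return sqrt(self.var)


@dataclass(frozen=True)
class ExperimentalPoint:
    """E: the combination ED30 measured from the combination DRC."""

    z_exp: float
    se: float
    df: int

    def __post_init__(self):
        if not self.z_exp > 0:
            raise ValidationError(f"experimental ED30 must be positive: {self.z_exp}")


def additive_point(
    ed_a: float, se_a: float, ed_b: float, se_b: float, df: int = 0
) -> AdditivePoint:
    """Theoretical additive ED30: midpoint of the isobologram's additive line.

    T sits at equal ED30 fractions of the two drugs, i.e. half of each
    component ED30 on the fused axis; its variance propagates the two
    component SEs, and df is the sum of the component regression dfs.
    """
    if not (ed_a > 0 and ed_b > 0):
        raise ValidationError(f"ED30s must be positive: ({ed_a}, {ed_b})")
    if se_a < 0 or se_b < 0:
        raise ValidationError("standard errors must be non-negative")
    z_add = ed_a / 2.0 + (ed_b * LOCAL_TO_FUSED) / 2.0
    var = (se_a**2 + (se_b * LOCAL_TO_FUSED) ** 2) / 4.0
    return AdditivePoint(z_add=z_add, var=var, df=df)


def interaction_index(z_exp: float, z_add: float) -> tuple[float, float]:
    """gamma = experimental / theoretical ED30; reported value truncated to 2 dp.

    Truncation toward zero (0.1396 -> 0.13) is deliberate and matches the
    conventional conservative reporting of supra-additive indices.
    """
    if not (z_exp > 0 and z_add > 0):
        raise ComputationError(
            f"interaction index needs positive doses: ({z_exp}, {z_add})"
        )
    gamma_raw = z_exp / z_add
    gamma_reported = trunc(gamma_raw * 100.0) / 100.0
    return gamma_raw, gamma_reported


def tallarida_test(
    exp: ExperimentalPoint, add: AdditivePoint, df: int | None = None
) -> tuple[float, float]:
    """Student t test of T vs E as independent means on the fused axis.

    t = (z_add - z_exp) / sqrt(se_add^2 + se_exp^2); two-sided p from the
    t distribution with df defaulting to the sum of the regression dfs.
    """
    pooled_var = add.var + exp.se**2
    if pooled_var <= 0:
        raise ComputationError("T-vs-E test undefined with zero pooled variance")
    if df is None:
        df = add.df + exp.df
    if df < 1:
        raise ComputationError(f"t test needs df >= 1, got {df}")
    t = (add.z_add - exp.z_exp) / sqrt(pooled_var)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def classify(gamma_raw: float, p: float, alpha: float = 0.05) -> str:
    """Interaction class from gamma and the T-vs-E p value.

    Not significant -> additive; else supra-additive when gamma < 1,
    infra-additive when gamma > 1. gamma == 1 is additive regardless.
    """
    if not gamma_raw > 0:
        raise ValidationError(f"gamma must be positive: {gamma_raw}")
    if p >= alpha or gamma_raw == 1.0:
        return "additive"
    return "supra_additive" if gamma_raw < 1.0 else "infra_additive"


@dataclass(frozen=True)
class InteractionResult:
    """Full T-vs-E comparison: gamma, the t test, and the classification."""

    gamma_raw: float
    gamma_reported: float
    t_stat: float
    p_value: float
    classification: str


def interaction_result(
    exp: ExperimentalPoint,
    add: AdditivePoint,
    alpha: float = 0.05,
    df: int | None = None,
) -> InteractionResult:
    gamma_raw, gamma_reported = interaction_index(exp.z_exp, add.z_add)
    t, p = tallarida_test(exp, add, df=df)
    return InteractionResult(
        gamma_raw=gamma_raw,
        gamma_reported=gamma_reported,
        t_stat=t,
        p_value=p,
        classification=classify(gamma_raw, p, alpha),
    )
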