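"""End-to-end analysis: study table -> metrics -> DRCs -> isobologram -> report.

``run_analysis`` chains the whole method: per-subject AUC and %
antinociception, group summaries, log-dose regressions for each
monotherapy and for the combination (on the fused total-dose axis), ED30
inversion, the fixed-ratio design table, the additive point T vs the
experimental point E, the interaction index with its t test, antagonist
participation, and one-way ANOVA with Tukey HSD across treated arms.
The report is a plain dict-of-dicts, deterministic given study + config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .doseresponse import DoseScale, DRCFit, EDxEstimate, edx, fit_drc, fit_report
from .errors import ComputationError, ValidationError
from .isobole import (
    AdditivePoint,
    ExperimentalPoint,
    FixedRatioDesign,
    InteractionResult,
    additive_point,
    build_fixed_ratio_design,
    fuse_total_dose,
    interaction_result,
)
from .metrics import PhaseWindows, group_summary_table, subject_effects
from .stats import antagonist_participation, one_way_anova, tukey_hsd
from .study import ArmRole, DoseUnit, Route, StudyTable, TreatmentArm


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs (the generator has its own)."""

    windows: PhaseWindows = field(default_factory=PhaseWindows)
    scale: DoseScale = DoseScale.LOG10_DOSE
    edx_level: float = 30.0
    factors: tuple[float, ...] = (1, 4, 16, 32)
    alpha: float = 0.05
    tallarida_df: int | None = None  # None: df_A + df_combination
    group_comparisons: bool = True  # ANOVA + Tukey table (the slowest section)
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.edx_level < 100:
            raise ValidationError(f"edx_level must be in (0, 100): {self.edx_level}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1): {self.alpha}")
        object.__setattr__(self, "scale", DoseScale(self.scale))

    def hash(self) -> str:
        payload = json.dumps(
            {
                "windows": [self.windows.phase1, self.windows.phase2],
                "scale": self.scale.value,
                "edx_level": self.edx_level,
                "factors": self.factors,
                "alpha": self.alpha,
                "tallarida_df": self.tallarida_df,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _arm_fused_total(arm: TreatmentArm) -> float:
    a = sum(d.dose for d in arm.doses if d.unit is DoseUnit.MG_PER_KG)
    b = sum(d.dose for d in arm.doses if d.unit is DoseUnit.UG_PER_PAW)
    return fuse_total_dose(a, b)


def _monotherapy_series(study: StudyTable, unit: DoseUnit) -> list[TreatmentArm]:
    arms = [
        a
        for a in study.arms.values()
        if a.role is ArmRole.MONOTHERAPY
        and len(a.doses) == 1
        and a.doses[0].unit is unit
        and a.doses[0].route is not Route.INTRAPLANTAR_CONTRALATERAL
    ]
    return sorted(arms, key=lambda a: a.doses[0].dose)


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, JSON-serializable via to_dict()."""

    group_effects: pd.DataFrame
    fit_a: DRCFit | None
    fit_b: DRCFit | None
    fit_comb: DRCFit | None
    ed_a: EDxEstimate | None
    ed_b: EDxEstimate | None
    ed_comb: EDxEstimate | None
    design: FixedRatioDesign | None
    additive: AdditivePoint | None
    experimental: ExperimentalPoint | None
    interaction: InteractionResult | None
    participation: pd.DataFrame
    anova: dict | None
    tukey: pd.DataFrame | None
    provenance: dict

    def to_dict(self) -> dict:
        def ed_dict(ed):
            return (
                None
                if ed is None
                else {"x": ed.x, "dose": ed.dose, "se": ed.se, "df": ed.df}
            )

        return {
            "group_effects": self.group_effects.to_dict(orient="records"),
            "drc": {
                name: (None if fit is None else fit_report(fit, ed))
                for name, (fit, ed) in {
                    "drug_a": (self.fit_a, self.ed_a),
                    "drug_b": (self.fit_b, self.ed_b),
                    "combination": (self.fit_comb, self.ed_comb),
                }.items()
            },
            "fixed_ratio_design": None
            if self.design is None
            else [asdict(r) for r in self.design.rows],
            "isobologram": None
            if self.interaction is None
            else {
                "z_additive": self.additive.z_add,
                "se_additive": self.additive.se,
                "z_experimental": self.experimental.z_exp,
                "se_experimental": self.experimental.se,
                "gamma_raw": self.interaction.gamma_raw,
                "gamma_reported": self.interaction.gamma_reported,
                "t": self.interaction.t_stat,
                "p": self.interaction.p_value,
                "classification": self.interaction.classification,
            },
            "participation": self.participation.to_dict(orient="records"),
            "anova": self.anova,
            "tukey": None if self.tukey is None else self.tukey.to_dict(orient="records"),
            "provenance": self.provenance,
        }


def _fit_series(
    doses: list[float], effects: list[float], config: AnalysisConfig, what: str
) -> tuple[DRCFit, EDxEstimate]:
    try:
        fit = fit_drc(doses, effects, config.scale)
        ed = edx(fit, config.edx_level)
    except (ValidationError, ComputationError) as exc:
        raise ComputationError(f"dose-response fit failed for {what}: {exc}") from exc
    return fit, ed


def run_analysis(study: StudyTable, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full analysis chain on a validated study."""
    config = config or AnalysisConfig()
    windows = config.windows
    summary = group_summary_table(study, windows)
    mean_by_arm = dict(zip(summary["arm"], summary["mean"]))

    fit_a = fit_b = fit_comb = None
    ed_a = ed_b = ed_comb = None
    design = None
    add = exp = inter = None

    arms_a = _monotherapy_series(study, DoseUnit.MG_PER_KG)
    arms_b = _monotherapy_series(study, DoseUnit.UG_PER_PAW)
    if len(arms_a) >= 2:
        fit_a, ed_a = _fit_series(
            [a.doses[0].dose for a in arms_a],
            [mean_by_arm[a.label] for a in arms_a],
            config,
            "systemic monotherapy",
        )
    if len(arms_b) >= 2:
        fit_b, ed_b = _fit_series(
            [a.doses[0].dose for a in arms_b],
            [mean_by_arm[a.label] for a in arms_b],
            config,
            "local monotherapy",
        )

    comb_arms = sorted(
        (a for a in study.arms.values() if a.role is ArmRole.COMBINATION),
        key=_arm_fused_total,
    )
    if len(comb_arms) >= 2:
        fit_comb, ed_comb = _fit_series(
            [_arm_fused_total(a) for a in comb_arms],
            [mean_by_arm[a.label] for a in comb_arms],
            config,
            "combination",
        )
    elif ed_a is not None and ed_b is not None:
        warnings.warn(
            "study has < 2 combination arms: isobologram section omitted",
            stacklevel=2,
        )

    if ed_a is not None and ed_b is not None:
        try:
            design = build_fixed_ratio_design(ed_a.dose, ed_b.dose, config.factors)
        except ValidationError as exc:
            warnings.warn(f"fixed-ratio design omitted: {exc}", stacklevel=2)
        if ed_comb is not None:
            add = additive_point(
                ed_a.dose, ed_a.se, ed_b.dose, ed_b.se, df=ed_a.df + ed_b.df
            )
            exp = ExperimentalPoint(z_exp=ed_comb.dose, se=ed_comb.se, df=ed_comb.df)
            df = (
                config.tallarida_df
                if config.tallarida_df is not None
                else ed_a.df + ed_comb.df
            )
            inter = interaction_result(exp, add, alpha=config.alpha, df=df)

    # antagonist participation, each antagonist arm against the combination
    # arm that shares its (non-antagonist) drug doses
    part_rows = []
    comb_by_total = {round(_arm_fused_total(a), 6): a for a in comb_arms}
    for arm in study.arms.values():
        if arm.role is not ArmRole.COMBINATION_WITH_ANTAGONIST:
            continue
        drug_names = {d.drug for a in comb_arms for d in a.doses}
        non_antag = tuple(d for d in arm.doses if d.drug in drug_names)
        key = round(
            fuse_total_dose(
                sum(d.dose for d in non_antag if d.unit is DoseUnit.MG_PER_KG),
                sum(d.dose for d in non_antag if d.unit is DoseUnit.UG_PER_PAW),
            ),
            6,
        )
        ref = comb_by_total.get(key)
        if ref is None:
            warnings.warn(
                f"antagonist arm {arm.label!r}: no matching combination arm",
                stacklevel=2,
            )
            continue
        antag = "+".join(sorted(d.drug for d in arm.doses if d.drug not in drug_names))
        part = antagonist_participation(mean_by_arm[ref.label], mean_by_arm[arm.label])
        part_rows.append(
            {
                "antagonist": antag,
                "arm": arm.label,
                "effect_comb": part.effect_comb,
                "effect_residual": part.effect_with_antagonist,
                "percent_reversal": part.percent_reversal,
                "flag": "exceeds_full_reversal" if part.exceeds_full_reversal else "",
            }
        )
    participation = pd.DataFrame(
        part_rows,
        columns=[
            "antagonist", "arm", "effect_comb", "effect_residual",
            "percent_reversal", "flag",
        ],
    )

    # ANOVA + Tukey across treated arms (per-subject effects)
    treated = [
        a.label for a in study.arms.values() if a.role is not ArmRole.VEHICLE_CONTROL
    ]
    anova = tukey = None
    if config.group_comparisons and len(treated) >= 2:
        vectors = [subject_effects(study, label, windows) for label in treated]
        if all(len(v) >= 2 for v in vectors):
            try:
                f, dfb, dfw, p = one_way_anova(vectors)
                anova = {"F": f, "df_between": dfb, "df_within": dfw, "p": p}
                tukey = tukey_hsd(vectors, alpha=config.alpha)
                tukey = tukey.assign(
                    group_a=[treated[i] for i in tukey["group_a"]],
                    group_b=[treated[i] for i in tukey["group_b"]],
                )
            except ComputationError as exc:
                warnings.warn(f"ANOVA section omitted: {exc}", stacklevel=2)

    provenance = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_arms": len(study.arms),
        "n_subjects": len(study.timecourses),
    }
    return AnalysisReport(
        group_effects=summary,
        fit_a=fit_a,
        fit_b=fit_b,
        fit_comb=fit_comb,
        ed_a=ed_a,
        ed_b=ed_b,
        ed_comb=ed_comb,
        design=design,
        additive=add,
        experimental=exp,
        interaction=inter,
        participation=participation,
        anova=anova,
        tukey=tukey,
        provenance=provenance,
    )
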