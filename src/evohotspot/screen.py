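"""Two-step microtiter plate screen decision logic.

Variants are always judged against the control replicates on their own plate
(plate-to-plate humidity variation makes cross-plate comparison unsafe).
Stage 1 uses single variant measurements: pass when the titer exceeds the
upper bound of the two-sided 90% t-confidence interval of the control mean
AND beats the control mean by at least 1 mM.  Stage 2 confirms triplicates:
the mean titer must exceed the control CI, the titer gain must be >= +10%,
and biomass loss no worse than -35%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenRecord",
    "ControlStats",
    "ScreenDecision",
    "percent_improvement",
    "round_half_away",
    "control_ci",
    "stage1_select",
    "stage2_confirm",
    "compare_titers",
    "read_screen_table",
]


@dataclass(frozen=True)
class ScreenRecord:
    """One end-point measurement: strain, plate, titer (mM) and final OD600."""

    strain_id: str
    plate_id: str
    replicate: int
    titer: float
    biomass: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.titer < 0 or self.biomass < 0:
            raise ValueError("titer and biomass must be non-negative")


@dataclass(frozen=True)
class ControlStats:
    plate_id: str
    mean_titer: float
    sd_titer: float
    n: int
    ci90: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.ci90
        if not (low <= self.mean_titer <= high):
            raise ValueError("confidence interval must bracket the mean")


@dataclass(frozen=True)
class ScreenDecision:
    strain_id: str
    stage: int
    titer_improvement: Optional[float]  # percent vs same-plate control mean
    biomass_change: Optional[float]  # percent
    passed: bool
    reasons: tuple[str, ...] = ()


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_improvement(variant_titer: float, control_titer: float) -> float:
    """Percent titer change of a variant versus its same-plate control mean,
    100 x (variant/control - 1).  Use :func:`round_half_away` for display;
    decisions always use the unrounded value."""
    if control_titer <= 0:
        raise ValueError("control titer must be positive")
    return 100.0 * (variant_titer / control_titer - 1.0)


def control_ci(
    control_titers: Sequence[float], level: float = 0.90, plate_id: str = ""
) -> ControlStats:
    """Two-sided t-confidence interval for the control mean titer."""
    titers = np.asarray(control_titers, dtype=float)
    n = len(titers)
    if n < 2:
        raise ValueError("need at least 2 control measurements for a confidence interval")
    mean = float(titers.mean())
    sd = float(titers.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sd / math.sqrt(n)
    return ControlStats(
        plate_id=plate_id,
        mean_titer=mean,
        sd_titer=sd,
        n=n,
        ci90=(mean - half, mean + half),
    )


def _split_plate(records: Sequence[ScreenRecord]) -> tuple[list[ScreenRecord], list[ScreenRecord]]:
    plates = {r.plate_id for r in records}
    if len(plates) > 1:
        raise ValueError(
            f"records span plates {sorted(plates)}; variants must be compared "
            "to controls on their own plate"
        )
    controls = [r for r in records if r.is_control]
    variants = [r for r in records if not r.is_control]
    if not controls:
        raise ValueError("plate has no control measurements")
    return controls, variants


def stage1_select(
    records: Sequence[ScreenRecord],
    level: float = 0.90,
    min_titer_gain_mm: float = 1.0,
) -> list[ScreenDecision]:
    """First characterization round: single measurements, no replicates.

    A variant passes when its titer exceeds the upper bound of the control
    mean's two-sided 90% CI and is at least ``min_titer_gain_mm`` (1 mM)
    above the control mean.  Decisions are independent of record order."""
    controls, variants = _split_plate(records)
    cs = control_ci([c.titer for c in controls], level=level, plate_id=controls[0].plate_id)
    control_biomass = float(np.mean([c.biomass for c in controls]))
    decisions = []
    for v in sorted(variants, key=lambda r: (r.strain_id, r.replicate)):
        reasons = []
        above_ci = v.titer > cs.ci90[1]
        above_gain = v.titer >= cs.mean_titer + min_titer_gain_mm
        if not above_ci:
            reasons.append(f"titer {v.titer:.2f} mM within control CI90 (upper {cs.ci90[1]:.2f})")
        if not above_gain:
            reasons.append(
                f"gain {v.titer - cs.mean_titer:+.2f} mM below {min_titer_gain_mm:.1f} mM threshold"
            )
        decisions.append(
            ScreenDecision(
                strain_id=v.strain_id,
                stage=1,
                titer_improvement=percent_improvement(v.titer, cs.mean_titer),
                biomass_change=(
                    percent_improvement(v.biomass, control_biomass) if control_biomass > 0 else None
                ),
                passed=above_ci and above_gain,
                reasons=tuple(reasons),
            )
        )
    return decisions


def stage2_confirm(
    variant_records: Sequence[ScreenRecord],
    control_records: Sequence[ScreenRecord],
    level: float = 0.90,
    min_titer_gain: float = 0.10,
    max_biomass_loss: float = 0.35,
    n_replicates: int = 3,
) -> ScreenDecision:
    """Second characterization round: technical triplicates.

    Improved iff the variant's mean titer exceeds the control CI90 upper
    bound, the relative titer gain is >= +10% (10.0% passes) and biomass
    formation dropped by no more than 35%."""
    if len(variant_records) < n_replicates or len(control_records) < n_replicates:
        raise ValueError(f"stage 2 requires {n_replicates} replicates of variant and control")
    plate_ids = {r.plate_id for r in list(variant_records) + list(control_records)}
    if len(plate_ids) > 1:
        raise ValueError("variant and control replicates must share one plate")
    cs = control_ci([c.titer for c in control_records], level=level, plate_id=control_records[0].plate_id)
    v_titer = float(np.mean([v.titer for v in variant_records]))
    v_biomass = float(np.mean([v.biomass for v in variant_records]))
    c_biomass = float(np.mean([c.biomass for c in control_records]))
    titer_impr = percent_improvement(v_titer, cs.mean_titer)
    biomass_change = percent_improvement(v_biomass, c_biomass) if c_biomass > 0 else None

    reasons = []
    above_ci = v_titer > cs.ci90[1]
    enough_gain = titer_impr >= 100.0 * min_titer_gain
    biomass_ok = biomass_change is None or biomass_change >= -100.0 * max_biomass_loss
    if not above_ci:
        reasons.append(f"mean titer {v_titer:.2f} mM within control CI90 (upper {cs.ci90[1]:.2f})")
    if not enough_gain:
        reasons.append(f"titer improvement {titer_impr:+.1f}% below +{100 * min_titer_gain:.0f}%")
    if not biomass_ok:
        reasons.append(
            f"biomass change {biomass_change:+.1f}% worse than -{100 * max_biomass_loss:.0f}%"
        )
    return ScreenDecision(
        strain_id=variant_records[0].strain_id,
        stage=2,
        titer_improvement=titer_impr,
        biomass_change=biomass_change,
        passed=above_ci and enough_gain and biomass_ok,
        reasons=tuple(reasons),
    )


def compare_titers(
    sample_a: Sequence[float], sample_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test on titers (Student pooled-variance by
    default, Welch on request).  Degenerate zero-variance samples with equal
    means report (0, 1); unequal means with zero variance report p=0."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def read_screen_table(source) -> list[ScreenRecord]:
    """Read ScreenRecords from a TSV with columns strain, plate, replicate,
    titer, biomass (OD600), is_control."""
    df = pd.read_csv(source, sep="\t")
    required = ["strain", "plate", "replicate", "titer", "biomass", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    return [
        ScreenRecord(
            strain_id=str(row.strain),
            plate_id=str(row.plate),
            replicate=int(row.replicate),
            titer=float(row.titer),
            biomass=float(row.biomass),
            is_control=bool(row.is_control),
        )
        for row in df.itertuples()
    ]
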