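"""End-product stoichiometry of ethanol–H2 fermentation under ethanol stress.

Ethanoligenens harbinense ferments glucose to ethanol, acetic acid, H2 and CO2.
When exogenous ethanol is added to the medium, the endogenous (cell-produced)
ethanol must be recovered by deducting the added amount from the measured
total; the ethanol-to-acetate molar ratio and the weight fraction of ethanol
among liquid end-products then summarize how far the fermentation has shifted
from acetate- toward ethanol-type metabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .errors import DegenerateInputError, ValidationError

#: Molar mass of ethanol, g mol^-1 (so 1 mM ethanol = 46.07 mg L^-1).
M_ETHANOL = 46.07
#: Molar mass of acetic acid, g mol^-1.
M_ACETATE = 60.05


@dataclass(frozen=True)
class FermentationRecord:
    """End-point yields of one batch culture at a given exogenous ethanol level."""

    condition_mM: float
    ethanol_total_mg_L: float
    acetate_mg_L: float | None = None
    h2_mL_L: float | None = None
    co2_mL_L: float | None = None
    cdw_mg_L: float | None = None

    def __post_init__(self) -> None:
        for name in ("condition_mM", "ethanol_total_mg_L", "acetate_mg_L", "h2_mL_L",
                     "co2_mL_L", "cdw_mg_L"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class StoichiometrySummary:
    """Derived stoichiometric quantities for one condition."""

    condition_mM: float
    ethanol_endog_mg_L: float
    ethanol_mM: float
    acetate_mM: float | None
    molar_ratio: float | None  # ethanol / acetate, mol/mol
    ethanol_weight_pct: float | None  # % (w/w) of liquid end-products
    fold_vs_control: float | None  # molar ratio relative to the control condition


def ethanol_mM_to_mg_L(mM: float) -> float:
    return mM * M_ETHANOL


def endogenous_ethanol(total_mg_L: float, exogenous_mM: float, rel_tol: float = 0.05) -> float:
    """Endogenous ethanol yield: measured total minus the exogenously added mass.

    Slightly negative differences (within ``rel_tol`` of the exogenous mass, a
    measurement-error allowance) clamp to 0; grossly negative differences mean
    the inputs are inconsistent and raise.
    """
    if total_mg_L < 0 or exogenous_mM < 0:
        raise ValidationError("yields and concentrations must be >= 0")
    exo_mass = ethanol_mM_to_mg_L(exogenous_mM)
    endog = total_mg_L - exo_mass
    if endog < 0:
        if exo_mass > 0 and -endog <= rel_tol * exo_mass:
            return 0.0
        raise ValidationError(
            f"measured total ethanol {total_mg_L} mg/L is far below the exogenous "
            f"addition {exo_mass:.1f} mg/L"
        )
    return endog


def molar_ratio(ethanol_mg_L: float, acetate_mg_L: float) -> float:
    """Ethanol-to-acetate molar ratio from mass concentrations."""
    if ethanol_mg_L < 0 or acetate_mg_L < 0:
        raise ValidationError("concentrations must be >= 0")
    if acetate_mg_L == 0:
        raise DegenerateInputError("molar ratio undefined at zero acetate")
    return (ethanol_mg_L / M_ETHANOL) / (acetate_mg_L / M_ACETATE)


def weight_percent_ethanol(ethanol_mg_L: float, acetate_mg_L: float) -> float:
    """Ethanol as % (w/w) of the liquid end-products (ethanol + acetate)."""
    if ethanol_mg_L < 0 or acetate_mg_L < 0:
        raise ValidationError("concentrations must be >= 0")
    total = ethanol_mg_L + acetate_mg_L
    if total == 0:
        raise DegenerateInputError("weight percentage undefined when both products are zero")
    return 100.0 * ethanol_mg_L / total


def summarize(
    records: Iterable[FermentationRecord], control_mM: float = 0.0
) -> list[StoichiometrySummary]:
    """Per-condition stoichiometry plus the molar-ratio fold change vs control.

    The control condition must be present and carry an acetate measurement.
    Conditions lacking an acetate value get None for the acetate-dependent
    quantities.  Output is sorted by condition.
    """
    records = sorted(records, key=lambda r: r.condition_mM)
    control = next((r for r in records if r.condition_mM == control_mM), None)
    if control is None:
        raise ValidationError(f"control condition {control_mM} mM missing from the table")
    if control.acetate_mg_L is None or control.acetate_mg_L == 0:
        raise ValidationError("control condition needs a positive acetate yield")

    ctrl_endog = endogenous_ethanol(control.ethanol_total_mg_L, control.condition_mM)
    ctrl_ratio = molar_ratio(ctrl_endog, control.acetate_mg_L)

    out = []
    for r in records:
        endog = endogenous_ethanol(r.ethanol_total_mg_L, r.condition_mM)
        if r.acetate_mg_L is not None and r.acetate_mg_L > 0:
            ratio = molar_ratio(endog, r.acetate_mg_L)
            wpct = weight_percent_ethanol(endog, r.acetate_mg_L)
            fold = ratio / ctrl_ratio
        else:
            ratio = wpct = fold = None
        out.append(
            StoichiometrySummary(
                condition_mM=r.condition_mM,
                ethanol_endog_mg_L=endog,
                ethanol_mM=endog / M_ETHANOL,
                acetate_mM=None if r.acetate_mg_L is None else r.acetate_mg_L / M_ACETATE,
                molar_ratio=ratio,
                ethanol_weight_pct=wpct,
                fold_vs_control=fold,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reference batch measurements (worked example)
# ---------------------------------------------------------------------------

#: Published end-point yields for E. harbinense YUAN-3 under 0–200 mM exogenous
#: ethanol: acetate at the 0 and 200 mM end points, endogenous ethanol at
#: 100 mM, relative endogenous-ethanol increases vs control, H2 end points.
#: Acetate at 50 and 100 mM was reported graphically only and is left NA.
_ENDOG_100_MG_L = 4030.4
_REL_INCREASE = {0: 0.0, 50: 0.151, 100: 0.301, 200: 0.274}
_ACETATE_MG_L = {0: 1767.7, 200: 160.6}
_H2_ML_L = {0: 1888.6, 200: 837.0}
_CDW_MG_L = {200: 544.0}


def reference_yield_table() -> list[FermentationRecord]:
    """The reference ethanol-stress yield table used in the worked example.

    Endogenous ethanol at the control is recovered from the reported 100 mM
    yield and its relative increase; totals add back the exogenous mass so the
    table round-trips through :func:`endogenous_ethanol`.
    """
    ctrl_endog = _ENDOG_100_MG_L / (1 + _REL_INCREASE[100])
    out = []
    for cond, rel in _REL_INCREASE.items():
        endog = ctrl_endog * (1 + rel)
        out.append(
            FermentationRecord(
                condition_mM=float(cond),
                ethanol_total_mg_L=endog + ethanol_mM_to_mg_L(cond),
                acetate_mg_L=_ACETATE_MG_L.get(cond),
                h2_mL_L=_H2_ML_L.get(cond),
                cdw_mg_L=_CDW_MG_L.get(cond),
            )
        )
    return out
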