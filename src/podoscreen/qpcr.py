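"""Pfaffl relative quantification for RT-qPCR fold changes.

The fold change of a target transcript relative to a reference
(housekeeping) gene, corrected for per-assay amplification efficiency:

    ratio = E_target ** dCt_target / E_ref ** dCt_ref

where E is the amplification efficiency per cycle (2 = perfect doubling)
and dCt = Ct(control) - Ct(treated).  With that sign convention an
upregulated target gives a fold > 1.  Efficiencies default to 2; with
E_target = E_ref = 2 the expression reduces to the classic ddCt rule
2 ** (dCt_target - dCt_ref).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Efficiencies and delta-Ct values for one target/reference pair.

    delta_ct_* is Ct(control) - Ct(treated), in cycles.  Efficiencies must
    lie in (1, 2]: 1 would mean no amplification, 2 is perfect doubling.
    """

    delta_ct_target: float
    delta_ct_reference: float
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self):
        for name, e in (
            ("efficiency_target", self.efficiency_target),
            ("efficiency_reference", self.efficiency_reference),
        ):
            if not (1.0 < e <= 2.0):
                raise ParameterError(f"{name} must be in (1, 2], got {e}")
        for name, d in (
            ("delta_ct_target", self.delta_ct_target),
            ("delta_ct_reference", self.delta_ct_reference),
        ):
            if not math.isfinite(d):
                raise ParameterError(f"{name} must be finite, got {d}")


def pfaffl_fold_change(m: QpcrMeasurement) -> float:
    """Efficiency-corrected fold change E_t**dCt_t / E_r**dCt_r."""
    return (
        m.efficiency_target ** m.delta_ct_target
        / m.efficiency_reference ** m.delta_ct_reference
    )


def pfaffl_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the Pfaffl calculation to a table of measurements.

    Expects columns ``E_target, dCt_target, E_ref, dCt_ref`` (plus any
    passthrough columns such as ``sample``); returns a copy with a ``fold``
    column appended.
    """
    required = ["E_target", "dCt_target", "E_ref", "dCt_ref"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"missing columns: {missing}")
    out = df.copy()
    out["fold"] = [
        pfaffl_fold_change(
            QpcrMeasurement(
                delta_ct_target=row.dCt_target,
                delta_ct_reference=row.dCt_ref,
                efficiency_target=row.E_target,
                efficiency_reference=row.E_ref,
            )
        )
        for row in df.itertuples()
    ]
    return out
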