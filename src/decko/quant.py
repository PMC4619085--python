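"""Knockout-evaluation arithmetic: relative expression and stain index.

relative_expression implements the comparative-Ct method. Writing
dCt = Ct(target) - Ct(housekeeping) for the sample and dCc for the
calibrator, the fold change is 2^-(dCt - dCc), i.e. 2^-ddCt: one extra
cycle to threshold means half the starting template. A strict "as-printed"
mode with the opposite sign (2^+(Ct-Cc), under which more template would
read as lower expression) is kept behind a flag for comparison against
worksheets that use that convention.

stain_index is the flow-cytometry separation measure
(mean positive - mean background) / (2 * SD background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd


class QuantError(ValueError):
    pass


def _finite_positive(value: float, name: str) -> float:
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise QuantError(f"{name} must be finite and > 0, got {value!r}")
    return v


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values for target and housekeeping genes, sample and calibrator."""

    ct_target: float
    ct_housekeeping: float
    cc_target: float
    cc_housekeeping: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_housekeeping", "cc_target", "cc_housekeeping"):
            object.__setattr__(self, name, _finite_positive(getattr(self, name), name))

    @property
    def ddct(self) -> float:
        return (self.ct_target - self.ct_housekeeping) - \
               (self.cc_target - self.cc_housekeeping)


def relative_expression(m: QpcrMeasurement, as_printed: bool = False) -> float:
    """Fold change of the sample relative to the calibrator.

    Default: 2^-ddCt (1.0 when sample and calibrator are identical; ddCt of
    +1 halves it). as_printed=True flips the exponent sign.
    """
    exponent = m.ddct if as_printed else -m.ddct
    return 2.0 ** exponent


@dataclass(frozen=True)
class FlowStats:
    """Fluorescence summary of a stained population vs. background."""

    mean_pos: float
    mean_bg: float
    sd_bg: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.mean_pos, self.mean_bg, self.sd_bg)):
            raise QuantError("flow statistics must be finite")
        if self.sd_bg <= 0:
            raise QuantError(f"sd_bg must be > 0, got {self.sd_bg}")


def stain_index(f: FlowStats) -> float:
    """(mean positive - mean background) / (2 * SD background)."""
    return (f.mean_pos - f.mean_bg) / (2.0 * f.sd_bg)


def expression_table(measurements: Iterable[tuple[str, QpcrMeasurement]],
                     as_printed: bool = False) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample": name, "ddct": m.ddct,
         "fold_change": relative_expression(m, as_printed=as_printed)}
        for name, m in measurements
    ])


def read_ct_table(path) -> list[tuple[str, QpcrMeasurement]]:
    """TSV with columns sample, ct_target, ct_housekeeping, cc_target, cc_housekeeping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"sample", "ct_target", "ct_housekeeping", "cc_target", "cc_housekeeping"}
    if not needed <= set(df.columns):
        raise QuantError(f"Ct table needs columns {sorted(needed)}")
    return [
        (str(r["sample"]), QpcrMeasurement(r["ct_target"], r["ct_housekeeping"],
                                           r["cc_target"], r["cc_housekeeping"]))
        for _, r in df.iterrows()
    ]
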