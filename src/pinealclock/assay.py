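"""Four-parameter-logistic radioimmunoassay calibration.

The melatonin RIA calibration curve is the standard 4PL

    y = (A - D) / (1 + (x / C)**B) + D

with A the zero-dose (maximal binding) response, D the infinite-dose
response, C the mid-dose and B the slope.  With A > D and B > 0 the curve
is strictly decreasing, y(0) = A, y(C) = (A + D)/2 and y -> D as x -> inf.
The fitted constants of the turkey melatonin assay are A = 1380,
B = 0.95, C = 45.7, D = -1.2 (response in bound counts, x in assay dose
units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FourPLParams:
    A: float = 1380.0
    B: float = 0.95
    C: float = 45.7
    D: float = -1.2

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("slope B must be positive")
        if self.C <= 0:
            raise ValueError("mid-dose C must be positive")
        if self.A == self.D:
            raise ValueError("A and D must differ")

    def to_json(self) -> str:
        return json.dumps({"A": self.A, "B": self.B, "C": self.C, "D": self.D})

    @classmethod
    def from_json(cls, text: str) -> "FourPLParams":
        d = json.loads(text)
        return cls(A=d["A"], B=d["B"], C=d["C"], D=d["D"])


def fourpl(x, p: FourPLParams = FourPLParams()):
    """Forward calibration curve: dose -> response."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    y = (p.A - p.D) / (1.0 + (x / p.C) ** p.B) + p.D
    return float(y) if y.ndim == 0 else y


def invert_fourpl(y, p: FourPLParams = FourPLParams()):
    """Inverse calibration: response -> dose, x = C*((A-D)/(y-D) - 1)**(1/B).

    Defined for y strictly between D and A (assuming A > D); responses
    outside that open interval are unquantifiable.
    """
    y = np.asarray(y, dtype=float)
    lo, hi = min(p.A, p.D), max(p.A, p.D)
    if np.any(y <= lo) or np.any(y >= hi):
        raise ValueError(f"response outside the quantifiable range ({lo}, {hi})")
    x = p.C * ((p.A - p.D) / (y - p.D) - 1.0) ** (1.0 / p.B)
    return float(x) if x.ndim == 0 else x
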