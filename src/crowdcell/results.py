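"""Tabulated scan results with the located optimum."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ScanResult:
    """A grid scan: one row per grid point, plus the located optimum.

    ``optimum`` maps observable names to their values at the optimum; the
    key ``'rho'`` is always present for occupancy scans.  Ties in the
    objective are broken toward the smallest rho.
    """

    table: pd.DataFrame
    objective: str
    optimum: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table is None or len(self.table) == 0:
            raise ValueError("empty scan result")

    @property
    def rho_opt(self) -> float:
        return self.optimum["rho"]


def argmax_with_ties(df: pd.DataFrame, column: str, tie_tol: float = 1e-12) -> int:
    """Index of the maximum of ``column``; ties broken toward smaller rho.

    Rows whose value is within ``tie_tol`` (relative) of the maximum are
    considered tied; among them the one with the smallest ``rho`` wins.
    """
    vals = df[column].to_numpy()
    best = vals.max()
    tied = df.index[vals >= best - tie_tol * abs(best)]
    sub = df.loc[tied]
    return int(sub["rho"].idxmin()) if "rho" in df.columns else int(tied[0])
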