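"""Case-control empirical-risk calibration of score thresholds.

For HLA-selected case and control score sets, the empirical (actual) risk
above a threshold τ is

    risk(τ) = P(score > τ | case) / P(score > τ | control) × background risk

i.e. the likelihood ratio of exceedance times the assumed background risk of
the disease in the HLA-selected population (default 5%).  Sensitivity at τ is
the case exceedance proportion itself.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import wilson_ci

DEFAULT_BACKGROUND_RISK = 0.05
DEFAULT_STEP = 0.1


@dataclass
class CaseControlScores:
    case_scores: np.ndarray
    control_scores: np.ndarray
    background_risk: float = DEFAULT_BACKGROUND_RISK

    def __post_init__(self):
        self.case_scores = np.asarray(self.case_scores, dtype=float)
        self.control_scores = np.asarray(self.control_scores, dtype=float)
        if len(self.case_scores) == 0 or len(self.control_scores) == 0:
            raise ValueError("case and control score lists must be nonempty")
        if not 0.0 < self.background_risk < 1.0:
            raise ValueError("background_risk must lie in (0, 1)")


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    # anchored at the integer floor/ceil of the score range so runs reproduce
    # across machines regardless of sampling jitter in the extremes
    start = math.floor(lo)
    stop = math.ceil(hi)
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def empirical_risk_curve(
    data: CaseControlScores, step: float = DEFAULT_STEP
) -> pd.DataFrame:
    """Empirical risk and sensitivity on a fixed-step threshold grid.

    Grid spans floor(min score) to ceil(max score) in units of ``step``.
    At each τ (strict '>'): ``empirical_risk = p_case/p_ctrl × background``;
    thresholds where no control exceeds τ are flagged ``risk_defined=False``.
    Risks above 100% are reported as-is with a warning.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    allv = np.concatenate([data.case_scores, data.control_scores])
    grid = _grid(allv.min(), allv.max(), step)
    if len(grid) == 0:
        raise ValueError("empty threshold grid")

    n_case, n_ctrl = len(data.case_scores), len(data.control_scores)
    rows = []
    for tau in grid:
        k_case = int((data.case_scores > tau).sum())
        k_ctrl = int((data.control_scores > tau).sum())
        p_case, p_ctrl = k_case / n_case, k_ctrl / n_ctrl
        defined = k_ctrl > 0
        risk = p_case / p_ctrl * data.background_risk if defined else np.nan
        lo, hi = wilson_ci(k_case, n_case)
        rows.append(
            {
                "threshold": float(tau),
                "prop_cases_above": p_case,
                "prop_controls_above": p_ctrl,
                "empirical_risk": risk,
                "risk_defined": defined,
                "sensitivity": p_case,
                "sens_ci_low": lo,
                "sens_ci_high": hi,
            }
        )
    curve = pd.DataFrame(rows)
    if (curve["empirical_risk"].dropna() > 1.0).any():
        warnings.warn("empirical risk exceeds 100% at some thresholds", stacklevel=2)
    return curve


def find_threshold_for_risk(curve: pd.DataFrame, target_risk: float) -> pd.Series:
    """Smallest grid threshold whose (defined) empirical risk ≥ target.

    Returns the full curve row (threshold, risk, sensitivity, ...).
    """
    if not 0.0 < target_risk < 1.0:
        raise ValueError("target_risk must lie in (0, 1)")
    ok = curve[curve["risk_defined"] & (curve["empirical_risk"] >= target_risk)]
    if ok.empty:
        attained = curve.loc[curve["risk_defined"], "empirical_risk"].max()
        raise ValueError(
            f"target risk {target_risk:.3f} never reached; max attained "
            f"{attained:.4f}"
        )
    return ok.iloc[0]


def read_score_file(path) -> np.ndarray:
    """Read a single-column score file (one float per line, optional header)."""
    vals = pd.read_csv(path, header=None).iloc[:, 0]
    vals = pd.to_numeric(vals, errors="coerce").dropna()
    return vals.to_numpy(dtype=float)
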