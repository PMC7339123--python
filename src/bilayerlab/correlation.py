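"""Descriptor-effect correlation screening with Fisher-transform CIs.

Physicochemical descriptors of the tested compounds (LogD and LogP
octanol/water lipophilicity, gas-phase dipole moment mu) are screened
against the measured membrane effects (potential-shift maxima,
desorption constant, melting-temperature shift, peak broadening,
leakage plateau).  For each pair the Pearson coefficient r is reported
with a confidence interval from the Fisher z-transformation,

    z = atanh(r),  z +/- z_crit(alpha) / sqrt(n - 3),

back-transformed through tanh; the pair is called significant when the
interval excludes zero.  Spearman rank correlations confirm monotone
association, except for dipole-moment-vs-potential pairs where theory
(parallel-plate capacitor) predicts a *linear* relation and a rank
statistic would not add information, so those cells are left absent by
rule.  Missing entries are pairwise-deleted, which is why n varies
between cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: effect columns for which Spearman confirmation is skipped against mu
POTENTIAL_EFFECTS = frozenset({"dphi_b_max", "dphi_d_max"})
DIPOLE_DESCRIPTOR = "dipole_moment"


@dataclass
class CorrelationResult:
    r: float | None = None
    n: int = 0
    ci_low: float | None = None
    ci_high: float | None = None
    alpha: float = 0.1
    significant: bool = False
    spearman_rho: float | None = None
    ok: bool = True
    reason: str | None = None


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fisher_interval(r: float, n: int, alpha: float = 0.1) -> tuple[float, float]:
    """Fisher-transform confidence interval for a Pearson coefficient."""
    r_c = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(r_c)
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_fisher(x, y, alpha: float = 0.1) -> CorrelationResult:
    """Pearson r with a Fisher-transform CI; significance = CI excludes 0.

    Missing entries (NaN) are pairwise-deleted.  Requires >= 4 complete
    pairs; zero variance in either variable yields an undefined result
    with a reason code.
    """
    xv, yv = _complete_pairs(x, y)
    n = int(xv.size)
    if n < 4:
        return CorrelationResult(n=n, alpha=alpha, ok=False, reason="fewer_than_4_pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(n=n, alpha=alpha, ok=False, reason="zero_variance")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = float(np.clip(r, -1.0, 1.0))
    lo, hi = fisher_interval(r, n, alpha)
    return CorrelationResult(
        r=r, n=n, ci_low=lo, ci_high=hi, alpha=alpha, significant=not (lo <= 0.0 <= hi)
    )


def spearman_rank(x, y) -> float:
    """Spearman rank correlation with midranks for ties.

    NaN pairs are deleted; raises on zero rank variance.
    """
    xv, yv = _complete_pairs(x, y)
    if xv.size < 4:
        raise ValueError("need >= 4 complete pairs")
    rx = sps.rankdata(xv, method="average")
    ry = sps.rankdata(yv, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance; Spearman undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def effect_descriptor_screen(
    descriptors: pd.DataFrame,
    effects: pd.DataFrame,
    alpha: float = 0.1,
    spearman_exclusions: frozenset = POTENTIAL_EFFECTS,
) -> dict[tuple[str, str], CorrelationResult]:
    """Full descriptor x effect correlation matrix.

    Both tables are indexed by compound; rows are aligned on the index
    union and missing entries pairwise-deleted per cell, so n varies
    between cells.  Spearman confirmation is attached to every cell
    except ``dipole_moment`` against the potential-shift effects (see
    module docstring).  Cells with fewer than 4 overlapping compounds
    are marked not-computable.
    """
    joined = descriptors.join(effects, how="outer", lsuffix="", rsuffix="_effect")
    out: dict[tuple[str, str], CorrelationResult] = {}
    for d_col in descriptors.columns:
        for e_col in effects.columns:
            res = pearson_fisher(joined[d_col], joined[e_col], alpha=alpha)
            if res.ok and not (d_col == DIPOLE_DESCRIPTOR and e_col in spearman_exclusions):
                try:
                    res.spearman_rho = spearman_rank(joined[d_col], joined[e_col])
                except ValueError:
                    res.spearman_rho = None
            out[(d_col, e_col)] = res
    return out


def screen_to_frame(screen: dict[tuple[str, str], CorrelationResult]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of a correlation screen."""
    rows = []
    for (d, e), r in screen.items():
        rows.append(
            {
                "descriptor": d,
                "effect": e,
                "r": r.r,
                "n": r.n,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "alpha": r.alpha,
                "significant": r.significant,
                "spearman_rho": r.spearman_rho,
                "ok": r.ok,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
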