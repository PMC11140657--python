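"""Behavioral scoring and auxiliary statistics.

Recognition accuracy is the corrected recognition score (hit rate minus
false-alarm rate) and the effect of cueing is the cueing benefit (cued minus
uncued corrected recognition). Supporting statistics: one-sample t tests
with Benjamini-Hochberg FDR adjustment, circular-linear correlation
(phase vs. a linear variable), the Watson-Williams test for equal mean
directions, robust (IRLS, Tukey bisquare) regression, and hypnogram-derived
sleep-architecture summaries.

Linear mixed-effects modeling is deliberately not implemented here; the
module exports tidy long-format tables ready for external fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sigio import Hypnogram


# ---------------------------------------------------------------------------
# Recognition scoring
# ---------------------------------------------------------------------------

def corrected_recognition(hit_rate: float, fa_rate: float) -> float:
    """Hit rate minus false-alarm rate, in [-1, 1]."""
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    return hit_rate - fa_rate


def cueing_benefit(cued_cr: float, uncued_cr: float) -> float:
    """Cued minus uncued corrected recognition; positive = cueing helped."""
    return cued_cr - uncued_cr


def score_behavior(items: pd.DataFrame) -> pd.DataFrame:
    """Per-participant condition scores from an item-level response table.

    Expects columns participant, component, emotion, cue, old_new, response.
    Hits are "old" responses to old items; false alarms are "old" responses
    to new items (per emotion for objects; one pooled rate for backgrounds,
    whose lures are all neutral). Returns one row per participant x emotion x
    component with hit_rate, fa_rate, corrected recognition for cued and
    uncued items, and the cueing benefit.
    """
    rows = []
    for pid, d in items.groupby("participant"):
        old = d[d.old_new == "old"]
        new = d[d.old_new == "new"]
        fa = {
            ("negative", "object"): _rate(new, "negative", "object"),
            ("neutral", "object"): _rate(new, "neutral", "object"),
        }
        fa_bg = (new[new.component == "background"].response == "old").mean()
        for emotion in ("negative", "neutral"):
            for component in ("object", "background"):
                fa_rate = fa_bg if component == "background" else fa[(emotion, component)]
                cell = old[(old.emotion == emotion) & (old.component == component)]
                hit_cued = (cell[cell.cue == "cued"].response == "old").mean()
                hit_uncued = (cell[cell.cue == "uncued"].response == "old").mean()
                cr_cued = corrected_recognition(hit_cued, fa_rate)
                cr_uncued = corrected_recognition(hit_uncued, fa_rate)
                rows.append({
                    "participant": pid, "emotion": emotion,
                    "component": component,
                    "hit_rate_cued": hit_cued, "hit_rate_uncued": hit_uncued,
                    "fa_rate": fa_rate,
                    "cr_cued": cr_cued, "cr_uncued": cr_uncued,
                    "cueing_benefit": cueing_benefit(cr_cued, cr_uncued),
                })
    return pd.DataFrame(rows)


def _rate(new: pd.DataFrame, emotion: str, component: str) -> float:
    cell = new[(new.emotion == emotion) & (new.component == component)]
    return (cell.response == "old").mean()


def to_long_format(scores: pd.DataFrame) -> pd.DataFrame:
    """Tidy long table (participant, emotion, component, cue, score) for
    external mixed-effects fitting."""
    long = scores.melt(
        id_vars=["participant", "emotion", "component"],
        value_vars=["cr_cued", "cr_uncued"],
        var_name="cue", value_name="corrected_recognition",
    )
    long["cue"] = long["cue"].map({"cr_cued": "cued", "cr_uncued": "uncued"})
    return long


# ---------------------------------------------------------------------------
# Classical statistics
# ---------------------------------------------------------------------------

def one_sample_t(values: np.ndarray, mu: float = 0.0) -> tuple[float, int, float]:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if values.std(ddof=1) == 0:
        # degenerate: no variability
        if values[0] == mu:
            return 0.0, int(values.size - 1), 1.0
        return float(np.inf * np.sign(values[0] - mu)), int(values.size - 1), 0.0
    res = stats.ttest_1samp(values, mu)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    from statsmodels.stats.multitest import fdrcorrection

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    if p.size == 1:
        return p.copy()
    _, adj = fdrcorrection(p, alpha=0.05, method="indep")
    return adj


def circ_linear_corr(phases_deg: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Circular-linear correlation between phases (degrees) and a linear
    variable, with an asymptotic chi-square (2 df) p value.

    r^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2) where r_xc,
    r_xs, r_cs are the Pearson correlations of the variable with cos(phase),
    sin(phase), and of cos with sin.
    """
    phi = np.deg2rad(np.asarray(phases_deg, dtype=float))
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0:
        raise ValueError("linear variable is constant")
    c, s = np.cos(phi), np.sin(phi)
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    r2 = (rxc ** 2 + rxs ** 2 - 2 * rxc * rxs * rcs) / (1 - rcs ** 2)
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(stats.chi2.sf(x.size * r ** 2, df=2))
    return r, p


def watson_williams(
    phases_a_deg: np.ndarray, phases_b_deg: np.ndarray
) -> tuple[float, float, bool]:
    """Watson-Williams test for a common mean direction of two samples.

    Returns (F, p, assumptions_ok). The test assumes von Mises samples with
    adequate concentration; ``assumptions_ok`` is False when the pooled
    resultant length is below 0.45 (the usual validity guideline).
    """
    a = np.deg2rad(np.asarray(phases_a_deg, dtype=float))
    b = np.deg2rad(np.asarray(phases_b_deg, dtype=float))
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 observations")
    n1, n2 = a.size, b.size
    n = n1 + n2
    r1 = np.abs(np.exp(1j * a).sum())
    r2 = np.abs(np.exp(1j * b).sum())
    if r1 == 0 or r2 == 0:
        raise ValueError("degenerate (zero-resultant) group")
    rall = np.abs(np.exp(1j * np.concatenate([a, b])).sum())
    rbar = (r1 + r2) / n
    assumptions_ok = bool(rbar >= 0.45)
    # correction factor for the F approximation
    kappa = _kappa_from_rbar(rbar)
    corr = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (n - 2) * (r1 + r2 - rall)
    den = n - (r1 + r2)
    if den <= 0:
        return 0.0, 1.0, assumptions_ok
    F = float(corr * num / den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, n - 2))
    return F, p, assumptions_ok


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from a resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


@dataclass
class RobustFit:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    weights: np.ndarray


def robust_regress(y: np.ndarray, X: np.ndarray, add_const: bool = True) -> RobustFit:
    """Robust linear regression: IRLS with Tukey bisquare weights
    (tuning constant 4.685), down-weighting outliers."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_const:
        X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(conv="coefs", tol=1e-8)
    try:
        w = np.asarray(res.weights)
    except AttributeError:  # perfect fit: IRLS exits before weighting
        w = np.ones(y.size)
    return RobustFit(np.asarray(res.params), np.asarray(res.bse),
                     np.asarray(res.pvalues), w)


# ---------------------------------------------------------------------------
# Sleep architecture
# ---------------------------------------------------------------------------

@dataclass
class SleepArchitecture:
    tst_min: float
    sol_min: float
    waso_min: float
    efficiency_pct: float
    stage_pct: dict[str, float]   # % of TST for N1/N2/N3/REM


def sleep_architecture(hyp: Hypnogram) -> SleepArchitecture:
    """Summary statistics of a night from its hypnogram.

    Time in bed is the scored span; sleep onset latency is the time to the
    first non-wake epoch; WASO is wake time after sleep onset.
    """
    ep_min = hyp.epoch_length_s / 60.0
    stages = hyp.stages
    sleep = [s != "W" for s in stages]
    if not any(sleep):
        raise ValueError("no sleep epochs")
    first = sleep.index(True)
    tst = sum(sleep) * ep_min
    sol = first * ep_min
    waso = sum(1 for s in stages[first:] if s == "W") * ep_min
    tib = len(stages) * ep_min
    pct = {
        st: 100.0 * sum(s == st for s in stages) * ep_min / tst
        for st in ("N1", "N2", "N3", "REM")
    }
    return SleepArchitecture(tst, sol, waso, 100.0 * tst / tib, pct)
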