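"""Proficiency analysis: how effect sizes depend on L2 proficiency.

Per-participant slowdown (or difference) effects are relate to proficiency as
measured by the Michigan English Placement Test (MPT, 0-50; native speakers
enter with the maximum score of 50 but keep a 0/1 nativeness indicator). Five
regression tests probe the shape of the relationship:

  m1: response ~ s(MPT)                — is there any (possibly nonlinear)
                                         proficiency effect? (smooth-term test)
  m2: response ~ MPT + MPT^2           — is the relation curved? (quadratic term)
  m3: response ~ English + MPT         — above-median-MPT participants only:
                                         do top L2 readers differ from natives?
  m4: response ~ English + MPT + MPT^2 — all participants, nativeness term
  m5: response ~ MPT                   — above-median participants: do effects
                                         still grow as proficiency drops?

MPT scores map onto CEFR bands via a fixed lookup, and the percentage of
correctly answered comprehension questions can substitute for the MPT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gam import ModelSpec, SmoothTerm, fit_model, significance_stars

__all__ = [
    "mpt_to_cefr",
    "CEFR_BANDS",
    "fit_proficiency_curve",
    "run_tests",
    "comprehension_proficiency",
    "ProficiencyTestResults",
]

# (low, high, band) — inclusive bounds
CEFR_BANDS = (
    (0, 16, "A1"),
    (17, 21, "A2"),
    (22, 31, "B1"),
    (32, 36, "B2"),
    (37, 50, "C1"),
)


def mpt_to_cefr(score: int) -> str:
    """CEFR band for an MPT score per the standard lookup
    (0-16 A1, 17-21 A2, 22-31 B1, 32-36 B2, 37-50 C1)."""
    if not float(score).is_integer():
        raise ValueError(f"MPT score must be an integer, got {score!r}")
    score = int(score)
    for lo, hi, band in CEFR_BANDS:
        if lo <= score <= hi:
            return band
    raise ValueError(f"MPT score {score} outside [0, 50]")


def fit_proficiency_curve(
    records: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    k: int = 10,
    grid: np.ndarray | None = None,
) -> dict:
    """Penalized-spline curve of response on MPT through the L2 records, with
    a bootstrap 95% band (resampling records with replacement), plus the L1
    reference mean with a normal-approximation CI.

    ``records`` needs columns mpt, english (0/1) and response.
    """
    l2 = records[records["english"] == 0]
    if len(l2) < 20:
        raise ValueError("need at least 20 L2 records for a proficiency curve")
    if l2["mpt"].nunique() < 3:
        raise ValueError("all (or nearly all) MPT values identical; no curve to fit")
    if grid is None:
        grid = np.linspace(l2["mpt"].min(), l2["mpt"].max(), 41)
    grid = np.asarray(grid, dtype=float)
    spec = ModelSpec("response", (SmoothTerm("mpt", k),), name="proficiency_curve")
    fit = fit_model(spec, l2, keep_cov=False)
    curve = fit.intercept + fit.partial_effect("mpt", grid)

    rng = np.random.default_rng(seed)
    boot = np.empty((B, grid.size))
    n = len(l2)
    for b in range(B):
        idx = rng.integers(0, n, n)
        sample = l2.iloc[idx]
        if sample["mpt"].nunique() < 3:
            boot[b] = np.nan
            continue
        f = fit_model(spec, sample, keep_cov=False)
        boot[b] = f.intercept + f.partial_effect("mpt", grid)
    lower = np.nanquantile(boot, 0.025, axis=0)
    upper = np.nanquantile(boot, 0.975, axis=0)

    l1 = records.loc[records["english"] == 1, "response"].to_numpy(dtype=float)
    if l1.size >= 2:
        half = 1.959963984540054 * l1.std(ddof=1) / np.sqrt(l1.size)
        l1_mean, l1_ci = float(l1.mean()), (float(l1.mean() - half), float(l1.mean() + half))
    else:
        l1_mean, l1_ci = (float(l1.mean()) if l1.size else np.nan), (np.nan, np.nan)
    return {
        "grid": grid,
        "curve": curve,
        "lower": lower,
        "upper": upper,
        "l1_mean": l1_mean,
        "l1_ci": l1_ci,
        "fit": fit,
    }


@dataclass(frozen=True)
class ProficiencyTestResults:
    p_values: dict[str, float]
    estimates: dict[str, float]
    median_mpt: float
    n_above_median: int

    @property
    def stars(self) -> dict[str, str]:
        return {k: significance_stars(v) for k, v in self.p_values.items()}


def run_tests(records: pd.DataFrame, median_scope: str = "all", k: int = 10) -> ProficiencyTestResults:
    """Run the five proficiency-shape tests m1-m5 on per-participant records.

    ``records`` needs columns mpt, english (0/1 nativeness; L1 rows carry
    mpt = 50) and response. The above-median subset for m3/m5 excludes ties at
    the median; the median is computed over all records by default
    (``median_scope="l2"`` restricts it to L2 records).
    """
    for col in ("mpt", "english", "response"):
        if col not in records.columns:
            raise ValueError(f"records must have column {col!r}")
    if records["english"].nunique() < 2:
        raise ValueError("records must include both L1 and L2 participants")
    mpt = records["mpt"].to_numpy(dtype=float)
    y = records["response"].to_numpy(dtype=float)
    eng = records["english"].to_numpy(dtype=float)
    scope = mpt if median_scope == "all" else mpt[eng == 0]
    med = float(np.median(scope))
    above = mpt > med
    if not above.any():
        raise ValueError("above-median subset is empty")

    p: dict[str, float] = {}
    est: dict[str, float] = {}

    # m1: response ~ s(MPT), approximate test of the smooth term
    spec = ModelSpec("response", (SmoothTerm("mpt", k),), name="m1")
    fit = fit_model(spec, records)
    _, _, p["m1"] = fit.smooth_term_test("mpt")
    est["m1_edf"] = fit.edf["s(mpt)"]

    # m2: response ~ MPT + MPT^2, quadratic term
    X = sm.add_constant(np.column_stack([mpt, mpt**2]))
    m2 = sm.OLS(y, X).fit()
    p["m2"] = float(m2.pvalues[2])
    est["m2_quadratic"] = float(m2.params[2])

    # m3: response ~ English + MPT, above-median participants only
    X3 = sm.add_constant(np.column_stack([eng[above], mpt[above]]))
    m3 = sm.OLS(y[above], X3).fit()
    p["m3"] = float(m3.pvalues[1])
    est["m3_english"] = float(m3.params[1])

    # m4: response ~ English + MPT + MPT^2, all participants
    X4 = sm.add_constant(np.column_stack([eng, mpt, mpt**2]))
    m4 = sm.OLS(y, X4).fit()
    p["m4"] = float(m4.pvalues[1])
    est["m4_english"] = float(m4.params[1])

    # m5: response ~ MPT, above-median participants
    X5 = sm.add_constant(mpt[above])
    m5 = sm.OLS(y[above], X5).fit()
    p["m5"] = float(m5.pvalues[1])
    est["m5_slope"] = float(m5.params[1])

    return ProficiencyTestResults(
        p_values=p, estimates=est, median_mpt=med, n_above_median=int(above.sum())
    )


def comprehension_proficiency(outcomes: pd.DataFrame, rescale_to: float = 50.0) -> pd.DataFrame:
    """Per-participant comprehension accuracy from question outcomes.

    ``outcomes`` needs columns participant_id and correct (bool/0/1); returns
    a DataFrame with accuracy in [0, 1] and a rescaled score usable as a
    drop-in substitute for the MPT in all proficiency analyses.
    """
    if "participant_id" not in outcomes.columns or "correct" not in outcomes.columns:
        raise ValueError("outcomes must have columns participant_id and correct")
    if len(outcomes) == 0:
        raise ValueError("zero question outcomes")
    grouped = outcomes.groupby("participant_id")["correct"]
    n = grouped.count()
    if (n == 0).any():
        raise ValueError("participant with zero question outcomes")
    acc = grouped.mean()
    out = pd.DataFrame(
        {
            "participant_id": acc.index,
            "accuracy": acc.to_numpy(dtype=float),
            "score": acc.to_numpy(dtype=float) * rescale_to,
        }
    ).reset_index(drop=True)
    return out
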