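"""Lice-resistance and fillet-colour trait definitions and descriptive tables.

Salmon lice counts (LC) are heavily right-skewed, so resistance is analysed
on a log scale. Dividing by body weight to the power 2/3 — an approximation
to skin surface area — converts a count into a density, and the working
trait is the log lice density

    LogLC = ln(LC + 1)
    LiceD = LC / BW^(2/3)          (BW in grams)
    LogLD = ln((LC + 1) / BW^(2/3)) = LogLC - (2/3) ln BW,

which is approximately normal. Fillet colour (FC, redness score) is treated
as Gaussian as recorded. ``describe`` produces the per-test summary and
correlation tables used to characterise a dataset.

Body weight enters the formulas in grams; descriptive tables are often
printed in kilograms, and callers convert explicitly — never silently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["log_lc", "lice_density", "log_ld", "derive", "describe"]


def _check_lc(lc):
    lc = np.asarray(lc, dtype=float)
    if np.any(lc < 0):
        raise ValueError("lice count must be >= 0")
    if np.any(lc != np.round(lc)):
        raise ValueError("lice count must be an integer")
    return lc


def _check_bw(bw):
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive (grams)")
    return bw


def log_lc(lc):
    """ln(lice count + 1); the +1 admits zero counts."""
    return np.log(_check_lc(lc) + 1.0)


def lice_density(lc, bw):
    """Lice per unit skin area: LC / BW^(2/3), BW in grams."""
    return _check_lc(lc) / _check_bw(bw) ** (2.0 / 3.0)


def log_ld(lc, bw):
    """Log lice density: ln((LC + 1) / BW^(2/3)) = log_lc(LC) - (2/3) ln BW."""
    return log_lc(lc) - (2.0 / 3.0) * np.log(_check_bw(bw))


def derive(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived trait columns (LogLC, LiceD, LogLD) to a phenotype table.

    Expects columns ``lc`` (count) and ``bw_g`` (grams); rows with missing
    inputs get missing derived values. Returns a copy.
    """
    out = table.copy()
    ok_lc = out["lc"].notna()
    out.loc[ok_lc, "loglc"] = log_lc(out.loc[ok_lc, "lc"])
    ok = ok_lc & out["bw_g"].notna()
    out.loc[ok, "liced"] = lice_density(out.loc[ok, "lc"], out.loc[ok, "bw_g"])
    out.loc[ok, "logld"] = log_ld(out.loc[ok, "lc"], out.loc[ok, "bw_g"])
    return out


def describe(table: pd.DataFrame, variables, by_test: bool = True):
    """Descriptive statistics and within-test correlations.

    Returns ``(summary, corr)``:

    * ``summary`` — one row per (test, variable): N, mean, SD, min, max.
    * ``corr`` — square Pearson correlation matrix over ``variables``; with
      two tests, test-1 coefficients sit above the diagonal and test-2
      coefficients below (the conventional compact layout). With one group
      the full symmetric matrix is returned.

    Variables that are entirely missing (or constant, for correlations) are
    reported as missing with a warning rather than dropped silently.
    """
    groups = (
        [(t, g) for t, g in table.groupby("test")] if by_test and "test" in table
        else [("all", table)]
    )
    rows = []
    for test, g in groups:
        for v in variables:
            x = pd.to_numeric(g[v], errors="coerce").dropna()
            if len(x) == 0:
                warnings.warn(f"variable {v!r} all-missing in test {test}; omitted")
                continue
            rows.append(
                {"test": test, "variable": v, "N": len(x), "mean": x.mean(),
                 "SD": x.std(ddof=1) if len(x) > 1 else np.nan,
                 "min": x.min(), "max": x.max()}
            )
    summary = pd.DataFrame(rows)

    def _corr(g):
        sub = g[list(variables)].apply(pd.to_numeric, errors="coerce")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return sub.corr(min_periods=2)

    corr = pd.DataFrame(np.nan, index=list(variables), columns=list(variables))
    if len(groups) >= 2:
        c_up, c_lo = _corr(groups[0][1]), _corr(groups[1][1])
        for a_i, a in enumerate(variables):
            for b_i, b in enumerate(variables):
                if a_i < b_i:
                    corr.loc[a, b] = c_up.loc[a, b]
                elif a_i > b_i:
                    corr.loc[a, b] = c_lo.loc[a, b]
    else:
        corr = _corr(groups[0][1])
        np.fill_diagonal(corr.values, np.nan)
    return summary, corr
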