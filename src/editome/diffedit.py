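"""Differential editing between time points via a beta-binomial LRT.

Each replicate's (edited, non-edited) read pair at a site is modelled as a
beta-binomial draw: k ~ BetaBinomial(n, alpha, beta).  The test fits the
two groups separately and pooled by maximum likelihood and forms

    LLR = 2 * [ll(group1) + ll(group2) - ll(pooled)],

referred to a chi-square with 2 degrees of freedom (the alternative fits
one extra (alpha, beta) pair).  Sites with p <= 0.05 are called
differentially edited; no multiple-testing correction is applied by
default, with an optional BH mode.

Optimisation runs in (logit mean, log concentration) coordinates, with the
concentration capped at 1e6 (the quasi-binomial limit) for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

LOG_CONC_MIN = np.log(1e-3)
LOG_CONC_MAX = np.log(1e6)
LOGIT_MIN, LOGIT_MAX = -30.0, 30.0


class DegenerateCountsError(ValueError):
    """All samples have zero total reads: nothing to fit."""


@dataclass
class BetaBinomFit:
    alpha: float
    beta: float
    loglik: float
    converged: bool
    x: np.ndarray | None = None      # optimum in (logit mean, log conc)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta


def betabinom_loglik(k: np.ndarray, n: np.ndarray,
                     alpha: float, beta: float) -> float:
    """Sum of beta-binomial log pmfs, including the binomial coefficient."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    lchoose = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    ll = (
        lchoose
        + special.betaln(k + alpha, n - k + beta)
        - special.betaln(alpha, beta)
    )
    return float(ll.sum())


def _params(x: np.ndarray) -> tuple[float, float]:
    mu = special.expit(x[0])
    s = np.exp(x[1])
    return mu * s, (1.0 - mu) * s


def _neg_loglik_grad(x: np.ndarray, k: np.ndarray, n: np.ndarray):
    """Negative log-likelihood and its gradient in (logit mu, log s)."""
    mu = special.expit(x[0])
    s = np.exp(x[1])
    a, b = mu * s, (1.0 - mu) * s
    ll = betabinom_loglik(k, n, a, b)
    da = (special.digamma(k + a) - special.digamma(a)
          + special.digamma(s) - special.digamma(n + s)).sum()
    db = (special.digamma(n - k + b) - special.digamma(b)
          + special.digamma(s) - special.digamma(n + s)).sum()
    g1 = (da - db) * s * mu * (1.0 - mu)
    g2 = da * a + db * b
    return -ll, -np.array([g1, g2])


def _mom_start(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    mu = k.sum() / n.sum()
    mu = min(max(mu, 1e-6), 1 - 1e-6)
    # crude overdispersion: compare per-sample proportion variance to binomial
    if len(k) > 1 and n.min() > 0:
        p = k / n
        v = p.var(ddof=1)
        vb = mu * (1 - mu) / n.mean()
        if v > vb > 0:
            rho = min(max((v - vb) / (mu * (1 - mu) - vb + 1e-12), 1e-6), 1 - 1e-6)
            s = (1 - rho) / rho
        else:
            s = 1e3
    else:
        s = 1e3
    s = min(max(s, 1.1e-3), 0.9e6)
    return np.array([special.logit(mu), np.log(s)])


def fit_betabinom_ml(samples, extra_starts=()) -> BetaBinomFit:
    """Maximum-likelihood beta-binomial fit to (edited, non-edited) pairs.

    Zero-total samples are dropped from the likelihood.  Initialised from
    method-of-moments estimates (plus any ``extra_starts`` in
    (logit mean, log concentration) coordinates) and optimised with bounded
    L-BFGS-B.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be a sequence of (edited, non_edited) pairs")
    k = arr[:, 0]
    n = arr.sum(axis=1)
    keep = n > 0
    k, n = k[keep], n[keep]
    if len(k) == 0:
        raise DegenerateCountsError("no informative samples (all totals zero)")

    bounds = [(LOGIT_MIN, LOGIT_MAX), (LOG_CONC_MIN, LOG_CONC_MAX)]
    starts = [_mom_start(k, n)]
    if extra_starts:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    else:
        # a flat moderate-concentration start helps near-binomial data
        starts.append(
            np.array([special.logit(min(max(k.sum() / n.sum(), 1e-6),
                                        1 - 1e-6)),
                      np.log(50.0)])
        )

    best = None
    for x0 in starts:
        x0 = np.clip(x0, [LOGIT_MIN, LOG_CONC_MIN], [LOGIT_MAX, LOG_CONC_MAX])
        res = optimize.minimize(
            _neg_loglik_grad, x0, args=(k, n), method="L-BFGS-B",
            bounds=bounds, jac=True,
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = _params(best.x)
    return BetaBinomFit(alpha=a, beta=b, loglik=-best.fun,
                        converged=bool(best.success), x=np.asarray(best.x))


@dataclass
class DiffEditResult:
    llr: float
    df: int
    p_value: float
    delta_el: float
    direction: str          # "up", "down" or "none"
    converged: bool
    el1: float
    el2: float


def redit_llr(group1, group2, df: int = 1) -> DiffEditResult:
    """Beta-binomial likelihood-ratio test between two sample groups.

    ``group1``/``group2`` are sequences of (edited, non-edited) pairs, one
    per replicate.  Group fits are additionally started from the pooled
    optimum so the LLR is non-negative by construction (each group fit is at
    least as good as the pooled parameters on its own data).

    The chi-square reference uses df = 1 by default: with duplicate designs
    the concentration parameter is pinned at the binomial boundary in both
    the null and alternative fits, so only the mean editing level
    contributes an effective degree of freedom (the empirical null LLR
    tracks chi-square(1); the classical 2-extra-parameter count df = 2 makes
    the test severely conservative at n = 2 per group).  Set ``df=2`` for
    the classical reference.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    pooled = np.vstack([g1, g2])
    fit0 = fit_betabinom_ml(pooled)
    fit1 = fit_betabinom_ml(g1, extra_starts=[fit0.x])
    fit2 = fit_betabinom_ml(g2, extra_starts=[fit0.x])
    llr = 2.0 * (fit1.loglik + fit2.loglik - fit0.loglik)
    if llr < 0:
        if llr < -1e-6:
            raise AssertionError(f"negative LLR beyond tolerance: {llr}")
        llr = 0.0
    p = float(stats.chi2.sf(llr, df))
    el1 = g1[:, 0].sum() / max(g1.sum(), 1)
    el2 = g2[:, 0].sum() / max(g2.sum(), 1)
    delta = abs(el2 - el1)
    if el2 > el1:
        direction = "up"
    elif el2 < el1:
        direction = "down"
    else:
        direction = "none"
    converged = fit0.converged and fit1.converged and fit2.converged
    return DiffEditResult(
        llr=llr, df=df, p_value=p, delta_el=delta, direction=direction,
        converged=converged, el1=el1, el2=el2,
    )


def scan_adjacent_timepoints(
    candidates: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    timepoints: list[str],
    presence: pd.DataFrame | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Test every site between each pair of adjacent time points.

    ``candidates`` is the long per-(site, sample) count table from the
    calling module.  When ``presence`` (site x timepoint survival matrix)
    is given, a site is tested for a pair only if it survived the cascade at
    both time points; sites missing counts at a time point are skipped.

    Returns one row per (site, pair) with the LLR, p-value, absolute EL
    change ("DE level") and direction, plus a ``significant`` flag at
    ``alpha`` (optionally BH-adjusted with ``adjust="bh"``).
    """
    df = candidates.merge(sample_sheet, on="sample", how="left")
    df = df.copy()
    df["site_id"] = (
        df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        + ":" + df["strand"] + ":" + df["alt"]
    )
    df["non_edited"] = df["covered"] - df["edited"]
    pairs = list(zip(timepoints[:-1], timepoints[1:]))
    grouped = {
        (sid, tp): grp[["edited", "non_edited"]].to_numpy()
        for (sid, tp), grp in df.groupby(["site_id", "timepoint"])
    }
    site_ids = df["site_id"].drop_duplicates().tolist()
    rows = []
    for t1, t2 in pairs:
        for sid in site_ids:
            if presence is not None:
                if sid not in presence.index:
                    continue
                if not (presence.loc[sid].get(t1, False)
                        and presence.loc[sid].get(t2, False)):
                    continue
            g1 = grouped.get((sid, t1))
            g2 = grouped.get((sid, t2))
            if g1 is None or g2 is None:
                continue
            res = redit_llr(g1, g2)
            rows.append(
                {
                    "site_id": sid, "pair": f"{t2}_vs_{t1}",
                    "llr": res.llr, "df": res.df, "p_value": res.p_value,
                    "de_level": res.delta_el, "dres": res.direction,
                    "converged": res.converged,
                }
            )
    out = pd.DataFrame(
        rows, columns=["site_id", "pair", "llr", "df", "p_value",
                       "de_level", "dres", "converged"]
    )
    if len(out):
        if adjust == "bh":
            from statsmodels.stats.multitest import multipletests

            out["p_adj"] = np.nan
            for pair, grp in out.groupby("pair"):
                _, padj, _, _ = multipletests(grp["p_value"], method="fdr_bh")
                out.loc[grp.index, "p_adj"] = padj
            crit = out["p_adj"] <= alpha
        else:
            crit = out["p_value"] <= alpha
        out["significant"] = crit & out["converged"]
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out
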