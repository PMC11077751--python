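"""PSI quantification and differential splicing calls.

Event discovery is delegated to the input table (five event classes: EX
exon skipping / mutually exclusive exons, IR intron retention, Alt3/Alt5
alternative acceptor/donor, MIC micro-exon skipping).  This module owns the
PSI arithmetic, the coverage filter and the differential rule:

    PSI = 100 * inclusion / (inclusion + exclusion)

An event is differential between two groups when |dPSI| >= 15 and the
signed gap between the two groups' PSI ranges is >= 5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EVENT_TYPES = ("EX", "IR", "Alt3", "Alt5", "MIC")


def compute_psi(inclusion, exclusion):
    """Percent spliced in on the 0-100 scale; undefined when total is 0."""
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, 100.0 * inc / total, np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def psi_table(events: pd.DataFrame, inc: pd.DataFrame, exc: pd.DataFrame) -> pd.DataFrame:
    """Event x sample PSI matrix from inclusion/exclusion count matrices."""
    if not inc.index.equals(exc.index) or not inc.columns.equals(exc.columns):
        raise ValueError("inclusion and exclusion matrices must be aligned")
    total = inc + exc
    psi = 100.0 * inc / total.where(total > 0)
    return psi


def coverage_filter(
    events: pd.DataFrame,
    inc: pd.DataFrame,
    exc: pd.DataFrame,
    min_ir: int = 25,
    min_other: int = 15,
    min_sample_frac: float = 0.2,
    ir_balance: pd.DataFrame | None = None,
    ir_balance_p: float = 0.05,
) -> pd.Index:
    """Events with sufficient junction coverage in enough samples.

    An event is retained iff inclusion + exclusion reaches the type-specific
    minimum (25 reads for IR, 15 otherwise) in at least
    ``ceil(min_sample_frac * n_samples)`` samples.  When ``ir_balance`` is
    given (IR events x 2 columns of intron-boundary read counts), IR events
    additionally must not fail a two-sided binomial balance test of the two
    boundary counts against 0.5.
    """
    total = inc + exc
    n_samples = total.shape[1]
    need = int(np.ceil(min_sample_frac * n_samples))
    minima = events["type"].map(lambda t: min_ir if t == "IR" else min_other)
    ok = total.ge(minima, axis=0).sum(axis=1) >= need
    keep = events.index[ok.reindex(events.index, fill_value=False)]
    if ir_balance is not None:
        bad = []
        for ev in keep:
            if events.loc[ev, "type"] != "IR" or ev not in ir_balance.index:
                continue
            a, b = ir_balance.loc[ev].iloc[:2]
            n = int(a + b)
            if n == 0:
                continue
            p = stats.binomtest(int(a), n, 0.5).pvalue
            if p < ir_balance_p:
                bad.append(ev)
        if bad:
            logger.info("coverage_filter: %d IR events failed the boundary "
                        "balance test", len(bad))
            keep = keep.difference(bad)
    return keep


def differential_splicing(
    psi: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    min_dpsi: float = 15.0,
    min_range: float = 5.0,
) -> pd.DataFrame:
    """Differential splicing between two sample groups.

    dPSI is mean(group2) - mean(group1) over defined PSIs.  The range
    statistic is the signed gap between the two groups' PSI sets:
    min(group2) - max(group1) when dPSI > 0, mirrored when dPSI < 0.  An
    event is significant iff |dPSI| >= min_dpsi and range >= min_range.
    Events with no defined PSI in a group are skipped (logged).
    """
    rows = []
    skipped = 0
    for ev, row in psi.iterrows():
        g1 = row[group1].dropna()
        g2 = row[group2].dropna()
        if g1.empty or g2.empty:
            skipped += 1
            continue
        dpsi = g2.mean() - g1.mean()
        if dpsi > 0:
            rng = g2.min() - g1.max()
        elif dpsi < 0:
            rng = g1.min() - g2.max()
        else:
            rng = min(g2.min() - g1.max(), g1.min() - g2.max())
        rows.append(
            {
                "event_id": ev,
                "dpsi": dpsi,
                "range": rng,
                "significant": bool(abs(dpsi) >= min_dpsi and rng >= min_range),
            }
        )
    if skipped:
        logger.info("differential_splicing: %d events without defined PSI "
                    "in a group skipped", skipped)
    return pd.DataFrame(rows, columns=["event_id", "dpsi", "range", "significant"])


def scan_adjacent_timepoints_psi(
    psi: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    timepoints: list[str],
    min_dpsi: float = 15.0,
    min_range: float = 5.0,
) -> pd.DataFrame:
    """Differential splicing for each adjacent time-point pair."""
    groups = {
        tp: grp["sample"].tolist()
        for tp, grp in sample_sheet.groupby("timepoint", sort=False)
    }
    out = []
    for t1, t2 in zip(timepoints[:-1], timepoints[1:]):
        res = differential_splicing(psi, groups[t1], groups[t2],
                                    min_dpsi=min_dpsi, min_range=min_range)
        res["pair"] = f"{t2}_vs_{t1}"
        out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["event_id", "dpsi", "range", "significant", "pair"]
    )
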