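"""Cross-layer analyses linking editing, splicing and translation.

Covers: the editing x splicing gene-presence association (Fisher's exact
test, with an optional transcript-length-stratified mode), pairing of each
editing site to its nearest same-gene splicing event, Pearson trajectory
correlation with strength categories (Strong |r| >= 0.7, Moderate
0.5 <= |r| < 0.7, Weak 0.3 <= |r| < 0.5, None below), distance and
event-type summaries of positively vs negatively correlated pairs, gene
classes by editing/splicing presence with translatable-transcript and TE
summaries, differential-group composition of dTE genes, and the
ADAR-expression correlation with editing activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EVENT_PRIORITY = {"IR": 0, "EX": 1, "Alt3": 2, "Alt5": 3, "MIC": 4}

CATEGORY_BOUNDS = (0.7, 0.5, 0.3)  # Strong / Moderate / Weak lower bounds


def correlation_category(r: float) -> str:
    """Map |r| to the Strong/Moderate/Weak/None strength category."""
    if not np.isfinite(r):
        return "None"
    a = abs(r)
    if a >= CATEGORY_BOUNDS[0]:
        return "Strong"
    if a >= CATEGORY_BOUNDS[1]:
        return "Moderate"
    if a >= CATEGORY_BOUNDS[2]:
        return "Weak"
    return "None"


@dataclass
class AssociationTable:
    table: np.ndarray        # 2x2: rows editing yes/no, cols splicing yes/no
    odds_ratio: float
    p_value: float


def association_fisher(flags: pd.DataFrame) -> AssociationTable:
    """Fisher's exact test of editing presence vs splicing presence.

    ``flags`` columns: es (has editing sites), as_ (has splicing events),
    one row per gene.  Degenerate margins give p = 1 and an undefined odds
    ratio.
    """
    es = flags["es"].astype(bool)
    asf = flags["as_"].astype(bool)
    table = np.array(
        [
            [int((es & asf).sum()), int((es & ~asf).sum())],
            [int((~es & asf).sum()), int((~es & ~asf).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return AssociationTable(table, np.nan, 1.0)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationTable(table, float(odds), float(p))


def association_fisher_stratified(
    flags: pd.DataFrame, lengths: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Length-stratified association: genes binned by length deciles.

    Returns one row per stratum with its 2x2 counts and Fisher p, plus a
    pooled Mantel-Haenszel row combining the strata.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    lengths = lengths.loc[flags.index]
    bins = pd.qcut(lengths.rank(method="first"), q=n_bins, labels=False)
    rows = []
    tables = []
    for b in range(n_bins):
        sub = flags.loc[bins == b]
        res = association_fisher(sub)
        tables.append(res.table)
        rows.append(
            {"stratum": b, "n_genes": len(sub), "odds_ratio": res.odds_ratio,
             "p_value": res.p_value}
        )
    st = StratifiedTable([t for t in tables if t.sum() > 0])
    mh = st.test_null_odds()
    rows.append(
        {
            "stratum": "pooled_MH",
            "n_genes": int(len(flags)),
            "odds_ratio": float(st.oddsratio_pooled),
            "p_value": float(mh.pvalue),
        }
    )
    return pd.DataFrame(rows)


def _event_distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return int(min(abs(pos - start), abs(pos - end)))


def pair_sites_to_events(sites: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Assign each editing site the closest same-gene splicing event.

    Only genes with both editing and splicing are considered.  Distance is
    0 for a site inside the event's alternative segment, otherwise the
    nucleotides to the nearest segment boundary.  Equidistant events are
    broken toward IR > EX > Alt3 > Alt5 > MIC, then smaller event id.  One
    pair per site; an event may serve several sites.
    """
    ev_by_gene = {g: grp for g, grp in events.groupby("gene_id")}
    rows = []
    unpaired_genes = set()
    for _, site in sites.drop_duplicates("site_id").iterrows():
        gene = site.get("gene_id", "")
        grp = ev_by_gene.get(gene)
        if grp is None or grp.empty:
            if gene:
                unpaired_genes.add(gene)
            continue
        best = None
        for ev_id, ev in grp.set_index("event_id").iterrows():
            d = _event_distance(int(site["pos"]), int(ev["start"]), int(ev["end"]))
            key = (d, EVENT_PRIORITY.get(ev["type"], 99), str(ev_id))
            if best is None or key < best[0]:
                best = (key, ev_id, ev["type"], d)
        rows.append(
            {
                "site_id": site["site_id"],
                "gene_id": gene,
                "event_id": best[1],
                "event_type": best[2],
                "distance": best[3],
            }
        )
    if unpaired_genes:
        logger.info("pair_sites_to_events: %d genes had sites but no events",
                    len(unpaired_genes))
    return pd.DataFrame(
        rows, columns=["site_id", "gene_id", "event_id", "event_type", "distance"]
    )


def pair_correlation(
    pairs: pd.DataFrame,
    el_by_tp: pd.DataFrame,
    psi_by_tp: pd.DataFrame,
    strong_r: float = 0.7,
    max_p: float = 0.05,
    min_points: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of EL and PSI trajectories for each pair.

    Computed on the time points where both trajectories are defined
    (>= ``min_points`` required).  Adds r, its two-sided p, the strength
    category, the sign, and a ``significant_strong`` flag
    (|r| >= strong_r and p <= max_p).  Constant trajectories leave r
    undefined with category "None".
    """
    rows = []
    for _, pair in pairs.iterrows():
        sid, evid = pair["site_id"], pair["event_id"]
        out = dict(pair)
        out.update({"r": np.nan, "p_value": np.nan, "category": "None",
                    "sign": "", "significant_strong": False, "n_points": 0})
        if sid in el_by_tp.index and evid in psi_by_tp.index:
            el = el_by_tp.loc[sid]
            psi = psi_by_tp.loc[evid]
            common = el.notna() & psi.notna()
            n = int(common.sum())
            out["n_points"] = n
            if n >= min_points:
                x = el[common].to_numpy(dtype=float)
                y = psi[common].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    pass  # constant trajectory: r undefined
                else:
                    r, p = stats.pearsonr(x, y)
                    out["r"] = float(r)
                    out["p_value"] = float(p)
                    out["category"] = correlation_category(r)
                    out["sign"] = "pos" if r >= 0 else "neg"
                    out["significant_strong"] = bool(abs(r) >= strong_r and p <= max_p)
        rows.append(out)
    return pd.DataFrame(rows)


def pair_summaries(
    pairs: pd.DataFrame,
    el_by_tp: pd.DataFrame | None = None,
    psi_by_tp: pd.DataFrame | None = None,
    n_groups: int = 6,
    seed: int = 0,
) -> dict:
    """Distance and event-type summaries of significant pos vs neg pairs.

    Returns a dict with the Wilcoxon rank-sum test of distances (pos vs
    neg), the event-type x sign contingency test (chi-square, Fisher for
    2x2 with small counts), and, when trajectories are provided, a fuzzy
    c-means clustering of strongly correlated pairs on the concatenated
    z-scored EL and PSI trajectories.
    """
    sig = pairs.loc[pairs["significant_strong"]]
    pos = sig.loc[sig["sign"] == "pos"]
    neg = sig.loc[sig["sign"] == "neg"]
    out: dict = {"n_pos": len(pos), "n_neg": len(neg)}
    if len(pos) and len(neg):
        # Wilcoxon rank-sum via the U statistic: exact for small samples
        _, p = stats.mannwhitneyu(pos["distance"], neg["distance"],
                                  alternative="two-sided")
        out["distance_wilcoxon_p"] = float(p)
        out["median_distance_pos"] = float(pos["distance"].median())
        out["median_distance_neg"] = float(neg["distance"].median())
        ct = pd.crosstab(sig["event_type"], sig["sign"])
        out["type_by_sign"] = ct
        if ct.shape == (2, 2) and (ct.to_numpy() < 5).any():
            _, p_ct = stats.fisher_exact(ct.to_numpy())
        else:
            _, p_ct, _, _ = stats.chi2_contingency(ct.to_numpy())
        out["type_by_sign_p"] = float(p_ct)
    else:
        logger.warning("pair_summaries: missing a correlation sign; "
                       "summaries skipped")
    if el_by_tp is not None and psi_by_tp is not None and len(sig) >= n_groups:
        from .patterns import fuzzy_cmeans, standardize_profiles

        el = el_by_tp.loc[sig["site_id"]].to_numpy(dtype=float)
        psi = psi_by_tp.loc[sig["event_id"]].to_numpy(dtype=float)
        joint = pd.DataFrame(
            np.hstack([el, psi]), index=sig["site_id"].to_numpy()
        )
        el_z = standardize_profiles(pd.DataFrame(el, index=joint.index))
        psi_z = standardize_profiles(pd.DataFrame(psi, index=joint.index))
        common = el_z.index.intersection(psi_z.index)
        joint_z = pd.concat([el_z.loc[common], psi_z.loc[common]], axis=1)
        joint_z.columns = range(joint_z.shape[1])
        fc = fuzzy_cmeans(joint_z, c=n_groups, seed=seed)
        out["joint_clusters"] = fc.to_frame()
    return out


def classify_genes(
    flags: pd.DataFrame,
    translatable: pd.Series | None = None,
    te: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four gene classes from editing/splicing presence, with summaries.

    ``flags``: per-gene boolean columns es, as_.  Returns (per-gene table
    with a ``gene_class`` column, per-class summary with mean +- normal CI
    of translatable-transcript counts and pairwise Wilcoxon p-values on
    TE between classes).
    """
    def cls(row) -> str:
        a = "AS" if row["as_"] else "Non-AS"
        e = "ES" if row["es"] else "Non-ES"
        return f"{a}&{e}"

    out = flags.copy()
    out["gene_class"] = out.apply(cls, axis=1)
    if translatable is not None:
        out["translatable"] = translatable.reindex(out.index)
    if te is not None:
        out["te"] = te.reindex(out.index)

    rows = []
    for name, grp in out.groupby("gene_class"):
        row = {"gene_class": name, "n_genes": len(grp)}
        if translatable is not None:
            vals = grp["translatable"].dropna()
            m = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            row.update(
                {"mean_translatable": m, "ci_lo": m - 1.96 * se,
                 "ci_hi": m + 1.96 * se}
            )
        if te is not None:
            row["median_te"] = grp["te"].dropna().median()
        rows.append(row)
    summary = pd.DataFrame(rows)

    if te is not None:
        classes = sorted(out["gene_class"].unique())
        for i, c1 in enumerate(classes):
            for c2 in classes[i + 1:]:
                a = out.loc[out["gene_class"] == c1, "te"].dropna()
                b = out.loc[out["gene_class"] == c2, "te"].dropna()
                if len(a) and len(b):
                    _, p = stats.ranksums(a, b)
                    summary.loc[summary["gene_class"] == c1,
                                f"wilcoxon_vs_{c2}"] = p
    return out, summary


def classify_dte_groups(
    dte: pd.DataFrame,
    dpsi_genes: set[str],
    del_genes: set[str],
) -> pd.DataFrame:
    """Partition dTE genes by differential-splicing / differential-editing status.

    ``dte`` rows: gene_id, direction ("up"/"down").  Returns one row per
    group (dAS&dES, dAS&Non-dES, Non-dAS&dES, Non-dAS&Non-dES) with gene
    counts and the up/down fractions, which sum to 1 within a group.
    """
    if dte.empty:
        return pd.DataFrame(
            columns=["group", "n_genes", "frac_up", "frac_down"]
        )

    def grp(gene: str) -> str:
        a = "dAS" if gene in dpsi_genes else "Non-dAS"
        e = "dES" if gene in del_genes else "Non-dES"
        return f"{a}&{e}"

    df = dte.copy()
    df["group"] = df["gene_id"].map(grp)
    rows = []
    for name, sub in df.groupby("group"):
        n = len(sub)
        up = (sub["direction"] == "up").sum()
        rows.append(
            {"group": name, "n_genes": n, "frac_up": up / n,
             "frac_down": (n - up) / n}
        )
    return pd.DataFrame(rows)


def adar_correlation(
    editing_summary: pd.DataFrame,
    adar_expression: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Pearson correlation of editing activity with ADAR expression.

    ``editing_summary``: time points x summaries (e.g. columns n_sites,
    shared_mean_el).  ``adar_expression`` maps an expression level ("RNA",
    "Ribo") to a genes x time points matrix of normalised expression for
    the ADAR genes.  Requires >= 3 time points.  Constant series leave r
    undefined, flagged.
    """
    tps = editing_summary.index
    if len(tps) < 3:
        raise ValueError("insufficient points: need >= 3 time points")
    rows = []
    for level, expr in adar_expression.items():
        expr = expr[tps]
        for gene, traj in expr.iterrows():
            for summary in editing_summary.columns:
                x = traj.to_numpy(dtype=float)
                y = editing_summary[summary].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rows.append(
                        {"gene": gene, "level": level, "summary": summary,
                         "r": np.nan, "p_value": np.nan, "constant": True}
                    )
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append(
                    {"gene": gene, "level": level, "summary": summary,
                     "r": float(r), "p_value": float(p), "constant": False}
                )
    return pd.DataFrame(rows)
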