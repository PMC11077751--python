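"""Gene expression normalisation and translational-efficiency analysis.

CDS-restricted RNA-seq and Ribo-seq count matrices are consolidated, genes
with a total count below 10 discarded, library sizes removed with
median-of-ratios size factors, and expression corrected by CDS length (kb).
Translational efficiency (TE) is the ratio of normalised Ribo-seq to
normalised RNA-seq expression, replicates averaged per time point before
the ratio.

Differential TE between two time points fits, per gene, a negative-binomial
GLM with design  library type + time + library type:time  (log link, size
factors as offsets, gene-wise method-of-moments dispersion) and Wald-tests
the interaction coefficient, which is the log2 TE fold change after base
conversion.  Genes with |log2FC| >= 1 and BH-adjusted p <= 0.05 are called
differential.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes whose total count across all samples is >= min_total."""
    return counts.loc[counts.sum(axis=1) >= min_total]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples; genes with a
    zero count in any sample are excluded from the reference.  Factors are
    not rescaled afterwards — the median against the geometric-mean
    reference leaves them with geometric mean ~1 for comparable libraries,
    and rescaling would break the exact absorption of a per-sample scaling
    constant into its factor.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene is nonzero in every sample; a pseudo-reference would be "
            "required for these counts"
        )
    sub = arr[nonzero]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_expression(
    counts: pd.DataFrame, factors: pd.Series, cds_length: pd.Series
) -> pd.DataFrame:
    """(count / size factor) / (CDS length in kb)."""
    if (cds_length <= 0).any():
        raise ValueError("every gene must have a positive CDS length")
    norm = counts.div(factors, axis=1)
    return norm.div(cds_length.loc[counts.index] / 1000.0, axis=0)


def translational_efficiency(
    ribo_norm: pd.DataFrame,
    rna_norm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Gene x time point TE matrix.

    Normalised replicate values are averaged per time point within each
    library type and the ratio Ribo / RNA taken afterwards; entries with
    zero RNA expression are left missing.
    """
    sheet = sample_sheet.set_index("sample")
    tps = list(sample_sheet["timepoint"].drop_duplicates())

    def per_tp(norm: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for tp in tps:
            samples = [s for s in norm.columns if sheet.loc[s, "timepoint"] == tp]
            cols[tp] = norm[samples].mean(axis=1)
        return pd.DataFrame(cols)

    ribo_tp = per_tp(ribo_norm)
    rna_tp = per_tp(rna_norm)
    genes = ribo_tp.index.intersection(rna_tp.index)
    te = ribo_tp.loc[genes] / rna_tp.loc[genes].where(rna_tp.loc[genes] > 0)
    return te


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int = 4) -> float:
    """Method-of-moments NB dispersion alpha with var = mu + alpha mu^2.

    Squared residuals are inflated by n/(n - p) to compensate for the p
    fitted mean parameters; the estimate is floored at 1e-8.
    """
    n = len(y)
    corr = n / max(n - n_params, 1)
    resid = corr * (y - mu) ** 2 - mu
    denom = mu ** 2
    ok = denom > 0
    if not ok.any():
        return 1e-8
    alpha = resid[ok].sum() / denom[ok].sum()
    return float(max(alpha, 1e-8))


def dte_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pair: tuple[str, str],
    factors: pd.Series | None = None,
    min_log2fc: float = 1.0,
    max_padj: float = 0.05,
    per_type_factors: bool = True,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the library type x time interaction.

    ``counts`` holds both library types; ``sample_sheet`` columns: sample,
    timepoint, replicate, libtype ("RNA"/"Ribo").  Only the two time points
    of ``pair`` are used; both library types need >= 2 replicates at both.
    Size factors are computed per library type by default.  Returns one row
    per gene with log2FoldChange (of TE, pair[1] relative to pair[0]),
    lfcSE, p, padj (BH) and the significance flag.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    t1, t2 = pair
    sheet = sample_sheet.set_index("sample")
    samples = [
        s for s in counts.columns if sheet.loc[s, "timepoint"] in (t1, t2)
    ]
    sub_sheet = sheet.loc[samples]
    for lt in ("RNA", "Ribo"):
        for tp in (t1, t2):
            n = ((sub_sheet["libtype"] == lt) & (sub_sheet["timepoint"] == tp)).sum()
            if n < 2:
                raise ValueError(
                    f"need >= 2 replicates of {lt} at {tp}, found {n}"
                )
    sub = counts[samples]

    if factors is None:
        if per_type_factors:
            factors = pd.Series(index=samples, dtype=float)
            for lt in ("RNA", "Ribo"):
                cols = [s for s in samples if sheet.loc[s, "libtype"] == lt]
                factors.loc[cols] = size_factors(sub[cols])
        else:
            factors = size_factors(sub)
    factors = factors.loc[samples]

    is_ribo = (sub_sheet["libtype"] == "Ribo").astype(float).to_numpy()
    is_t2 = (sub_sheet["timepoint"] == t2).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(samples)), is_ribo, is_t2, is_ribo * is_t2])
    offset = np.log(factors.to_numpy())

    rows = []
    for gene, y in sub.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        # dispersion from a Poisson pre-fit's fitted means
        try:
            pre = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            alpha = _mom_dispersion(y, pre.mu)
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            ).fit(maxiter=100)
            converged = bool(res.converged)
        except Exception:
            rows.append({"gene_id": gene, "log2FoldChange": np.nan,
                         "lfcSE": np.nan, "p": np.nan, "converged": False})
            continue
        beta = res.params[3]
        se = res.bse[3]
        if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
            converged = False
            p = np.nan
        else:
            z = beta / se
            p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "gene_id": gene,
                "log2FoldChange": beta / np.log(2),
                "lfcSE": se / np.log(2),
                "p": p,
                "converged": converged,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=["gene_id", "log2FoldChange", "lfcSE", "p",
                                    "converged", "padj", "significant",
                                    "direction", "pair"])
        return out
    ok = out["converged"] & out["p"].notna()
    out["padj"] = np.nan
    if ok.any():
        _, padj, _, _ = multipletests(out.loc[ok, "p"], method="fdr_bh")
        out.loc[ok, "padj"] = padj
    out["significant"] = (
        ok
        & (out["log2FoldChange"].abs() >= min_log2fc)
        & (out["padj"] <= max_padj)
    )
    out["direction"] = np.where(out["log2FoldChange"] > 0, "up", "down")
    out["pair"] = f"{t2}_vs_{t1}"
    return out


def scan_adjacent_timepoints_te(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    timepoints: list[str],
    **kwargs,
) -> pd.DataFrame:
    """dTE tests for each adjacent time-point pair."""
    out = []
    for t1, t2 in zip(timepoints[:-1], timepoints[1:]):
        out.append(dte_test(counts, sample_sheet, (t1, t2), **kwargs))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()
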