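"""Proteome-transcriptome integration and the translation model.

Converts relative transcript abundances (FPKM) to mRNA copies per cell under
an assumed cellular mRNA total, computes per-gene translational efficiency
(protein copies per transcript), extrapolates the total proteome from the
unmeasured transcript pool, corrects observed correlations for measurement
reliability (Spearman's attenuation correction), fits log-log slopes by OLS
and Ranged-Major-Axis regression, and builds a forward-selected multivariate
linear model of protein abundance from transcript abundance plus gene
features and feature x transcript interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TOTAL_MRNA_PER_CELL", "TranslationModelFit",
    "fpkm_to_cpc", "translational_efficiency", "extrapolate_total_proteome",
    "disattenuate", "loglog_slopes", "fit_translation_model",
]

#: assumed total mRNA molecules per yeast cell (alternate historical value 15000)
TOTAL_MRNA_PER_CELL = 60000.0


def fpkm_to_cpc(fpkm: pd.Series, total_mrna: float = TOTAL_MRNA_PER_CELL) -> pd.Series:
    """Proportional allocation of the cellular mRNA pool across genes.

    cpc_i = fpkm_i / sum(fpkm) * total_mrna; the result sums to ``total_mrna``
    exactly (values kept fractional).
    """
    f = pd.Series(fpkm).astype(float)
    total = f.sum()
    if not total > 0:
        raise ValueError("FPKM values sum to zero")
    if (f < 0).any():
        raise ValueError("FPKM values must be >= 0")
    return f / total * total_mrna


def translational_efficiency(
    protein_cpc: pd.Series,
    mrna_cpc: pd.Series,
) -> tuple[pd.Series, float, int]:
    """Per-gene TE = protein cpc / mRNA cpc, plus the median TE.

    Genes are matched on index; genes with zero/missing mRNA are excluded.
    Returns ``(te, median_te, n_excluded)``.
    """
    p = pd.Series(protein_cpc).dropna()
    m = pd.Series(mrna_cpc).dropna()
    p, m = p.align(m, join="inner")
    if len(p) == 0:
        raise ValueError("no shared genes between protein and transcript tables")
    ok = m > 0
    te = p[ok] / m[ok]
    return te, float(te.median()), int((~ok).sum())


def extrapolate_total_proteome(
    measured_cpc_sum: float,
    median_te: float,
    unmeasured_mrna_cpc_sum: float,
) -> float:
    """Total protein molecules per cell.

    The measured proteome sum plus the median proteins-per-transcript applied
    to the transcript pool of unmeasured genes.
    """
    if min(measured_cpc_sum, median_te, unmeasured_mrna_cpc_sum) < 0:
        raise ValueError("inputs must be >= 0")
    return measured_cpc_sum + median_te * unmeasured_mrna_cpc_sum


def disattenuate(r_observed: float, reliability_x: float, reliability_y: float) -> float:
    """Spearman's correction for attenuation.

    r_corrected = r / sqrt(rel_x * rel_y), where the reliabilities are the
    repeatabilities of the two measurements estimated from replicates.
    Values beyond +-1 are clipped with a warning.
    """
    if not (0 < reliability_x <= 1) or not (0 < reliability_y <= 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    if not -1 <= r_observed <= 1:
        raise ValueError("r must lie in [-1, 1]")
    r = r_observed / np.sqrt(reliability_x * reliability_y)
    if abs(r) > 1:
        warnings.warn("disattenuated correlation exceeds 1; clipped", stacklevel=2)
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """First-principal-axis (major axis) slope."""
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        return 1.0 if syy >= sxx else 0.0
    return float((syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy))


def loglog_slopes(protein_cpc, mrna_cpc) -> dict:
    """OLS, major-axis and Ranged-Major-Axis slopes of log10 P on log10 M.

    OLS treats the transcript as error-free; the major-axis (model II) slope
    shares error between both variables; Ranged Major Axis first ranges both
    variables to [0, 1] ((v - min) / (max - min)), takes the major axis of
    the ranged values and back-transforms by the range ratio, making the fit
    scale-invariant.
    """
    p = np.asarray(protein_cpc, dtype=float)
    m = np.asarray(mrna_cpc, dtype=float)
    ok = (p > 0) & (m > 0) & np.isfinite(p) & np.isfinite(m)
    x = np.log10(m[ok])
    y = np.log10(p[ok])
    if x.size < 3:
        raise ValueError("need at least three positive pairs")
    rx = np.ptp(x)
    ry = np.ptp(y)
    if rx == 0 or ry == 0:
        raise ValueError("degenerate range: one variable is constant")
    ols = stats.linregress(x, y)
    u = (x - x.min()) / rx
    v = (y - y.min()) / ry
    rma = _ma_slope(u, v) * (ry / rx)
    xm, ym = x.mean(), y.mean()
    return {
        "ols_slope": float(ols.slope),
        "ols_intercept": float(ols.intercept),
        "ma_slope": _ma_slope(x, y),
        "rma_slope": float(rma),
        "rma_intercept": float(ym - rma * xm),
        "n": int(x.size),
        "r_squared": float(ols.rvalue ** 2),
    }


# ---------------------------------------------------------------------------
# forward-selected translation model
# ---------------------------------------------------------------------------

@dataclass
class TranslationModelFit:
    """Forward-selection result for log10 protein ~ log10 mRNA + features."""

    terms: list                      # term names in inclusion order
    params: pd.Series                # coefficients
    bse: pd.Series                   # standard errors
    r_squared: float
    spearman_rho: float
    trace: list = field(default_factory=list)  # (term, r_squared after adding)
    n_obs: int = 0
    n_interactions: int = 0
    notes: list = field(default_factory=list)


def fit_translation_model(
    protein_cpc: pd.Series,
    mrna_cpc: pd.Series,
    features: pd.DataFrame,
    *,
    alpha: float = 0.01,
    max_terms: int | None = None,
    collinearity_r: float = 0.99,
) -> TranslationModelFit:
    """Forward selection of a multivariate linear translation model.

    Response: log10 protein cpc.  The base term log10 mRNA cpc is always
    included.  Each candidate feature is tried both as a main effect and as an
    interaction with centred log10 mRNA (centred before multiplying); at each
    step the form maximising adjusted r^2 is added if its partial F-test
    p-value is below ``alpha``.  Ties break by term name; features nearly
    collinear (|r| > ``collinearity_r``) with an included term are skipped
    with a note.  The selection trace (term added, r^2 after) is recorded and
    r^2 is non-decreasing along it.
    """
    p = pd.Series(protein_cpc).astype(float)
    m = pd.Series(mrna_cpc).astype(float)
    p, m = p.align(m, join="inner")
    feats = features.reindex(p.index)
    numeric = feats.select_dtypes(include=[np.number])
    keep = (p > 0) & (m > 0) & numeric.notna().all(axis=1)
    y = np.log10(p[keep])
    logm = np.log10(m[keep])
    numeric = numeric[keep]
    n = len(y)
    notes = []
    if n < 10 * (numeric.shape[1] + 1):
        notes.append(f"n={n} is small for {numeric.shape[1]} candidates")
        warnings.warn(notes[-1], stacklevel=2)

    logm_c = logm - logm.mean()
    columns: dict[str, pd.Series] = {"log_mrna": logm}
    for name in numeric.columns:
        z = numeric[name]
        columns[name] = z
        columns[f"{name}:log_mrna"] = (z - z.mean()) * logm_c

    def fit(term_names: list[str]):
        X = sm.add_constant(pd.DataFrame({t: columns[t] for t in term_names}))
        return sm.OLS(y, X).fit()

    included = ["log_mrna"]
    model = fit(included)
    trace = [("log_mrna", float(model.rsquared))]
    remaining = sorted(numeric.columns)

    while remaining and (max_terms is None or len(included) - 1 < max_terms):
        best = None
        for feat in remaining:
            for term in (feat, f"{feat}:log_mrna"):
                col = columns[term]
                collinear = any(
                    abs(np.corrcoef(col, columns[t])[0, 1]) > collinearity_r
                    for t in included
                    if np.std(col) > 0 and np.std(columns[t]) > 0
                )
                if collinear or np.std(col) == 0:
                    continue
                cand = fit(included + [term])
                # strict > keeps the first (alphabetically earliest) term on ties
                if best is None or cand.rsquared_adj > best[0]:
                    best = (cand.rsquared_adj, cand, term, feat)
        if best is None:
            break
        _, cand, term, feat = best
        # partial F-test of the added term against the current model
        rss0, rss1 = model.ssr, cand.ssr
        df1 = cand.df_resid
        fstat = (rss0 - rss1) / (rss1 / df1)
        pval = stats.f.sf(fstat, 1, df1)
        if pval >= alpha:
            break
        included.append(term)
        model = cand
        trace.append((term, float(model.rsquared)))
        remaining.remove(feat)

    pred = model.fittedvalues
    rho = stats.spearmanr(pred, y).statistic if n > 2 else np.nan
    return TranslationModelFit(
        terms=included,
        params=model.params,
        bse=model.bse,
        r_squared=float(model.rsquared),
        spearman_rho=float(rho),
        trace=trace,
        n_obs=n,
        n_interactions=sum(1 for t in included if t.endswith(":log_mrna")),
        notes=notes,
    )
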