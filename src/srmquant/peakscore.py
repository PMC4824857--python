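"""Decoy transitions, peak-group scoring and target-decoy FDR.

A light (endogenous) peak group is scored against its heavy internal-standard
reference via three sub-scores — co-elution/pattern correlation, normalised
intensity dot product, and log aggregate signal-to-noise — combined after
z-scaling on the decoy population.  q-values come from simple target-decoy
counting:  FDR(s) = #{decoys >= s} / max(1, #{targets >= s}), monotonised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import TransitionDef

__all__ = ["PeakGroup", "ScoredPeakGroup", "generate_decoys",
           "score_peak_group", "estimate_fdr", "score_table"]


@dataclass
class PeakGroup:
    peptide_id: str
    label: str                      # 'light' | 'heavy'
    areas: np.ndarray               # per-transition integrated areas
    sn: np.ndarray | float          # per-transition or aggregate S/N
    apex_rt: float | None = None
    decoy: bool = False

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size < 1:
            raise ValueError("peak group needs at least one transition")
        if np.nanmin(self.areas) < 0:
            raise ValueError("areas must be non-negative")


@dataclass
class ScoredPeakGroup:
    peptide_id: str
    coelution_corr: float
    pattern_dot: float
    log_sn: float
    score: float
    decoy: bool = False
    q_value: float | None = None


def generate_decoys(
    transitions: list[TransitionDef],
    offset: float = 11.0,
    min_separation: float = 0.5,
    step: float = 1.0,
) -> list[TransitionDef]:
    """One decoy per target: same precursor m/z and RT, product m/z shifted.

    The shift starts at ``offset`` Th and is incremented by ``step`` until the
    decoy product lies at least ``min_separation`` Th from every real product.
    """
    if not transitions:
        raise ValueError("need at least one target transition")
    real = np.array([t.product_mz for t in transitions])
    out = []
    for t in transitions:
        shift = offset
        while np.min(np.abs(real - (t.product_mz + shift))) < min_separation:
            shift += step
        out.append(replace(t, product_mz=t.product_mz + shift, decoy=True))
    return out


def _subscores(light: np.ndarray, heavy: np.ndarray, sn) -> tuple[float, float, float]:
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    # co-elution / relative-pattern correlation across transitions
    if light.std() == 0 or heavy.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(light, heavy)[0, 1])
    nl = np.linalg.norm(light)
    nh = np.linalg.norm(heavy)
    dot = float(light @ heavy / (nl * nh)) if nl > 0 and nh > 0 else 0.0
    mean_sn = float(np.mean(sn))
    log_sn = float(np.log10(max(mean_sn, 1e-12)))
    return corr, dot, log_sn


def score_peak_group(
    group: PeakGroup,
    reference: PeakGroup,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ScoredPeakGroup:
    """Score a light group against its heavy reference.

    The composite is a weighted sum of the sub-scores; within a full table the
    weights are applied after z-scaling each sub-score on the decoy population
    (see :func:`score_table`), which makes the composite scale-free.  Scoring
    is invariant to uniform scaling of all areas (ratio-based sub-scores).
    """
    if group.areas.size != reference.areas.size:
        raise ValueError("transition count mismatch between group and reference")
    corr, dot, log_sn = _subscores(group.areas, reference.areas, group.sn)
    w1, w2, w3 = weights
    return ScoredPeakGroup(
        peptide_id=group.peptide_id,
        coelution_corr=corr,
        pattern_dot=dot,
        log_sn=log_sn,
        score=w1 * corr + w2 * dot + w3 * log_sn,
        decoy=group.decoy,
    )


def estimate_fdr(
    target_scores: np.ndarray,
    decoy_scores: np.ndarray,
    conservative: bool = False,
) -> np.ndarray:
    """q-value per target from target-decoy counting.

    FDR at threshold s is #{decoys >= s} / max(1, #{targets >= s}); the
    q-value of a target is the minimum FDR over all thresholds at or below its
    score (monotone non-increasing in score).  ``conservative`` adds the +1
    pseudo-count to the decoy count (q-value floor 1/#targets).
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if d.size == 0:
        raise ValueError("no decoy scores: generate decoy transitions first")
    order = np.argsort(-t, kind="stable")
    ts = t[order]
    # decoys >= s for each target threshold
    d_sorted = np.sort(d)
    n_d_ge = d.size - np.searchsorted(d_sorted, ts, side="left")
    n_t_ge = np.arange(1, t.size + 1)
    fdr = (n_d_ge + (1 if conservative else 0)) / np.maximum(1, n_t_ge)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(t)
    out[order] = q
    return out


def score_table(peaks: pd.DataFrame, weights=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Score a long per-transition peak table into replicate-level quantities.

    Input columns: ``peptide_id, protein_group_id, replicate, spike_label,
    spike_amount_mol, transition, label, area, decoy, noise_area`` (and
    optionally ``cells_on_column``).  Light groups (target and decoy) are
    scored against the heavy reference of the same peptide (decoys use their
    target's reference); sub-scores are z-scaled on the decoys, summed with
    ``weights`` and converted to q-values.  Returns one row per target peptide
    x replicate x spike with light/heavy areas, ratio, S/N and q-value.
    """
    df = peaks.copy()
    df["_key"] = (df["peptide_id"].astype(str) + "|" + df["replicate"].astype(str)
                  + "|" + df["spike_label"].astype(str))
    meta = df.drop_duplicates("_key")[
        ["_key", "protein_group_id", "peptide_id", "replicate", "spike_label",
         "spike_amount_mol", "noise_area", "decoy"]
    ].set_index("_key")
    wide = df.pivot(index="_key", columns=["label", "transition"], values="area")
    wide = wide.reindex(meta.index)
    n_tr = len({c[1] for c in wide.columns if c[0] == "light"})
    light_cols = [("light", i) for i in range(1, n_tr + 1)]
    heavy_cols = [("heavy", i) for i in range(1, n_tr + 1)]
    heavy_cols = [c for c in heavy_cols if c in wide.columns]
    meta = meta.reset_index(drop=True)
    L = wide[light_cols].to_numpy(dtype=float)
    is_decoy = meta["decoy"].to_numpy(dtype=bool)

    # heavy reference per (peptide, replicate, spike); decoys borrow the
    # reference of their target peptide
    target_pid = meta["peptide_id"].str.replace("^DECOY_", "", regex=True)
    href = wide[heavy_cols].to_numpy(dtype=float)
    ref_key = pd.MultiIndex.from_arrays(
        [target_pid, meta["replicate"], meta["spike_label"]]
    )
    own_key = pd.MultiIndex.from_arrays(
        [meta["peptide_id"], meta["replicate"], meta["spike_label"]]
    )
    href_df = pd.DataFrame(href, index=own_key)
    H = href_df.reindex(ref_key).to_numpy()

    noise = meta["noise_area"].to_numpy(dtype=float)
    light_total = np.nansum(L, axis=1)
    light_total = np.where(np.all(np.isnan(L), axis=1), np.nan, light_total)
    heavy_total = np.nansum(H, axis=1)
    sn = light_total / noise
    heavy_sn = heavy_total / noise

    # vectorised sub-scores; all-NaN rows (censored light groups) are masked below
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mL = np.nanmean(L, axis=1, keepdims=True)
        mH = np.nanmean(H, axis=1, keepdims=True)
        dL = L - mL
        dH = H - mH
        cov = np.nansum(dL * dH, axis=1)
        denom = np.sqrt(np.nansum(dL ** 2, axis=1) * np.nansum(dH ** 2, axis=1))
        corr = np.where(denom > 0, cov / denom, 0.0)
        nl = np.sqrt(np.nansum(L ** 2, axis=1))
        nh = np.sqrt(np.nansum(H ** 2, axis=1))
        dot = np.where((nl > 0) & (nh > 0), np.nansum(L * H, axis=1) / (nl * nh), 0.0)
        log_sn = np.log10(np.maximum(sn, 1e-12))

    detected = ~np.isnan(light_total)
    sub = np.column_stack([corr, dot, log_sn])
    sub[~detected] = np.nan

    dec_mask = is_decoy & detected
    mu = np.nanmean(sub[dec_mask], axis=0) if dec_mask.any() else np.zeros(3)
    sd = np.nanstd(sub[dec_mask], axis=0) if dec_mask.any() else np.ones(3)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    z = (sub - mu) / sd
    score = z @ np.asarray(weights, dtype=float)

    t_mask = ~is_decoy & detected
    d_mask = is_decoy & detected
    q = np.full(len(meta), np.nan)
    if t_mask.any():
        q[t_mask] = estimate_fdr(score[t_mask], score[d_mask]) if d_mask.any() else 0.0

    out = meta.loc[~is_decoy, ["protein_group_id", "peptide_id", "replicate",
                               "spike_label", "spike_amount_mol", "noise_area"]].copy()
    sel = (~is_decoy)
    out["light_area"] = light_total[sel]
    out["heavy_area"] = heavy_total[sel]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = light_total[sel] / heavy_total[sel]
    out["sn"] = sn[sel]
    out["heavy_sn"] = heavy_sn[sel]
    out["score"] = score[sel]
    out["q_value"] = q[sel]
    if "cells_on_column" in peaks.columns:
        cells = peaks.drop_duplicates("peptide_id").set_index("peptide_id")["cells_on_column"]
        out["cells_on_column"] = out["peptide_id"].map(cells)
    return out.reset_index(drop=True)
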