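"""Synthetic proteome / SRM / transcriptome data with known ground truth.

Emulates the statistical structure of a chemostat-grown yeast census
experiment: log-normal protein abundance spanning ~5 orders of magnitude,
two surrogate peptides per protein measured in 4 biological replicates at
three heavy-standard spike levels, a hard limit of detection producing
heavy-only (Type B) and failed (Type C) outcomes, decoy peak groups for FDR
estimation, and a matched transcriptome with log-normal per-gene
translational efficiency driven by configurable gene features.

All randomness flows from the single integer seed in :class:`SimConfig`
through one ``numpy.random.Generator``; identical configs give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design

__all__ = ["FeatureSpec", "SimConfig", "TruthTable",
           "simulate_truth", "simulate_srm", "simulate_transcriptome",
           "AVOGADRO"]

AVOGADRO = 6.02214e23

#: area units per mol of analyte on column (arbitrary instrument response)
AREA_PER_MOL = 1.0e20

_AA_POOL = "ADEFGHILNQSTVWY"  # no K/R/P/M/C: interior residues of clean tryptic peptides


@dataclass(frozen=True)
class FeatureSpec:
    """One gene-level covariate entering the generative model of log10 TE.

    ``main_coef`` multiplies the (centred, unit-variance) feature itself;
    ``interaction_coef`` multiplies feature x (log10 mRNA - mean), the form a
    translation model fits as an interaction with transcript abundance.
    ``kind`` is ``continuous`` (standard normal latent) or ``binary``
    (Bernoulli(prevalence)).
    """

    name: str
    main_coef: float = 0.0
    interaction_coef: float = 0.0
    kind: str = "continuous"
    prevalence: float = 0.5


def default_features() -> tuple[FeatureSpec, ...]:
    """Default covariates emulating the usual translational-control candidates.

    Signs follow the known relationships: codon adaptation (tAI) up, 4E-BP
    (CAF20) RIP enrichment down, transcript structure (PARS) up, poly-A tail
    length down, PEST degron presence (weakly) up, protein half-life up.
    Effect sizes are set once so that, with the residual TE spread, the
    default dataset has mRNA-only r^2 ~ 0.58 and full-model r^2 ~ 0.70 on
    log10 protein.
    """
    return (
        FeatureSpec("tai", 0.35),
        FeatureSpec("caf20_rip", -0.22),
        FeatureSpec("pars_score", 0.18),
        FeatureSpec("polya_length", -0.12),
        FeatureSpec("pest", 0.20, kind="binary", prevalence=0.5),
        FeatureSpec("half_life_min", 0.12),
    )


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults are the conditions of the emulated census experiment: four
    biological replicates at ~12% measurement CV per peak area, heavy-standard
    spikes at low 100-250 amol, medium 1-2 fmol and high 10-20 fmol, the
    protein equivalent of 200,000 cells on column, and a detection floor that
    yields Type A/B/C peptide fractions near 44/38/17%.
    """

    n_genes: int = 1000
    seed: int = 0

    # protein abundance: log10 cpc ~ Normal(mean, sd); sd 0.9 spans ~5 orders
    protein_log10_mean: float = 2.8
    protein_log10_sd: float = 0.9

    # translational efficiency (proteins per transcript): log-normal about the
    # median with residual log10 spread te_log10_sd on top of feature effects
    te_median: float = 1035.0
    te_log10_sd: float = 0.59
    features: tuple[FeatureSpec, ...] = field(default_factory=default_features)

    # SRM measurement
    n_replicates: int = 4
    replicate_cv: float = 0.12           # CV of each measured peak area
    spike_levels: tuple = (
        ("low", 100e-18, 250e-18),       # mol
        ("medium", 1e-15, 2e-15),
        ("high", 10e-15, 20e-15),
    )
    cells_on_column: float = 2.0e5
    lod_area: float = 1.7e4              # light peak groups below this are censored
    noise_area: float | None = None      # background; default lod_area / sn_at_lod
    sn_at_lod: float = 5.0
    light_dropout_prob: float = 0.02     # random loss of a light group
    peptide_fail_prob: float = 0.17      # assay fails entirely (Type C candidate)
    peptide_bias_log2_sd: float = 0.55   # per-peptide light response bias
    n_transitions: int = 3
    fpkm_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        for label, lo, hi in self.spike_levels:
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad spike range for {label!r}")
        if self.cells_on_column <= 0:
            raise ValueError("cells_on_column must be > 0")
        if self.noise_area is None:
            self.noise_area = self.lod_area / self.sn_at_lod if self.lod_area > 0 else 1e-6

    @classmethod
    def model_recovery(cls, seed: int, target_r2: float = 0.70,
                       n_genes: int = 1200) -> "SimConfig":
        """Conditions for translation-model parameter recovery.

        One main-effect feature, one pure-interaction feature and two null
        features; the residual TE spread is set so the generative full-model
        r^2 on log10 protein equals ``target_r2``:  with log10 protein the
        root variable, the best linear predictor from (log10 mRNA, features)
        achieves r^2 = sd_p^2 / (sd_p^2 + sd_eta^2), hence
        sd_eta = sd_p * sqrt((1 - r2) / r2).
        """
        p_sd = 0.9
        eta = p_sd * np.sqrt((1.0 - target_r2) / target_r2)
        return cls(
            n_genes=n_genes, seed=seed, protein_log10_sd=p_sd,
            te_log10_sd=float(eta),
            features=(
                FeatureSpec("feat_main", main_coef=0.35),
                FeatureSpec("feat_int", interaction_coef=0.25),
                FeatureSpec("null_a"), FeatureSpec("null_b"),
            ),
        )

    @classmethod
    def noise_free(cls, **kw) -> "SimConfig":
        """Conditions with every stochastic distortion switched off.

        Under these the quantification pipeline must invert the generator
        exactly (to floating-point rounding).
        """
        kw.setdefault("replicate_cv", 0.0)
        kw.setdefault("lod_area", 0.0)
        kw.setdefault("light_dropout_prob", 0.0)
        kw.setdefault("peptide_fail_prob", 0.0)
        kw.setdefault("peptide_bias_log2_sd", 0.0)
        kw.setdefault("fpkm_noise_cv", 0.0)
        return cls(**kw)


@dataclass
class TruthTable:
    """Ground truth: per-gene abundances, features and generative coefficients."""

    genes: pd.DataFrame          # gene_id, protein_cpc, mrna_cpc, te, features...
    coefficients: dict           # generative model coefficients
    total_protein_molecules: float
    total_mrna_molecules: float

    def __post_init__(self) -> None:
        g = self.genes
        if (g["protein_cpc"] <= 0).any() or (g["mrna_cpc"] <= 0).any():
            raise ValueError("cpc values must be positive")


def _lognorm_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with the given CV (log-normal, unit median)."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig) -> TruthTable:
    """Draw ground-truth protein/mRNA abundances and gene features.

    log10 protein cpc is Normal(protein_log10_mean, protein_log10_sd).
    log10 TE = log10(te_median) + sum of centred feature effects + residual,
    where interaction effects multiply the centred log10 mRNA; the implied
    relation  log10 P = log10 M + log10 TE  holds exactly per gene.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(1, n + 1)])

    log_p = rng.normal(config.protein_log10_mean, config.protein_log10_sd, n)

    feat_cols: dict[str, np.ndarray] = {}
    centred: dict[str, np.ndarray] = {}
    for spec in config.features:
        if spec.kind == "binary":
            x = (rng.random(n) < spec.prevalence).astype(float)
            z = x - spec.prevalence
        else:
            # truncated at +-3.5 sd: real covariates are bounded, and this keeps
            # the interaction solve (1 + sum coef*f) positive for |coef| < 0.28
            x = np.clip(rng.normal(0.0, 1.0, n), -3.5, 3.5)
            z = x - x.mean()
        feat_cols[spec.name] = x
        centred[spec.name] = z

    eta = rng.normal(0.0, config.te_log10_sd, n)
    main = sum(
        (spec.main_coef * centred[spec.name] for spec in config.features),
        start=np.zeros(n),
    )
    # With interaction terms, log10 TE depends on centred log10 M, which in
    # turn is log10 P - log10 TE; solving the linear relation per gene keeps
    #   log10 P = log10 M + c + sum(main) + sum(int * f * (log10 M - mean)) + eta
    # exact.  mean(log10 M) is approximated by its expectation
    # protein_log10_mean - log10(te_median).
    c = np.log10(config.te_median)
    int_coef = sum(
        (spec.interaction_coef * centred[spec.name] for spec in config.features),
        start=np.zeros(n),
    )
    mu_m = config.protein_log10_mean - c
    denom = 1.0 + int_coef
    if (denom <= 0).any():
        raise ValueError("interaction coefficients too large: 1 + sum(coef*f) <= 0")
    log_te = (c + main + int_coef * (log_p - mu_m) + eta) / denom
    # note: (log_p - log_te - mu_m) == centred log10 M up to the constant c;
    # the algebra above uses log10 M - mu_m = log_p - log_te - mu_m.
    log_m = log_p - log_te

    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "protein_cpc": 10.0 ** log_p,
        "mrna_cpc": 10.0 ** log_m,
        "te": 10.0 ** log_te,
        **feat_cols,
    })
    # half-life display units and turnover class (bins at 20 and 40 min)
    if "half_life_min" in genes:
        hl = 30.0 * 2.0 ** genes["half_life_min"]  # latent z -> minutes, median 30
        genes["half_life_min"] = hl
        genes["turnover_class"] = pd.cut(
            hl, bins=[0, 20, 40, np.inf], labels=["fast", "medium", "slow"]
        ).astype(str)

    coefs = {
        "te_log10_median": c,
        "te_log10_resid_sd": config.te_log10_sd,
        "mrna_log10_mean": mu_m,
        **{f"main:{s.name}": s.main_coef for s in config.features},
        **{f"interaction:{s.name}": s.interaction_coef for s in config.features},
    }
    return TruthTable(
        genes=genes,
        coefficients=coefs,
        total_protein_molecules=float(genes["protein_cpc"].sum()),
        total_mrna_molecules=float(genes["mrna_cpc"].sum()),
    )


# ---------------------------------------------------------------------------
# SRM peak data
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 15) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(_AA_POOL), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_srm(truth: TruthTable, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate SRM peak areas and the matching transition list.

    Returns ``(peak_table, transitions)``.  The peak table is per-transition,
    long format: one row per gene x peptide x transition x label x replicate
    x spike level, plus decoy rows (noise-only light signal with the decoy
    flag set).  Light areas are proportional to true cpc x cells / N_A times
    a per-peptide response bias and per-measurement log-normal noise; heavy
    areas are proportional to the spiked amount with the same per-measurement
    noise.  Light peak groups whose total area falls below ``lod_area`` are
    censored (area and S/N set to NaN), producing Type B outcomes; peptides
    hit by ``peptide_fail_prob`` yield background-level areas for both labels
    (Type C).
    """
    need = {"gene_id", "protein_cpc"}
    if not need <= set(truth.genes.columns):
        raise ValueError(f"truth table missing columns: {sorted(need - set(truth.genes.columns))}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = truth.genes
    n_genes = len(genes)
    n_pep = 2
    n_tr = config.n_transitions
    n_rep = config.n_replicates
    levels = list(config.spike_levels)
    n_lev = len(levels)

    # peptide identities and sequences
    pep_rows = []
    for gi, gene in enumerate(genes["gene_id"]):
        for pj in range(n_pep):
            seq = _random_peptide(rng)
            pep_rows.append((f"{gene}_P{pj + 1}", gene, seq))
    peptides = pd.DataFrame(pep_rows, columns=["peptide_id", "protein_group_id", "sequence"])

    # transition list (light + heavy pairs) with scheduled retention times
    rts = rng.uniform(5.0, 55.0, len(peptides))
    frag_idx = np.array([3, 5, 7])
    t_rows = []
    for (pid, gene, seq), rt in zip(pep_rows, rts):
        z = 2
        prec = design.compute_mz(seq, z, "precursor")
        shift = design.LABEL_SHIFT_13C6
        for k in frag_idx:
            k_eff = int(min(k, len(seq) - 1))
            for label, lab_shift in (("light", 0.0), ("heavy", shift)):
                t_rows.append({
                    "protein": gene, "peptide": seq, "peptide_id": pid,
                    "precursor_mz": round(prec + (lab_shift / z if label == "heavy" else 0.0), 4),
                    "precursor_charge": z,
                    "fragment_ion": f"y{k_eff}",
                    "product_mz": round(design.compute_mz(seq, 1, f"y{k_eff}", lab_shift), 4),
                    "product_charge": 1,
                    "label_type": label,
                    "expected_rt": round(float(rt), 2),
                })
    transitions = pd.DataFrame(t_rows)

    # per-peptide structure
    n_p = len(peptides)
    bias = 2.0 ** rng.normal(0.0, config.peptide_bias_log2_sd, n_p)
    failed = rng.random(n_p) < config.peptide_fail_prob
    # per-peptide relative transition intensity pattern (shared light/heavy)
    w = rng.dirichlet(np.full(n_tr, 5.0), size=n_p)

    spike_amounts = np.array([
        rng.uniform(lo, hi, size=1)[0] for (_, lo, hi) in levels
    ])  # one drawn amount per level, common to all peptides (one QconCAT pool)

    cpc = genes["protein_cpc"].to_numpy()
    light_mol = np.repeat(cpc, n_pep) * config.cells_on_column / AVOGADRO  # per peptide

    # noise: independent per peptide x replicate x level x label
    shape = (n_p, n_rep, n_lev)
    light_noise = _lognorm_factor(rng, config.replicate_cv, shape)
    heavy_noise = _lognorm_factor(rng, config.replicate_cv, shape)
    dropout = rng.random(shape) < config.light_dropout_prob

    light_total = (bias * light_mol)[:, None, None] * AREA_PER_MOL * light_noise
    heavy_total = spike_amounts[None, None, :] * AREA_PER_MOL * heavy_noise

    # censoring and failure
    censored = (light_total < config.lod_area) | dropout
    bg = config.noise_area
    fail_light = bg * _lognorm_factor(rng, 0.5, shape)
    fail_heavy = bg * _lognorm_factor(rng, 0.5, shape)
    light_total = np.where(failed[:, None, None], fail_light, light_total)
    heavy_total = np.where(failed[:, None, None], fail_heavy, heavy_total)
    censored = np.where(failed[:, None, None], False, censored)

    # assemble long table
    idx_p, idx_r, idx_l = np.meshgrid(
        np.arange(n_p), np.arange(n_rep), np.arange(n_lev), indexing="ij"
    )
    base = pd.DataFrame({
        "peptide_id": peptides["peptide_id"].to_numpy()[idx_p.ravel()],
        "protein_group_id": peptides["protein_group_id"].to_numpy()[idx_p.ravel()],
        "replicate": idx_r.ravel() + 1,
        "spike_label": np.array([l[0] for l in levels])[idx_l.ravel()],
        "spike_amount_mol": spike_amounts[idx_l.ravel()],
        "light_total": np.where(censored, np.nan, light_total).ravel(),
        "heavy_total": heavy_total.ravel(),
    })

    def explode(df: pd.DataFrame, label: str, col: str) -> pd.DataFrame:
        reps = df.loc[df.index.repeat(n_tr)].reset_index(drop=True)
        tr = np.tile(np.arange(1, n_tr + 1), len(df))
        area = df[col].to_numpy()[:, None] * w[idx_p.ravel()]
        reps["transition"] = tr
        reps["label"] = label
        reps["area"] = area.ravel()
        return reps

    light = explode(base, "light", "light_total")
    heavy = explode(base, "heavy", "heavy_total")
    peaks = pd.concat([light, heavy], ignore_index=True)
    peaks["decoy"] = False

    # decoy peak groups: background-only light signal, one per target peptide
    d_idx_p = np.arange(n_p)
    d_area = bg * _lognorm_factor(rng, 0.5, (n_p, n_rep, n_lev, n_tr))
    dp, dr, dl, dt = np.meshgrid(
        d_idx_p, np.arange(n_rep), np.arange(n_lev), np.arange(1, n_tr + 1), indexing="ij"
    )
    decoys = pd.DataFrame({
        "peptide_id": "DECOY_" + pd.Series(peptides["peptide_id"].to_numpy()[dp.ravel()]),
        "protein_group_id": "DECOY",
        "replicate": dr.ravel() + 1,
        "spike_label": np.array([l[0] for l in levels])[dl.ravel()],
        "spike_amount_mol": spike_amounts[dl.ravel()],
        "transition": dt.ravel(),
        "label": "light",
        "area": d_area.ravel(),
        "decoy": True,
    })
    # decoys are scored against the matching target heavy reference
    peaks = pd.concat(
        [peaks.drop(columns=["light_total", "heavy_total"]), decoys],
        ignore_index=True,
    )
    peaks["noise_area"] = bg
    peaks["cells_on_column"] = config.cells_on_column
    return peaks, transitions


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def simulate_transcriptome(truth: TruthTable, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table (proportional to true mRNA cpc, with noise) + feature table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = truth.genes
    noisy = genes["mrna_cpc"].to_numpy() * _lognorm_factor(rng, config.fpkm_noise_cv, len(genes))
    # arbitrary FPKM scale: normalise so the column sums to 5e5
    fpkm = noisy / noisy.sum() * 5.0e5
    fpkm_table = pd.DataFrame({"gene_id": genes["gene_id"], "fpkm": fpkm})
    feat_cols = [c for c in genes.columns if c not in
                 ("protein_cpc", "mrna_cpc", "te")]
    features = genes[feat_cols].copy()
    return fpkm_table, features
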