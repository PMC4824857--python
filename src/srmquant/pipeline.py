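"""End-to-end convenience wrappers: simulate -> score -> quantify."""

from __future__ import annotations

import pandas as pd

from . import peakscore, quant, syndata

__all__ = ["run_quantification", "simulate_and_quantify"]


def run_quantification(
    peak_table: pd.DataFrame,
    *,
    fdr_threshold: float = 0.01,
    sn_min: float = 5.0,
    min_pass: int = 3,
    discrepancy_threshold_log2: float | None = quant.DEFAULT_DISCREPANCY_LOG2,
    cells_on_column: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a long per-transition peak table and quantify peptides + proteins.

    Returns ``(peptide_table, protein_table)``.
    """
    scored = peakscore.score_table(peak_table)
    peptides = quant.quantify_peptides(
        scored, fdr_threshold=fdr_threshold, sn_min=sn_min,
        min_pass=min_pass, cells_on_column=cells_on_column,
    )
    proteins = quant.quantify_proteins(peptides, discrepancy_threshold_log2)
    return peptides, proteins


def simulate_and_quantify(config: syndata.SimConfig):
    """Generate a synthetic study and push it through the full pipeline.

    Returns ``(truth, peptide_table, protein_table)``.
    """
    truth = syndata.simulate_truth(config)
    peaks, _ = syndata.simulate_srm(truth, config)
    peptides, proteins = run_quantification(peaks)
    return truth, peptides, proteins
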