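"""Design quantotypic peptides and SRM transitions for a toy proteome.

Digests two proteins, selects two surrogate peptides each (unique, 7-25
residues, no Met/Cys, low missed-cleavage risk), assembles a QconCAT ordered
to minimise junction risk, and checks that a transition set fits a scheduled
SRM method (1.25 s cycle, 40 ms dwell -> at most 31 concurrent transitions).
"""

from srmquant import design

proteome = {
    "ENO2": "MAVSKVYARSVYDSRGNPTVEVELTTEKGVFRSIVPSGASTGVHEALEMRDGDKSKWLGKGVLHAVK",
    "PGK1": "MSLSSKLSVQDLDLKDKRVFIRVDFNVPLDGKKITSNQRIVAALPTIKYVLEHHPRYVVLASHLGRP",
}

counts: dict[str, int] = {}
digests = {}
for pid, seq in proteome.items():
    peps = design.digest_tryptic(seq, pid)
    digests[pid] = peps
    for s in {p.sequence for p in peps}:
        counts[s] = counts.get(s, 0) + 1

selected = []
for pid, peps in digests.items():
    best = design.select_quantotypic(peps, counts)
    selected.extend(best)
    for p in best:
        mz = design.compute_mz(p.sequence, 2)
        print(f"{pid}: {p.sequence:<22} risk={p.cleavage_risk:.2f} [M+2H]2+ = {mz:.4f}")

qconcat = design.assemble_qconcat(selected)
print(f"QconCAT: {qconcat.n_peptides} peptides, {qconcat.monoisotopic_mass:.1f} Da, "
      f"junction risk sum {qconcat.junction_risk_sum:.2f}")

glu_fib = design.compute_mz("EGVNDNEEGFFSAR", 2)
heavy = design.compute_mz("EGVNDNEEGFFSAR", 2, label_shift=design.LABEL_SHIFT_13C6)
print(f"glu-fibrinopeptide standard: light {glu_fib:.1f} / heavy {heavy:.1f} Th")
# The light/heavy pair (785.8 / 788.9) is the XIC pair used to quantify the
# heavy QconCAT stock against a known light spike.
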