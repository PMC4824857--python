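"""In-silico QconCAT/SRM assay design.

Tryptic digestion, quantotypic peptide selection, QconCAT assembly,
monoisotopic mass / m/z computation, transition selection and
acquisition-schedule feasibility for scheduled SRM on a triple quadrupole.

A QconCAT is an artificial protein concatenating surrogate ("Q") tryptic
peptides from many target proteins; expressed with stable-isotope labels it
yields one heavy internal standard per peptide on digestion.  Good Q-peptides
are *quantotypic*: reliably observed and stoichiometric with their parent —
no missed cleavage, no modifiable residues, unique in the proteome.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "PeptideCandidate",
    "QconCATDesign",
    "TransitionDef",
    "SRMSchedule",
    "PROTON_MASS",
    "LABEL_SHIFT_13C6",
    "LABEL_SHIFTS",
    "CLEAVAGE_RULES",
    "digest_tryptic",
    "cleavage_risk",
    "junction_risk",
    "select_quantotypic",
    "assemble_qconcat",
    "compute_mz",
    "peptide_monoisotopic_mass",
    "select_transitions",
    "schedule_srm",
]

PROTON_MASS = 1.007276
WATER_MASS = 18.0105646863

#: mass shift of common metabolic labels on a C-terminal K/R
LABEL_SHIFT_13C6 = 6.020129
LABEL_SHIFTS = {
    "13C6": 6.020129,            # 6 x (13.0033548 - 12)
    "13C6-15N2": 8.014199,       # Lys(+8)
    "13C6-15N4": 10.008269,      # Arg(+10)
}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Hand-rolled monoisotopic residue masses; kept as the single source used by
# compute_mz via pyteomics would be redundant -- pyteomics is authoritative,
# this table only documents valid residues.
_VALID_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass
class PeptideCandidate:
    """A fully tryptic peptide with its design context.

    Coordinates are 1-based inclusive within the parent protein.  ``n_flank``
    / ``c_flank`` are the residues immediately outside the peptide, or ``'-'``
    at a protein terminus.
    """

    sequence: str
    protein_id: str
    start: int
    end: int
    n_flank: str = "-"
    c_flank: str = "-"
    unique_in_proteome: bool | None = None
    cleavage_risk: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class QconCATDesign:
    peptides: list[PeptideCandidate]
    sequence: str
    monoisotopic_mass: float
    junction_risks: list[float]

    @property
    def junction_risk_sum(self) -> float:
        return float(sum(self.junction_risks))

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


@dataclass
class TransitionDef:
    """One precursor -> product ion pair monitored over time."""

    peptide: str
    precursor_charge: int
    precursor_mz: float
    fragment_type: str          # 'y' or 'b'
    fragment_index: int
    fragment_charge: int
    product_mz: float
    label: str = "light"        # 'light' | 'heavy'
    expected_rt: float | None = None  # minutes
    protein_id: str | None = None
    decoy: bool = False


@dataclass
class SRMSchedule:
    window_min: float
    cycle_time_s: float
    max_concurrent: int
    capacity: int
    feasible: bool
    concurrency: dict  # RT (min) -> number of concurrent transitions


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _check_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - AMINO_ACIDS)
        raise ValueError(f"illegal residue characters: {bad}")
    return seq


def digest_tryptic(sequence: str, protein_id: str = "") -> list[PeptideCandidate]:
    """Fully tryptic digest: cleave after K or R unless followed by P.

    The returned peptides tile the protein exactly (their concatenation equals
    the input sequence); flanking residues are recorded for cleavage-context
    scoring.
    """
    seq = _check_sequence(sequence)
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(seq)]
    out = []
    for s, e in zip(starts, ends):
        out.append(PeptideCandidate(
            sequence=seq[s:e],
            protein_id=protein_id,
            start=s + 1,
            end=e,
            n_flank=seq[s - 1] if s > 0 else "-",
            c_flank=seq[e] if e < len(seq) else "-",
        ))
    return out


# ---------------------------------------------------------------------------
# cleavage risk: explicit, versioned rule table
# ---------------------------------------------------------------------------

#: additive penalties for features of a tryptic cleavage site.  A site is the
#: junction K/R|X between the residue cleaved after (prev1) and the residue
#: following it (next1), with one further residue of context each side.
#: (name, penalty); conditions implemented in :func:`_site_risk`.
CLEAVAGE_RULES = [
    ("proline_block", 1.0),     # K/R followed by P: trypsin does not cleave
    ("acidic_neighbor", 0.25),  # D/E immediately adjacent to the site
    ("dibasic", 0.30),          # KK/RR/KR/RK at the site
]

_RULES = dict(CLEAVAGE_RULES)


def _site_risk(prev2: str, prev1: str, next1: str, next2: str) -> float:
    """Additive missed-cleavage risk for one site, clamped to [0, 1]."""
    if prev1 == "-" or next1 == "-":
        return 0.0  # protein terminus: no cleavage needed
    score = 0.0
    if next1 == "P":
        score += _RULES["proline_block"]
    if prev2 in "DE" or next1 in "DE":
        score += _RULES["acidic_neighbor"]
    if prev2 in "KR" or next1 in "KR":
        score += _RULES["dibasic"]
    return min(1.0, score)


def junction_risk(c_terminal_peptide: str, n_terminal_peptide: str) -> float:
    """Missed-cleavage risk of the junction formed by concatenating two peptides."""
    left = c_terminal_peptide
    right = n_terminal_peptide
    prev2 = left[-2] if len(left) >= 2 else "-"
    next2 = right[1] if len(right) >= 2 else "-"
    return _site_risk(prev2, left[-1], right[0], next2)


def cleavage_risk(peptide: PeptideCandidate) -> float:
    """Risk that the peptide is released sub-stoichiometrically on digestion.

    Both cleavage sites needed to release the peptide (N-terminal and
    C-terminal junction) are scored with the additive rule table; the peptide
    risk is the clamped sum, so it is monotone in every fired rule.
    """
    seq = peptide.sequence
    # N-terminal site: cleave after n_flank (K/R), before seq[0]
    n_site = _site_risk(
        "-" if peptide.n_flank == "-" else "?",  # prev2 unknown from flanks
        peptide.n_flank,
        seq[0],
        seq[1] if len(seq) >= 2 else "-",
    )
    # C-terminal site: cleave after seq[-1] (K/R), before c_flank
    c_site = _site_risk(
        seq[-2] if len(seq) >= 2 else "-",
        seq[-1],
        peptide.c_flank,
        "?",
    )
    return min(1.0, n_site + c_site)


# ---------------------------------------------------------------------------
# quantotypic selection
# ---------------------------------------------------------------------------

def select_quantotypic(
    candidates: Sequence[PeptideCandidate],
    proteome_peptide_counts: dict[str, int] | None = None,
    *,
    min_length: int = 7,
    max_length: int = 25,
    n_select: int = 2,
    max_risk: float = 0.99,
) -> list[PeptideCandidate]:
    """Rank candidates of one protein and return the best ``n_select``.

    Hard filters: length bounds, uniqueness in the proteome, no Met
    (oxidation) or Cys (alkylation variability), cleavage risk below
    ``max_risk``.  If the hard filters leave fewer than ``n_select``
    peptides, the modifiable-residue filter is relaxed and the returned
    peptides carry warning flags.  Ranking key: (cleavage risk, distance
    from the preferred length range midpoint, sequence).

    ``proteome_peptide_counts`` maps peptide sequence -> number of proteins
    it occurs in after digesting the full proteome; peptides occurring in
    more than one protein are excluded.
    """
    counts = proteome_peptide_counts or {}

    def base_ok(p: PeptideCandidate) -> bool:
        if not (min_length <= len(p.sequence) <= max_length):
            return False
        if counts.get(p.sequence, 1) > 1:
            return False
        p.unique_in_proteome = counts.get(p.sequence, 1) <= 1
        risk = cleavage_risk(p)
        p.cleavage_risk = risk
        return risk <= max_risk

    pool = [p for p in candidates if base_ok(p)]
    clean = [p for p in pool if not set(p.sequence) & {"M", "C"}]

    chosen = clean
    if len(clean) < n_select:
        fallback = [p for p in pool if p not in clean]
        for p in fallback:
            p.warnings.append("modifiable_residue")
        chosen = clean + fallback

    mid = (min_length + max_length) / 2.0
    ranked = sorted(
        chosen,
        key=lambda p: (p.cleavage_risk, abs(len(p.sequence) - mid), p.sequence),
    )
    return ranked[:n_select]


def _ordering_cost(seqs: Sequence[str]) -> float:
    return sum(junction_risk(a, b) for a, b in zip(seqs, seqs[1:]))


def assemble_qconcat(
    peptides: Sequence[PeptideCandidate],
    max_exhaustive: int = 7,
) -> QconCATDesign:
    """Order peptides to minimise the summed junction missed-cleavage risk.

    Exhaustive search up to ``max_exhaustive`` peptides; beyond that, greedy
    nearest-neighbour chains from every start plus the input ordering are
    compared and the best taken (never worse than the input ordering).
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    seqs = [p.sequence for p in peptides]
    n = len(seqs)
    if n == 1:
        best_order = [0]
    elif n <= max_exhaustive:
        best_order = min(
            itertools.permutations(range(n)),
            key=lambda perm: (_ordering_cost([seqs[i] for i in perm]), perm),
        )
    else:
        candidates = [list(range(n))]
        for start in range(n):
            order, left = [start], set(range(n)) - {start}
            while left:
                nxt = min(left, key=lambda j: (junction_risk(seqs[order[-1]], seqs[j]), j))
                order.append(nxt)
                left.remove(nxt)
            candidates.append(order)
        best_order = min(candidates, key=lambda o: _ordering_cost([seqs[i] for i in o]))
    ordered = [peptides[i] for i in best_order]
    cat = "".join(p.sequence for p in ordered)
    risks = [junction_risk(a.sequence, b.sequence) for a, b in zip(ordered, ordered[1:])]
    return QconCATDesign(
        peptides=list(ordered),
        sequence=cat,
        monoisotopic_mass=peptide_monoisotopic_mass(cat),
        junction_risks=risks,
    )


# ---------------------------------------------------------------------------
# masses and m/z
# ---------------------------------------------------------------------------

def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide (Da)."""
    return float(_pt_mass.fast_mass(_check_sequence(sequence)))


def compute_mz(
    sequence: str,
    charge: int,
    ion_spec: str = "precursor",
    label_shift: float = 0.0,
) -> float:
    """Monoisotopic m/z (Th) of a precursor or y/b fragment ion.

    ``ion_spec`` is ``"precursor"`` or e.g. ``"y7"`` / ``"b3"``.  ``label_shift``
    is the neutral-mass shift of a stable-isotope label; it is applied to the
    precursor and to y ions (which retain the labelled C-terminal K/R) but not
    to b ions.
    """
    seq = _check_sequence(sequence)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if ion_spec == "precursor":
        neutral = peptide_monoisotopic_mass(seq) + label_shift
        return (neutral + charge * PROTON_MASS) / charge

    m = re.match(r"^([yb])(\d+)$", ion_spec)
    if not m:
        raise ValueError(f"unknown ion spec {ion_spec!r}")
    ion_type, k = m.group(1), int(m.group(2))
    if not (1 <= k <= len(seq) - 1):
        raise ValueError(f"fragment index {k} out of range for {len(seq)}-mer")
    frag = seq[-k:] if ion_type == "y" else seq[:k]
    shift = label_shift if ion_type == "y" else 0.0
    # fast_mass with ion_type handles water (y keeps it, b does not) and protons
    mz = _pt_mass.fast_mass(frag, ion_type=ion_type, charge=charge)
    return float(mz + shift / charge)


# ---------------------------------------------------------------------------
# transition selection and scheduling
# ---------------------------------------------------------------------------

def select_transitions(
    fragments: Sequence[dict],
    precursor_mz: float,
    n_first: int = 6,
    n_final: int = 3,
) -> tuple[list[dict], list[dict]]:
    """Two-stage SRM transition selection.

    Stage 1 (design, from spectral libraries): rank by tier — y ions with
    product m/z above the precursor first — then by intensity descending; take
    ``n_first``.  Stage 2 (refinement, from on-instrument data): re-rank those
    by signal-to-background descending and take ``n_final``.  Ties break by
    fragment index ascending.  Each fragment dict needs keys ``fragment_type``,
    ``fragment_index``, ``product_mz``, ``intensity`` and, for stage 2,
    ``signal_to_background``.

    Returns ``(six, three)``.  Raises ``ValueError`` for < ``n_final``
    candidates (peptide unusable).
    """
    if len(fragments) < n_final:
        raise ValueError("peptide unusable: fewer than %d candidate fragments" % n_final)

    def tier(f: dict) -> int:
        return 0 if (f["fragment_type"] == "y" and f["product_mz"] > precursor_mz) else 1

    six = sorted(
        fragments,
        key=lambda f: (tier(f), -f["intensity"], f["fragment_index"]),
    )[:n_first]
    three = sorted(
        six,
        key=lambda f: (-f.get("signal_to_background", f["intensity"]), f["fragment_index"]),
    )[:n_final]
    return six, three


def schedule_srm(
    transitions: Iterable[TransitionDef],
    window_min: float = 3.0,
    peak_width_s: float = 15.0,
    points_per_peak: int = 12,
    min_dwell_s: float = 0.040,
) -> SRMSchedule:
    """Feasibility of a time-scheduled SRM method.

    Cycle time = peak width / points per peak (15 s / 12 = 1.25 s by default);
    at every retention time the transitions whose ±window/2 scheduling window
    covers it must all fit in one cycle at the minimum dwell, i.e. concurrency
    <= floor(cycle / dwell) (31 with the defaults).
    """
    cycle = peak_width_s / points_per_peak
    capacity = math.floor(cycle / min_dwell_s)
    half = window_min / 2.0
    rts = sorted({t.expected_rt for t in transitions if t.expected_rt is not None})
    trans = [t for t in transitions if t.expected_rt is not None]
    concurrency = {
        rt: sum(1 for t in trans if abs(t.expected_rt - rt) <= half)
        for rt in rts
    }
    max_conc = max(concurrency.values(), default=0)
    return SRMSchedule(
        window_min=window_min,
        cycle_time_s=cycle,
        max_concurrent=max_conc,
        capacity=capacity,
        feasible=max_conc <= capacity,
        concurrency=concurrency,
    )
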