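"""Assay design: digestion, cleavage risk, selection, masses, scheduling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srmquant import design
from srmquant.design import (
    PROTON_MASS, LABEL_SHIFT_13C6, PeptideCandidate, TransitionDef,
    assemble_qconcat, cleavage_risk, compute_mz, digest_tryptic,
    junction_risk, peptide_monoisotopic_mass, schedule_srm,
    select_quantotypic, select_transitions,
)

# independent residue-mass oracle (monoisotopic, Da) -- kept separate from the
# implementation's mass backend on purpose
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565


def oracle_precursor_mz(seq, z):
    return (sum(RESIDUE_MASS[a] for a in seq) + WATER + z * 1.00728) / z


aa_text = st.text(alphabet=sorted(RESIDUE_MASS), min_size=1, max_size=60)


class TestDigestion:
    @pytest.mark.parametrize("seq,expected", [
        ("MKRAPK", ["MK", "R", "APK"]),
        ("AKPR", ["AKPR"]),          # proline suppresses cleavage
        ("MK", ["MK"]),
        ("KKK", ["K", "K", "K"]),
    ])
    def test_cleavage_rule(self, seq, expected):
        assert [p.sequence for p in digest_tryptic(seq)] == expected

    @settings(max_examples=200, derandomize=True)
    @given(aa_text)
    def test_tiling_identity(self, seq):
        peps = digest_tryptic(seq)
        assert "".join(p.sequence for p in peps) == seq
        for p in peps:
            assert seq[p.start - 1:p.end] == p.sequence

    def test_flanks_recorded(self):
        peps = digest_tryptic("MKRAPK")
        assert peps[0].n_flank == "-" and peps[0].c_flank == "R"
        assert peps[2].n_flank == "R" and peps[2].c_flank == "-"

    def test_illegal_residue(self):
        with pytest.raises(ValueError):
            digest_tryptic("MKX")
        with pytest.raises(ValueError):
            digest_tryptic("")


class TestCleavageRisk:
    def test_plain_junctions_zero(self):
        p = PeptideCandidate("AAAK", "P", 1, 4, n_flank="K", c_flank="A")
        assert cleavage_risk(p) == 0.0

    def test_proline_blocked_site_maximal(self):
        p = PeptideCandidate("AAAK", "P", 1, 4, n_flank="K", c_flank="P")
        assert cleavage_risk(p) == 1.0

    def test_acidic_neighbor_monotone(self):
        lo = PeptideCandidate("AAAK", "P", 1, 4, n_flank="K", c_flank="A")
        hi = PeptideCandidate("AADK", "P", 1, 4, n_flank="K", c_flank="A")
        assert cleavage_risk(hi) > cleavage_risk(lo)

    def test_dibasic_junction_penalised(self):
        assert junction_risk("AAAK", "KAAA") > junction_risk("AAAK", "AAAA")


class TestQuantotypicSelection:
    def test_met_fallback_with_warning(self):
        peps = [PeptideCandidate("AAMAAAAK", "P", 1, 8, "K", "A"),
                PeptideCandidate("AAAMAAAR", "P", 9, 16, "K", "A")]
        sel = select_quantotypic(peps, {})
        assert len(sel) == 2
        assert all("modifiable_residue" in p.warnings for p in sel)

    def test_shared_peptide_excluded(self):
        shared = PeptideCandidate("AAAAAAAK", "P1", 1, 8, "K", "A")
        own = PeptideCandidate("TTTTTTTK", "P1", 9, 16, "K", "A")
        sel = select_quantotypic([shared, own], {"AAAAAAAK": 2, "TTTTTTTK": 1})
        assert [p.sequence for p in sel] == ["TTTTTTTK"]

    def test_filter_audit_on_synthetic_proteome(self, rng):
        # every selected peptide must pass all hard filters (brute force)
        proteins = {}
        for i in range(120):
            n = int(rng.integers(60, 200))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            proteins[f"P{i}"] = seq
        counts = {}
        digests = {}
        for pid, seq in proteins.items():
            peps = digest_tryptic(seq, pid)
            digests[pid] = peps
            for s in {p.sequence for p in peps}:
                counts[s] = counts.get(s, 0) + 1
        for pid, peps in digests.items():
            for p in select_quantotypic(peps, counts):
                assert 7 <= len(p.sequence) <= 25
                assert counts[p.sequence] == 1
                if not p.warnings:
                    assert not set(p.sequence) & {"M", "C"}


class TestQconCATAssembly:
    def test_single_peptide(self):
        p = PeptideCandidate("AAAK", "P", 1, 4, "K", "A")
        d = assemble_qconcat([p])
        assert d.sequence == "AAAK" and d.junction_risks == []

    def test_beats_identity_ordering(self, rng):
        for _ in range(20):
            peps = []
            for j in range(5):
                n = int(rng.integers(4, 10))
                seq = "".join(rng.choice(list("ADEKNPRST"), size=n - 1)) + "K"
                peps.append(PeptideCandidate(seq, f"P{j}", 1, n, "K", "A"))
            d = assemble_qconcat(peps)
            identity = sum(junction_risk(a.sequence, b.sequence)
                           for a, b in zip(peps, peps[1:]))
            assert d.junction_risk_sum <= identity + 1e-12
            # and matches the exhaustive optimum for n=5
            seqs = [p.sequence for p in peps]
            best = min(
                sum(junction_risk(seqs[a], seqs[b]) for a, b in zip(perm, perm[1:]))
                for perm in itertools.permutations(range(5))
            )
            assert d.junction_risk_sum == pytest.approx(best)

    def test_mass_additivity(self):
        peps = [PeptideCandidate(s, "P", 1, len(s), "K", "A")
                for s in ("AAAK", "TTTR", "GGGK")]
        d = assemble_qconcat(peps)
        expected = sum(sum(RESIDUE_MASS[a] for a in p.sequence) for p in peps) + WATER
        assert d.monoisotopic_mass == pytest.approx(expected, abs=1e-3)


class TestMz:
    def test_glu_fibrinopeptide_printed_value(self):
        assert round(compute_mz("EGVNDNEEGFFSAR", 2), 1) == 785.8

    def test_glycine_singly_protonated(self):
        assert compute_mz("G", 1) == pytest.approx(76.0393, abs=1e-3)

    def test_charge_state_identity(self):
        for seq in ("PEPTIDEK", "EGVNDNEEGFFSAR"):
            mz1 = compute_mz(seq, 1)
            mz2 = compute_mz(seq, 2)
            assert 2 * mz2 - 2 * PROTON_MASS == pytest.approx(mz1 - PROTON_MASS, abs=1e-9)

    def test_heavy_light_shift_exact(self):
        for z in (1, 2, 3):
            light = compute_mz("AAAK", z)
            heavy = compute_mz("AAAK", z, label_shift=LABEL_SHIFT_13C6)
            assert heavy - light == pytest.approx(LABEL_SHIFT_13C6 / z, abs=1e-12)

    def test_y_ion_contains_water_b_does_not(self):
        seq = "GASPK"
        y2 = compute_mz(seq, 1, "y2")
        b2 = compute_mz(seq, 1, "b2")
        assert y2 == pytest.approx(RESIDUE_MASS["P"] + RESIDUE_MASS["K"] + WATER + 1.00728, abs=1e-3)
        assert b2 == pytest.approx(RESIDUE_MASS["G"] + RESIDUE_MASS["A"] + 1.00728, abs=1e-3)

    def test_against_table_oracle_random_peptides(self, rng):
        aas = list(RESIDUE_MASS)
        for _ in range(1000):
            seq = "".join(rng.choice(aas, size=int(rng.integers(5, 25))))
            z = int(rng.integers(1, 4))
            assert compute_mz(seq, z) == pytest.approx(oracle_precursor_mz(seq, z), abs=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_mz("AAAK", 0)
        with pytest.raises(ValueError):
            compute_mz("AAAK", 1, "y9")
        with pytest.raises(ValueError):
            compute_mz("AAAK", 1, "z3")


def _frag(ftype, idx, mz, inten, sb=None):
    return {"fragment_type": ftype, "fragment_index": idx, "product_mz": mz,
            "intensity": inten, "signal_to_background": sb if sb is not None else inten}


class TestTransitionSelection:
    def test_above_precursor_y_ions_ranked_first(self):
        frags = [_frag("y", i, 400.0 + i, 100.0) for i in range(1, 9)]
        frags += [_frag("y", 9, 900.0, 100.0), _frag("y", 10, 950.0, 100.0)]
        six, _ = select_transitions(frags, precursor_mz=800.0)
        assert {f["product_mz"] for f in six[:2]} == {900.0, 950.0}

    def test_deterministic_tie_break_by_index(self):
        frags = [_frag("b", i, 300.0 + i, 50.0) for i in (5, 3, 8, 1, 2, 4, 7)]
        six, three = select_transitions(frags, precursor_mz=800.0)
        assert [f["fragment_index"] for f in six] == [1, 2, 3, 4, 5, 7]
        assert [f["fragment_index"] for f in three] == [1, 2, 3]

    def test_trio_subset_of_six(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 12))
            frags = [
                _frag(rng.choice(["y", "b"]), i, float(rng.uniform(200, 1200)),
                      float(rng.uniform(1, 100)), float(rng.uniform(1, 50)))
                for i in range(1, n + 1)
            ]
            six, three = select_transitions(frags, precursor_mz=700.0)
            ids = {(f["fragment_type"], f["fragment_index"]) for f in six}
            assert all((f["fragment_type"], f["fragment_index"]) in ids for f in three)

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            select_transitions([_frag("y", 1, 500, 10)], precursor_mz=700.0)


class TestScheduling:
    def _transitions(self, n, rt=20.0):
        return [TransitionDef("PEPK", 2, 500.0, "y", 3, 1, 600.0, expected_rt=rt)
                for _ in range(n)]

    def test_capacity_bound(self):
        # 1.25 s cycle / 40 ms dwell -> 31 concurrent transitions fit, 32 do not
        assert schedule_srm(self._transitions(31)).feasible
        sched = schedule_srm(self._transitions(32))
        assert not sched.feasible and sched.capacity == 31

    def test_cycle_time(self):
        assert schedule_srm([]).cycle_time_s == pytest.approx(1.25)

    def test_empty_is_feasible(self):
        sched = schedule_srm([])
        assert sched.feasible and sched.max_concurrent == 0

    def test_disjoint_windows_do_not_stack(self):
        ts = self._transitions(20, rt=10.0) + self._transitions(20, rt=40.0)
        assert schedule_srm(ts).feasible
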