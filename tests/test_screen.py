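"""The screening funnel, spectral similarity and mass-shift verification."""

import dataclasses

import numpy as np
import pytest

from adductscreen.chem import Peptidoform, peptide_neutral_mass, precursor_mz
from adductscreen.screen import (
    CandidateRecord,
    ScreenCriteria,
    apply_funnel,
    collect_modified_proteins,
    identified_both,
    prioritize,
    reliability_filter,
    spectral_similarity,
    verify_mass_shift,
)
from adductscreen.search import PSM
from adductscreen.synthetic_data import reference_candidates


def make_psm(protein, seq, mods, charge=2, score=3.0, group="treated",
             start=1, pmz=None):
    pf = Peptidoform(seq, mods, protein, start)
    if pmz is None:
        pmz = precursor_mz(peptide_neutral_mass(pf), charge)
    return PSM(f"{protein}|{seq}|{group}", pf, charge, score,
               group=group, precursor_mz=pmz, q_value=0.0)


def test_collect_dedups_by_protein(jb, cam):
    psms = [
        make_psm("A", "ACDK", {2: jb}, score=2.0),
        make_psm("A", "ACDK", {2: jb}, score=5.0, charge=3),
        make_psm("B", "CEFK", {1: jb}, score=1.0),
        make_psm("C", "CEFK", {1: cam}, score=4.0),  # no adduct -> excluded
    ]
    recs = collect_modified_proteins(psms, jb, {"A": "Cytoplasm"})
    assert [r.protein for r in recs] == ["A", "B"]
    a = recs[0]
    assert a.xcorr == 5.0 and a.charge == 3 and a.location == "Cytoplasm"


def test_collect_empty_without_adduct(jb, cam):
    assert collect_modified_proteins(
        [make_psm("A", "ACDK", {2: cam})], jb
    ) == []


def test_reliability_thresholds_from_reference_table():
    recs = reliability_filter(reference_candidates())
    passing = {r.protein for r in recs if r.passes_reliability}
    assert passing == {"TOM40", "DTX1"}


def test_reliability_unlisted_charge_fails_closed():
    r = CandidateRecord(protein="NID2", charge=4, xcorr=1.93)
    assert reliability_filter([r])[0].passes_reliability is False


def test_reliability_boundary_is_strict():
    r = CandidateRecord(protein="X", charge=2, xcorr=2.2)
    assert reliability_filter([r])[0].passes_reliability is False
    r2 = CandidateRecord(protein="X", charge=2, xcorr=2.2000001)
    assert reliability_filter([r2])[0].passes_reliability is True


def test_identified_both_site_level(jb, cam):
    psms = [
        make_psm("A", "ACDK", {2: cam}, group="control"),
        make_psm("A", "ACDK", {2: jb}, group="treated"),
        # B: adduct only in treated, never alkylated in control
        make_psm("B", "CEFK", {1: jb}, group="treated"),
        # C: alkylated in control, adduct at a DIFFERENT site in treated
        make_psm("C", "CACK", {1: cam}, group="control"),
        make_psm("C", "CACK", {3: jb}, group="treated"),
    ]
    both = identified_both(psms, jb)
    assert both == {"A": True, "B": False, "C": False}


def test_identified_both_respects_protein_position(jb, cam):
    # same peptide sequence but at different positions in the protein
    psms = [
        make_psm("A", "ACDK", {2: cam}, group="control", start=1),
        make_psm("A", "ACDK", {2: jb}, group="treated", start=11),
    ]
    assert identified_both(psms, jb)["A"] is False


def test_prioritize_reference_table_top_candidate():
    recs = reliability_filter(reference_candidates())
    ranked = prioritize(recs)
    assert ranked[0].protein == "TOM40"
    assert ranked[0].priority_rank == 1
    # permutation invariance
    rev = prioritize(list(reversed(recs)))
    assert [r.protein for r in rev] == [r.protein for r in ranked]


def test_prioritize_all_filters_off_is_xcorr_order():
    recs = [
        CandidateRecord(protein=p, charge=2, xcorr=x,
                        identified_both=False, passes_reliability=False)
        for p, x in [("A", 1.0), ("B", 3.0), ("C", 2.0)]
    ]
    crit = ScreenCriteria(phenotype_terms=("nosuchterm",))
    ranked = prioritize(recs, crit)
    assert [r.protein for r in ranked] == ["B", "C", "A"]


def test_funnel_monotone():
    recs = reliability_filter(reference_candidates())
    loose = ScreenCriteria(require_identified_both=False,
                           phenotype_terms=("",))  # matches everything
    strict = ScreenCriteria()
    assert {r.protein for r in apply_funnel(recs, strict)} <= {
        r.protein for r in apply_funnel(recs, loose)
    }


def test_funnel_single_survivor_from_reference_table():
    surv = apply_funnel(reference_candidates())
    assert len(surv) == 1
    assert surv[0].protein == "TOM40"
    assert surv[0].xcorr == pytest.approx(5.42)


def test_similarity_identity_and_disjoint():
    a = np.array([[100.0, 50.0], [200.0, 100.0]])
    assert spectral_similarity(a, a.copy()) == pytest.approx(1.0)
    b = np.array([[500.0, 50.0], [600.0, 100.0]])
    assert spectral_similarity(a, b) == 0.0
    with pytest.raises(ValueError):
        spectral_similarity(a, np.empty((0, 2)))


def test_similarity_symmetric_scale_invariant(rng):
    for _ in range(100):
        n, m = rng.integers(2, 20, 2)
        a = np.column_stack([rng.uniform(100, 1000, n), rng.uniform(1, 100, n)])
        b = np.column_stack([rng.uniform(100, 1000, m), rng.uniform(1, 100, m)])
        sab = spectral_similarity(a, b)
        assert sab == pytest.approx(spectral_similarity(b, a), abs=1e-12)
        assert 0.0 <= sab <= 1.0
        a_scaled = np.column_stack([a[:, 0], a[:, 1] * 13.7])
        assert spectral_similarity(a_scaled, b) == pytest.approx(sab, abs=1e-12)


def test_similarity_robust_to_small_intensity_jitter(rng):
    ok = 0
    for _ in range(100):
        n = int(rng.integers(10, 30))
        a = np.column_stack([rng.uniform(100, 1500, n), rng.uniform(5, 100, n)])
        jit = a.copy()
        jit[:, 1] *= rng.normal(1.0, 0.05, n).clip(0.01)
        if spectral_similarity(a, jit) > 0.95:
            ok += 1
    assert ok == 100


def test_verify_mass_shift_exact_pair(jb, cam):
    alk = make_psm("A", "LELCDER", {4: cam}, group="control")
    add = make_psm("A", "LELCDER", {4: jb}, group="treated")
    obs, theo, ok = verify_mass_shift(alk, add, jb)
    assert theo == pytest.approx(273.162, abs=1e-3)
    assert obs == pytest.approx(theo, abs=1e-6)
    assert ok


def test_verify_mass_shift_identical_psms(jb, cam):
    alk = make_psm("A", "LELCDER", {4: cam}, group="control")
    obs, theo, ok = verify_mass_shift(alk, alk, jb)
    assert obs == 0.0 and not ok


def test_verify_mass_shift_jitter_exceeds_tolerance(jb, cam):
    alk = make_psm("A", "LELCDER", {4: cam}, group="control")
    add = make_psm("A", "LELCDER", {4: jb}, group="treated")
    add = dataclasses.replace(
        add, precursor_mz=add.precursor_mz + 0.05 / add.charge
    )
    _, _, ok = verify_mass_shift(alk, add, jb)
    assert not ok


def test_verify_mass_shift_rejects_sequence_mismatch(jb, cam):
    alk = make_psm("A", "LELCDER", {4: cam})
    add = make_psm("A", "ACDK", {2: jb})
    with pytest.raises(ValueError):
        verify_mass_shift(alk, add, jb)
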