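"""Tryptic digestion, peptidoform enumeration and fragment generation,
checked against independent brute-force enumerators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adductscreen.chem import PROTON, WATER, Peptidoform, peptide_neutral_mass
from adductscreen.digest import (
    DigestConfig,
    digest,
    enumerate_peptidoforms,
    fragment,
    read_fasta,
)


def brute_force_digest(seq, max_mc, min_len=1, max_len=10**9):
    """Independent oracle: enumerate all segments bounded by cleavage
    sites (after K/R not before P) or termini."""
    cut_after = [
        i for i in range(len(seq))
        if seq[i] in "KR" and (i == len(seq) - 1 or seq[i + 1] != "P")
    ]
    bounds = [0] + [c + 1 for c in cut_after]
    if bounds[-1] != len(seq):
        bounds.append(len(seq))
    out = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_mc, len(bounds))):
            pep = seq[bounds[i]:bounds[j]]
            if min_len <= len(pep) <= max_len:
                out.add((pep, bounds[i] + 1))
    return out


WIDE = DigestConfig(max_missed_cleavages=0, min_length=1, max_length=100)


@pytest.mark.parametrize(
    "seq, mc, expected",
    [
        ("AKRPCK", 0, {"AK", "RPCK"}),      # no cleavage before P
        ("AAAA", 2, {"AAAA"}),              # no K/R at all
        ("AKCK", 1, {"AK", "CK", "AKCK"}),
    ],
)
def test_digest_examples(seq, mc, expected):
    cfg = DigestConfig(max_missed_cleavages=mc, min_length=1, max_length=100)
    assert {p.sequence for p in digest(seq, cfg)} == expected


@given(
    st.text(alphabet="ACDGKPRSV", min_size=1, max_size=15),
    st.integers(0, 3),
)
@settings(max_examples=200, deadline=None)
def test_digest_matches_brute_force(seq, mc):
    cfg = DigestConfig(max_missed_cleavages=mc, min_length=1, max_length=100)
    got = {(p.sequence, p.start) for p in digest(seq, cfg)}
    assert got == brute_force_digest(seq, mc)


@given(st.text(alphabet="ACDGKPRSV", min_size=1, max_size=15), st.integers(1, 3))
@settings(max_examples=100, deadline=None)
def test_digest_missed_cleavage_superset(seq, mc):
    lo = DigestConfig(max_missed_cleavages=mc - 1, min_length=1, max_length=100)
    hi = DigestConfig(max_missed_cleavages=mc, min_length=1, max_length=100)
    assert {(p.sequence, p.start) for p in digest(seq, lo)} <= {
        (p.sequence, p.start) for p in digest(seq, hi)
    }


def test_digest_positions_are_one_based():
    peps = {p.sequence: p.start for p in digest("AKRPCK", WIDE)}
    assert peps == {"AK": 1, "RPCK": 3}


@pytest.mark.parametrize(
    "peptide, cap, expected_count",
    [("ACDK", 4, 3), ("ADEK", 4, 1), ("CC", 1, 3)],
)
def test_enumerate_counts(registry, jb, cam, peptide, cap, expected_count):
    mods = [jb, cam] if peptide != "CC" else [jb]
    cfg = DigestConfig(min_length=1, max_variable_mods=cap)
    forms = enumerate_peptidoforms(peptide, mods, cfg, protein_nterm=False)
    assert len(forms) == expected_count
    # the unmodified form is always present
    assert any(not f.mods for f in forms)


def brute_force_count(n_sites, n_mods, cap):
    """Closed-form/brute-force count of site assignments: each site gets
    one of (none | one of n_mods), at most cap sites modified."""
    total = 0
    for chosen in range(0, min(n_sites, cap) + 1):
        total += math.comb(n_sites, chosen) * n_mods**chosen
    return total


@pytest.mark.parametrize("n_sites", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("cap", [0, 1, 2, 4])
def test_enumeration_matches_combinatorics(jb, cam, n_sites, cap):
    peptide = "A" + "C" * n_sites + "K"
    cfg = DigestConfig(min_length=1, max_variable_mods=cap)
    forms = enumerate_peptidoforms(peptide, [jb, cam], cfg, protein_nterm=False)
    assert len(forms) == brute_force_count(n_sites, 2, cap)
    assert len({f.key() for f in forms}) == len(forms)  # all distinct


def test_static_mods_do_not_count_against_cap(registry):
    tmt, cam, ox = registry["TMT6"], registry["carbamidomethyl"], registry["oxidation"]
    cfg = DigestConfig(min_length=1, max_variable_mods=1)
    forms = enumerate_peptidoforms(
        "MCAK", [ox], cfg, static_mods=[tmt, cam], protein_nterm=False
    )
    # every form carries TMT on N-term and K plus carbamidomethyl on C
    for f in forms:
        assert f.mods["N-term"].name == "TMT6"
        assert f.mods[4].name == "TMT6"
        assert f.mods[2].name == "carbamidomethyl"
    assert len(forms) == 2  # with/without oxidation


def test_fragment_smallest_case():
    frags = fragment(Peptidoform("GG"), 1)
    by = {(f.ion_type, f.index): f.mz for f in frags}
    assert set(by) == {("b", 1), ("y", 1)}
    # y1 = glycine residue + water + proton
    assert by[("y", 1)] == pytest.approx(57.02146 + WATER + PROTON, abs=1e-4)


def test_fragment_mod_shifts_prefixes(jb):
    plain = {(f.ion_type, f.index): f.mz for f in fragment(Peptidoform("ACDK"))}
    modded = {
        (f.ion_type, f.index): f.mz
        for f in fragment(Peptidoform("ACDK", {2: jb}))
    }
    for i in range(1, 4):
        expected_shift = jb.delta if i >= 2 else 0.0
        assert modded[("b", i)] - plain[("b", i)] == pytest.approx(
            expected_shift, abs=1e-9
        )
        # complementary y ions shift iff they contain C2, i.e. y_j with j >= 3
        y_shift = jb.delta if (4 - i) >= 3 else 0.0
        assert modded[("y", 4 - i)] - plain[("y", 4 - i)] == pytest.approx(
            y_shift, abs=1e-9
        )


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=12))
@settings(max_examples=100, deadline=None)
def test_by_complementarity(seq):
    p = Peptidoform(seq)
    frags = {(f.ion_type, f.index): f.mz for f in fragment(p)}
    n = len(seq)
    neutral = peptide_neutral_mass(p)
    for i in range(1, n):
        b, y = frags[("b", i)], frags[("y", n - i)]
        # singly-charged b_i + y_(n-i) = neutral + 2 protons
        assert b + y == pytest.approx(neutral + 2 * PROTON, abs=1e-9)


def test_fragment_requires_two_residues():
    with pytest.raises(ValueError):
        fragment(Peptidoform("G"))


def test_read_fasta_parses_location(tmp_path):
    f = tmp_path / "db.fasta"
    f.write_text(
        ">P1 location=Mitochondrion outer membrane\nMAKCR\n"
        ">P2 some description\nMMKR\n"
    )
    seqs, locs = read_fasta(f)
    assert seqs == {"P1": "MAKCR", "P2": "MMKR"}
    assert locs == {"P1": "Mitochondrion outer membrane"}
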