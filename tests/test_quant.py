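"""TMT normalization, moderated-t DEP calling, ORA and GSEA."""

import math

import numpy as np
import pandas as pd
import pytest

from adductscreen.quant import (
    QuantMatrix,
    differential,
    gsea_es,
    normalize_channels,
    ora_enrichment,
    read_gmt,
    write_gmt,
)

GROUPS = {"C1": "control", "C2": "control", "C3": "control",
          "T1": "treated", "T2": "treated", "T3": "treated"}


def make_qm(data, provenance="whole-cell"):
    df = pd.DataFrame(data, columns=list(GROUPS))
    df.index = [f"P{i}" for i in range(len(df))]
    return QuantMatrix(df, GROUPS, provenance)


def test_quant_matrix_validation():
    df = pd.DataFrame(np.ones((2, 6)), columns=list(GROUPS))
    with pytest.raises(ValueError):
        QuantMatrix(df, {c: "control" for c in GROUPS})  # no treated group
    with pytest.raises(ValueError):
        QuantMatrix(-df, GROUPS)


def test_normalize_equal_medians_unchanged(rng):
    base = rng.lognormal(10, 1, (50, 1)) * np.ones((1, 6))
    qm = normalize_channels(make_qm(base))
    np.testing.assert_allclose(qm.data.values, base, rtol=1e-12)


def test_normalize_restores_scaled_channel(rng):
    base = rng.lognormal(10, 1, (200, 1)) * np.ones((1, 6))
    skew = base.copy()
    skew[:, 2] *= 2.0
    qm = normalize_channels(make_qm(skew))
    med = np.log2(qm.data).median(axis=0)
    assert np.ptp(med.values) < 1e-9


def test_normalize_rejects_zero_channel():
    data = np.ones((3, 6))
    data[:, 0] = 0.0
    with pytest.raises(ValueError):
        normalize_channels(make_qm(data))


def test_differential_null_no_calls(rng):
    base = rng.lognormal(14, 1, 100)[:, None] * rng.lognormal(0, 0.1, (100, 6))
    dep = differential(make_qm(base))
    assert set(dep.columns) == {"log2fc", "p", "fdr", "call"}
    assert (dep["call"] == "none").all()


def test_differential_identical_groups_fc_zero():
    data = np.tile(np.linspace(1e5, 2e5, 10)[:, None], (1, 6))
    dep = differential(make_qm(data))
    np.testing.assert_allclose(dep["log2fc"], 0.0, atol=1e-12)
    assert (dep["call"] == "none").all()


def test_differential_label_swap_symmetry(rng):
    data = rng.lognormal(14, 0.5, (50, 6))
    data[:5, 3:] *= 4.0  # strong up in treated
    qm = make_qm(data)
    dep = differential(qm)
    swapped = QuantMatrix(
        qm.data, {c: ("treated" if g == "control" else "control")
                  for c, g in qm.groups.items()},
    )
    dep_sw = differential(swapped)
    np.testing.assert_allclose(dep["log2fc"], -dep_sw["log2fc"], atol=1e-12)
    np.testing.assert_allclose(dep["p"], dep_sw["p"], atol=1e-12)
    assert ((dep["call"] == "up") == (dep_sw["call"] == "down")).all()


def test_differential_requires_replicates():
    df = pd.DataFrame(np.ones((3, 3)), columns=["C1", "T1", "T2"])
    qm = QuantMatrix(df, {"C1": "control", "T1": "treated", "T2": "treated"})
    with pytest.raises(ValueError):
        differential(qm)


def test_bh_qvalues_monotone_in_p(rng):
    data = rng.lognormal(14, 0.5, (300, 6))
    data[:30, 3:] *= rng.uniform(1.2, 3.0, (30, 3))
    dep = differential(make_qm(data)).sort_values("p")
    fdr = dep["fdr"].values
    assert (np.diff(fdr) >= -1e-12).all()
    assert (fdr >= dep["p"].values - 1e-12).all()


def exact_hypergeom_upper(k, N, m, n):
    """Oracle: P(X >= k) by direct combinatorial enumeration."""
    num = sum(
        math.comb(m, j) * math.comb(N - m, n - j)
        for j in range(k, min(m, n) + 1)
        if n - j <= N - m
    )
    return num / math.comb(N, n)


def test_ora_exact_small_configuration():
    bg = [f"g{i}" for i in range(10)]
    res = ora_enrichment(bg[:5], {"t": bg[:5]}, bg)
    assert res.loc["t", "p"] == pytest.approx(1 / 252, rel=1e-12)


def test_ora_matches_enumeration_all_small_configs():
    for N in range(2, 13):
        bg = [f"g{i}" for i in range(N)]
        for m in range(0, N + 1):
            for n in range(1, N + 1):
                deps = bg[:n]
                members = bg[N - m:]  # overlap k = max(0, n - (N - m))
                k = len(set(deps) & set(members))
                res = ora_enrichment(deps, {"t": members}, bg)
                expected = exact_hypergeom_upper(k, N, m, n) if m else 1.0
                assert res.loc["t", "p"] == pytest.approx(expected, rel=1e-9), (
                    N, m, n, k
                )


def test_ora_degenerate_full_overlap_p_one():
    bg = ["a", "b", "c"]
    res = ora_enrichment(bg, {"t": bg}, bg)
    assert res.loc["t", "p"] == pytest.approx(1.0)


def test_ora_rejects_empty_background():
    with pytest.raises(ValueError):
        ora_enrichment(["a"], {"t": ["a"]}, [])


def test_ora_planted_term_smallest_p(rng):
    bg = [f"g{i}" for i in range(100)]
    deps = bg[:10]
    sets = {"planted": bg[:12],
            "rand1": list(rng.choice(bg, 12, replace=False)),
            "rand2": list(rng.choice(bg, 12, replace=False))}
    res = ora_enrichment(deps, sets, bg)
    assert res["p"].idxmin() == "planted"


def ranking(n=100):
    scores = np.linspace(3, -3, n)
    return pd.Series(scores, index=[f"g{i}" for i in range(n)])


def test_gsea_top_block_enriched():
    r = ranking()
    es, nes, p = gsea_es(r, [f"g{i}" for i in range(10)], n_perm=1000, seed=1)
    assert es > 0 and nes > 1
    assert p <= 0.002


def test_gsea_reversed_ranking_flips_sign():
    r = ranking()
    top = [f"g{i}" for i in range(10)]
    es, _, _ = gsea_es(r, top, n_perm=10, seed=1)
    es_rev, _, _ = gsea_es(-r, top, n_perm=10, seed=1)
    assert es > 0 > es_rev


def test_gsea_random_set_nes_near_one(rng):
    r = ranking()
    nes_abs = []
    for b in range(20):
        members = list(rng.choice(r.index, 10, replace=False))
        _, nes, _ = gsea_es(r, members, n_perm=200, seed=100 + b)
        nes_abs.append(abs(nes))
    assert 0.7 < np.mean(nes_abs) < 1.4


def test_gsea_rejects_unknown_members():
    with pytest.raises(ValueError):
        gsea_es(ranking(), ["not_a_gene"], n_perm=10)


def test_gmt_roundtrip(tmp_path):
    sets = {"a": ["x", "y"], "b": ["z"]}
    p = tmp_path / "sets.gmt"
    write_gmt(sets, p)
    assert read_gmt(p) == sets
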