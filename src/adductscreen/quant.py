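"""TMT reporter quantification: normalization, differential expression,
over-representation and GSEA enrichment.

Differential calls use a moderated two-sample t on log2 intensities:
per-protein pooled variances are shrunk toward the mean variance with a
prior weight of 10 pseudo-replicates, and p-values use the augmented
degrees of freedom.  Calls require both the fold-change criterion on the
linear scale (> 1.5 up, < 0.67 down, both taken literally) and
Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantMatrix",
    "normalize_channels",
    "differential",
    "ora_enrichment",
    "gsea_es",
    "read_gmt",
    "write_gmt",
    "DEP_FC_UP",
    "DEP_FC_DOWN",
    "DEP_FDR",
]

DEP_FC_UP = 1.5
DEP_FC_DOWN = 0.67
DEP_FDR = 0.05

#: prior weight (pseudo-replicates) for variance shrinkage
PRIOR_DF = 10.0


@dataclass
class QuantMatrix:
    """Proteins x channels reporter-intensity table with group labels.

    ``groups`` maps each column of ``data`` to ``"control"`` or
    ``"treated"``; ``provenance`` records whether the sample was a
    whole-cell or mitochondrial preparation.
    """

    data: pd.DataFrame
    groups: Mapping[str, str]
    provenance: str = "whole-cell"

    def __post_init__(self) -> None:
        self.groups = dict(self.groups)
        missing = set(self.data.columns) - set(self.groups)
        if missing:
            raise ValueError(f"channels without group labels: {sorted(missing)}")
        labels = set(self.groups.values())
        if not {"control", "treated"} <= labels:
            raise ValueError("both control and treated channels are required")
        if (self.data.values < 0).any():
            raise ValueError("negative intensities")

    def channels(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = self.data.copy()
        df.index.name = "protein"
        header = "#groups\t" + "\t".join(self.groups[c] for c in df.columns)
        with open(path, "w") as fh:
            fh.write(f"#provenance\t{self.provenance}\n{header}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "QuantMatrix":
        with open(path) as fh:
            prov_line = fh.readline().rstrip("\n").split("\t")
            group_line = fh.readline().rstrip("\n").split("\t")
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if prov_line[0] != "#provenance" or group_line[0] != "#groups":
            raise ValueError("malformed QuantMatrix TSV header")
        groups = dict(zip(df.columns, group_line[1:]))
        return cls(df, groups, prov_line[1])


def normalize_channels(qm: QuantMatrix) -> QuantMatrix:
    """Equalize per-channel medians of log2 intensity to the grand median."""
    data = qm.data
    if len(data) < 1:
        raise ValueError("empty quantification matrix")
    if (data <= 0).all(axis=0).any():
        raise ValueError("channel with no positive intensities")
    log2 = np.log2(data.where(data > 0))
    med = log2.median(axis=0)
    grand = float(np.median(med.values))
    scaled = data * np.power(2.0, grand - med)
    return QuantMatrix(scaled, qm.groups, qm.provenance)


def differential(qm: QuantMatrix) -> pd.DataFrame:
    """Per-protein moderated two-sample t on log2 intensities.

    Returns a frame indexed by protein with columns ``log2fc`` (treated
    minus control), ``p``, ``fdr`` and ``call`` (up / down / none).
    """
    ctrl = qm.channels("control")
    trt = qm.channels("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("each group needs >= 2 replicates")
    x = np.log2(qm.data[ctrl].values)
    y = np.log2(qm.data[trt].values)
    n1, n2 = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    log2fc = my - mx
    df_resid = n1 + n2 - 2
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (df_resid * s2 + PRIOR_DF * s2_prior) / (df_resid + PRIOR_DF)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid + PRIOR_DF)
    fdr = multipletests(p, method="fdr_bh")[1]
    fc = np.power(2.0, log2fc)
    call = np.where(
        (fc > DEP_FC_UP) & (fdr < DEP_FDR), "up",
        np.where((fc < DEP_FC_DOWN) & (fdr < DEP_FDR), "down", "none"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "call": call},
        index=qm.data.index,
    )


def ora_enrichment(
    dep_proteins: Sequence[str],
    term_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term among the DEPs.

    p is the upper-tail probability of an overlap at least as large as
    observed when drawing ``len(dep_proteins)`` proteins from the
    background; BH correction across terms.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    deps = set(dep_proteins) & bg
    n = len(deps)
    N = len(bg)
    rows = []
    for term, members in term_sets.items():
        mem = set(members) & bg
        m = len(mem)
        k = len(mem & deps)
        p = float(stats.hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append((term, k, m, N, n, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "k", "m", "N", "n", "p"]
    ).set_index("term")
    df["fdr"] = multipletests(df["p"].values, method="fdr_bh")[1] if len(df) else []
    return df.sort_values("p")


def gsea_es(
    ranked: pd.Series,
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Weighted Kolmogorov-Smirnov enrichment of ``gene_set`` in a ranking.

    ``ranked`` maps protein -> ranking score (e.g. log2fc), ordered by
    decreasing score.  Hits advance the running sum in proportion to
    |score|; misses retreat uniformly.  ES is the maximum signed
    deviation; NES and the empirical p come from ``n_perm`` random gene
    sets of equal size (gene-label permutation).
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    ranked = ranked.sort_values(ascending=False)
    genes = list(ranked.index)
    members = set(gene_set)
    if not members <= set(genes):
        raise ValueError("gene set contains proteins absent from the ranking")
    scores = np.abs(ranked.values.astype(float))
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))

    def es_from_hits(h: np.ndarray) -> float:
        w = scores * h
        tot = w.sum()
        if tot == 0:
            w = h.astype(float)
            tot = w.sum()
        n_miss = len(h) - h.sum()
        step_hit = w / tot
        step_miss = (~h) / max(n_miss, 1)
        running = np.cumsum(step_hit - step_miss)
        return float(running[np.argmax(np.abs(running))])

    es = es_from_hits(hit)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(hit.sum())
    perm = np.empty(n_perm)
    idx = np.arange(len(genes))
    for b in range(n_perm):
        h = np.zeros(len(genes), dtype=bool)
        h[rng.choice(idx, size=m, replace=False)] = True
        perm[b] = es_from_hits(h)
    same_sign = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
    if len(same_sign) == 0:
        nes = np.sign(es) * abs(es)
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
    return es, float(nes), float(p)


def read_gmt(path: Union[str, Path]) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for term, members in sets.items():
            fh.write("\t".join([term, term] + list(members)) + "\n")
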