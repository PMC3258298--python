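"""Per-miRNA tests of influence on the transcriptome.

Two complementary views of whether a miRNA's targets respond:

* **Target-set enrichment** — a 2×2 Fisher exact test asking whether a
  miRNA's predicted targets are over- or under-represented among the
  differentially expressed genes, with BH-FDR control across miRNAs.
* **Regulatory-effect (RE) score** — a rank statistic per sample measuring
  how suppressed a miRNA's targets are relative to non-targets, compared
  between conditions with a Welch two-sample t-test. Being rank-based, the
  RE score is invariant to any monotone transform of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_target_enrichment",
    "bh_fdr",
    "re_score_per_sample",
    "re_score_test",
    "TargetMap",
]


@dataclass(frozen=True)
class TargetMap:
    """Bipartite miRNA→gene relation from an external target predictor."""

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        seen = set()
        uniq = []
        for m, g in pairs:
            if (m, g) in seen:
                raise ValueError(f"duplicate target pair {(m, g)}")
            seen.add((m, g))
            uniq.append((str(m), str(g)))
        return cls(tuple(uniq))

    def targets(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.pairs if m == mirna)

    def regulators(self, gene: str) -> frozenset[str]:
        return frozenset(m for m, g in self.pairs if g == gene)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def targets_by_mirna(self) -> dict[str, frozenset[str]]:
        d: dict[str, set[str]] = {}
        for m, g in self.pairs:
            d.setdefault(m, set()).add(g)
        return {m: frozenset(gs) for m, gs in d.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.pairs), columns=["mirna_id", "gene_id"])

    def __len__(self) -> int:
        return len(self.pairs)


def fisher_target_enrichment(
    targets: Iterable[str],
    diff_set: Iterable[str],
    background: Iterable[str],
) -> dict:
    """Two-sided Fisher exact test of target overlap with a differential set.

    The 2×2 table partitions the background by target membership and
    differential status: ``[[|T∩D|, |T\\D|], [|D\\T|, |B\\(T∪D)|]]``.
    Targets outside the background are ignored (they were not assayed).

    Returns a dict with the table counts, odds ratio, two-sided p-value
    and an ``"enriched"``/``"depleted"`` direction flag (observed overlap
    above or below its hypergeometric expectation).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    d = set(diff_set)
    if not d <= bg:
        raise ValueError("differential set must be a subset of the background")
    t = set(targets) & bg
    n11 = len(t & d)
    n12 = len(t - d)
    n21 = len(d - t)
    n22 = len(bg) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    expected = len(t) * len(d) / len(bg)
    direction = "enriched" if n11 > expected else "depleted"
    return {
        "n_overlap": n11,
        "n_target_only": n12,
        "n_diff_only": n21,
        "n_neither": n22,
        "odds_ratio": float(odds),
        "p_value": float(p),
        "expected_overlap": expected,
        "direction": direction,
    }


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def re_score_per_sample(
    expr_sample: Mapping[str, float] | pd.Series,
    targets: Iterable[str],
) -> float:
    """Rank-based regulatory-effect score of a target set in one sample.

    All genes in the sample are ranked by expression (ascending, average
    ranks on ties); the score is the mean rank of non-targets minus the
    mean rank of targets, divided by the total number of genes. It lies
    in (−1, 1); positive values mean the targets sit low in the ranking,
    i.e. look suppressed.
    """
    s = pd.Series(expr_sample, dtype=float)
    t = set(targets) & set(s.index)
    n = len(s)
    if len(t) == 0:
        raise ValueError("target set is empty (or disjoint from the background)")
    if len(t) >= n:
        raise ValueError("target set must be a proper subset of the background")
    ranks = pd.Series(stats.rankdata(s.to_numpy()), index=s.index)
    is_t = s.index.isin(t)
    return float((ranks[~is_t].mean() - ranks[is_t].mean()) / n)


def re_score_test(
    expr: pd.DataFrame,
    target_map: TargetMap,
    condition: Mapping[str, str] | pd.Series,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Compare each miRNA's regulatory-effect score between two conditions.

    Parameters
    ----------
    expr
        genes × samples expression matrix (index = gene ids).
    target_map
        miRNA→gene relation; genes absent from ``expr`` are ignored.
    condition
        sample name → condition label; exactly two labels, ≥2 samples each.
    fdr_threshold
        BH-FDR level for the ``significant`` flag.

    Returns
    -------
    pandas.DataFrame
        Per miRNA: one RE-score column per sample, Welch ``t``, ``p_value``,
        ``q_value`` and ``significant``. miRNAs with no usable targets are
        dropped.
    """
    cond = pd.Series(condition)
    cond = cond[cond.index.isin(expr.columns)]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition labels, got {levels}")
    g1 = list(cond.index[cond == levels[0]])
    g2 = list(cond.index[cond == levels[1]])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two samples per condition")

    samples = g1 + g2
    gene_index = expr.index
    # vectorized: rank each sample once, then average ranks over target sets
    ranks = pd.DataFrame(
        stats.rankdata(expr[samples].to_numpy(), axis=0),
        index=gene_index,
        columns=samples,
    )
    n = len(gene_index)
    total = ranks.sum(axis=0)

    rows = []
    for mirna, tset in sorted(target_map.targets_by_mirna().items()):
        t = list(tset & set(gene_index))
        k = len(t)
        if k == 0 or k >= n:
            continue
        t_sum = ranks.loc[t].sum(axis=0)
        re = ((total - t_sum) / (n - k) - t_sum / k) / n
        t_stat, p = stats.ttest_ind(
            re[g1].to_numpy(), re[g2].to_numpy(), equal_var=False
        )
        row = {"mirna_id": mirna, "n_targets": k, "t": float(t_stat), "p_value": float(p)}
        for s in samples:
            row[f"re_{s}"] = float(re[s])
        rows.append(row)
    if not rows:
        raise ValueError("no miRNA has usable targets in the expression background")
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"])
    out["significant"] = out["q_value"] < fdr_threshold
    return out
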