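"""Two-layer analysis: miRNA → transcription factor → transcriptome.

If miRNAs act on the transcriptome indirectly, their fingerprints should
appear on the transcription-factor (TF) layer: TFs selected by GO
annotation labels are tested for representation among the differential
genes, and the miRNA→TF edges of the coherence-labeled network are
extracted as the candidate relay points of a two-layer cascade.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .regnet import RegNetwork, classify_edges
from .response import fisher_target_enrichment

__all__ = [
    "DEFAULT_TF_TERMS",
    "select_tfs",
    "tf_underrepresentation_test",
    "mirna_tf_coherent_pairs",
    "tf_expression_comparison",
]

DEFAULT_TF_TERMS = (
    "DNA binding",
    "transcription factor activity",
    "transcription activator activity",
    "transcription repressor activity",
)


def select_tfs(
    annotations: Mapping[str, Iterable[str]],
    term_list: Iterable[str] = DEFAULT_TF_TERMS,
) -> set[str]:
    """Genes annotated with at least one TF-associated GO term label.

    Matching is by exact term label (no traversal of the GO graph); the
    default list covers generic DNA binding plus transcription factor /
    activator / repressor activity.
    """
    terms = set(term_list)
    if not terms:
        raise ValueError("empty term list")
    if not annotations:
        raise ValueError("empty annotation collection")
    return {g for g, ann in annotations.items() if terms & set(ann)}


def tf_underrepresentation_test(
    diff_genes: Iterable[str],
    tf_genes: Iterable[str],
    background: Iterable[str],
) -> dict:
    """Fisher exact test of TF representation among differential genes.

    Two-sided test on the 2×2 table of (TF, differential) membership over
    the background; ``direction`` is "depleted" (under-representation)
    when the observed TF count among differential genes falls below its
    expectation.
    """
    bg = set(background)
    d = set(diff_genes)
    t = set(tf_genes)
    if not d or not t or d == bg or t == bg:
        raise ValueError("degenerate margins: differential and TF sets must be proper non-empty subsets")
    return fisher_target_enrichment(t, d, bg)


def mirna_tf_coherent_pairs(net: RegNetwork) -> tuple[pd.DataFrame, dict]:
    """miRNA→TF edges of the network with their coherence labels.

    Requires the network's genes to carry TF flags. Returns the edge table
    restricted to TF genes and summary counts ``n_tf_targets`` (TF genes
    with ≥1 differential-miRNA edge), ``n_mirnas`` (miRNAs involved),
    ``n_edges`` and ``n_coherent``.
    """
    if net.tf_flag is None:
        raise ValueError("network carries no TF flags")
    edges = pd.DataFrame(classify_edges(net))
    if len(edges) == 0:
        return edges, {"n_tf_targets": 0, "n_mirnas": 0, "n_edges": 0, "n_coherent": 0}
    tf_genes = {g for g, f in zip(net.gene_ids, net.tf_flag) if f}
    tf_edges = edges[edges["gene_id"].isin(tf_genes)].reset_index(drop=True)
    summary = {
        "n_tf_targets": int(tf_edges["gene_id"].nunique()),
        "n_mirnas": int(tf_edges["mirna_id"].nunique()),
        "n_edges": int(len(tf_edges)),
        "n_coherent": int((tf_edges["label"] == "coherent").sum()),
    }
    return tf_edges, summary


def tf_expression_comparison(
    expr_means: Mapping[str, float] | pd.Series,
    tf_genes: Iterable[str],
) -> dict:
    """Mean expression of TF vs non-TF genes with a rank-sum p-value.

    A reporting utility for judging whether TFs are systematically less
    abundant than other genes (which could mask differential TFs): group
    means and a two-sided Mann–Whitney U test.
    """
    s = pd.Series(expr_means, dtype=float)
    tf = s.index.isin(set(tf_genes))
    if tf.all() or not tf.any():
        raise ValueError("need both TF and non-TF genes in the expression background")
    u, p = stats.mannwhitneyu(s[tf], s[~tf], alternative="two-sided")
    return {
        "mean_tf": float(s[tf].mean()),
        "mean_non_tf": float(s[~tf].mean()),
        "n_tf": int(tf.sum()),
        "n_non_tf": int((~tf).sum()),
        "u_statistic": float(u),
        "p_value": float(p),
    }
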