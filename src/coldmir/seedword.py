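"""Seed-word enrichment landscapes along a ranked gene list.

A miRNA recognises its targets chiefly through complementarity between its
5'-end seed (positions 1–7 or 2–8) and a site in the target's 3' UTR. If a
miRNA drives expression change, the DNA word complementary to its seed
should be over-represented in the UTRs of genes at one end of a list ranked
from most up- to most down-regulated.

The landscape scans a grid of leading-bin cutoffs: at each cutoff the genes
whose UTR contains a word are tested against a hypergeometric null (genes
sampled without replacement from the full list), and the signed score is
−log10 of the one-sided tail p, positive for enrichment and negative for
depletion. No background-composition correction is applied; word occurrence
is binarized per gene (the sampling unit of the hypergeometric model is the
gene).
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mirna_seed_words",
    "word_presence",
    "word_enrichment_profile",
    "top_words",
    "default_cutoffs",
    "all_words",
]

_RNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}


def _revcomp_dna(rna: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(rna))


def mirna_seed_words(mirna_seq: str) -> dict[str, str]:
    """The two 7-nt DNA words complementary to a miRNA's seed region.

    Positions 1–7 and 2–8 from the 5' end of the mature miRNA are each
    reverse-complemented into DNA (U→A pairing, written with T), giving
    the UTR words a perfect seed match would contain.
    """
    seq = mirna_seq.strip().upper()
    if len(seq) < 8:
        raise ValueError(f"miRNA sequence shorter than 8 nt: {mirna_seq!r}")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in miRNA sequence (expect RNA)")
    return {"seed_1_7": _revcomp_dna(seq[0:7]), "seed_2_8": _revcomp_dna(seq[1:8])}


def build_seed_index(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Seed words for a set of miRNAs, one row per (miRNA, register)."""
    rows = []
    for mirna, seq in sequences.items():
        words = mirna_seed_words(seq)
        rows.append({"mirna_id": mirna, "register": "1-7", "word": words["seed_1_7"]})
        rows.append({"mirna_id": mirna, "register": "2-8", "word": words["seed_2_8"]})
    return pd.DataFrame(rows)


def all_words(word_len: int = 7) -> list[str]:
    """All 4^k DNA words of length ``word_len`` in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=word_len)]


def count_word_occurrences(seq: str, word_len: int = 7) -> dict[str, int]:
    """Overlapping occurrence counts of every ``word_len``-mer in ``seq``."""
    seq = seq.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - word_len + 1):
        w = seq[i : i + word_len]
        counts[w] = counts.get(w, 0) + 1
    return counts


def word_presence(
    utrs: Mapping[str, str],
    genes: Sequence[str],
    word_len: int = 7,
    words: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene occurrence counts of UTR words, rows ordered like ``genes``.

    Genes without a UTR are dropped (the ranked list used downstream is the
    returned frame's index). Columns are restricted to ``words`` when
    given, otherwise to every word observed in at least one UTR — absent
    words carry no enrichment information at any cutoff.
    """
    if not utrs:
        raise ValueError("empty UTR collection")
    if len(set(genes)) != len(genes):
        raise ValueError("ranked gene list contains duplicates")
    kept = [g for g in genes if g in utrs]
    counts_per_gene = {g: count_word_occurrences(utrs[g], word_len) for g in kept}
    if words is None:
        vocab = sorted(set().union(*counts_per_gene.values())) if kept else []
    else:
        vocab = list(words)
        for w in vocab:
            if len(w) != word_len or set(w) - set("ACGT"):
                raise ValueError(f"invalid word {w!r}")
    mat = np.zeros((len(kept), len(vocab)), dtype=np.int64)
    col = {w: j for j, w in enumerate(vocab)}
    for i, g in enumerate(kept):
        for w, c in counts_per_gene[g].items():
            j = col.get(w)
            if j is not None:
                mat[i, j] = c
    return pd.DataFrame(mat, index=pd.Index(kept, name="gene_id"), columns=vocab)


def default_cutoffs(n_genes: int, n_cutoffs: int = 20) -> np.ndarray:
    """Evenly spaced leading-bin sizes ending at the full list."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    cuts = np.unique(np.linspace(0, n_genes, n_cutoffs + 1).round().astype(int)[1:])
    return cuts[cuts > 0]


def word_enrichment_profile(
    presence: pd.DataFrame,
    cutoffs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Signed hypergeometric enrichment landscape over leading bins.

    For word *w* with *K* carrier genes among *N*, and *x* carriers in the
    leading *c* genes: the enrichment tail is P(X ≥ x) and the depletion
    tail P(X ≤ x) under X ~ Hypergeometric(N, K, c). The signed score is
    +(−log10 P(X ≥ x)) when x exceeds the expectation cK/N and
    −(−log10 P(X ≤ x)) otherwise. At c = N both tails include the whole
    mass, so every word scores exactly 0.

    Returns a long-format frame (word, cutoff, n_carriers_bin,
    n_carriers_total, p_value, score).
    """
    n = len(presence)
    if n == 0:
        raise ValueError("empty presence matrix")
    if cutoffs is None:
        cutoffs = default_cutoffs(n)
    cutoffs = np.asarray(list(cutoffs), dtype=int)
    if np.any(np.diff(cutoffs) <= 0) or cutoffs[0] < 1 or cutoffs[-1] > n:
        raise ValueError("cutoffs must be strictly increasing within the list length")

    binary = (presence.to_numpy() > 0).astype(np.int64)
    big_k = binary.sum(axis=0)  # carriers per word
    cum = np.cumsum(binary, axis=0)
    frames = []
    for c in cutoffs:
        x = cum[c - 1]
        expected = c * big_k / n
        enrich = x > expected
        # many words share the same (x, K); evaluate each pair once
        keys, inv = np.unique(x + (n + 1) * big_k, return_inverse=True)
        ux, uk = keys % (n + 1), keys // (n + 1)
        uenrich = ux > c * uk / n
        # sf(x-1) = P(X >= x); cdf(x) = P(X <= x)
        up = np.where(
            uenrich,
            stats.hypergeom.sf(ux - 1, n, uk, c),
            stats.hypergeom.cdf(ux, n, uk, c),
        )
        p = up[inv]
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        score = np.where(enrich, -np.log10(p), np.log10(p))
        frames.append(
            pd.DataFrame(
                {
                    "word": presence.columns,
                    "cutoff": c,
                    "n_carriers_bin": x,
                    "n_carriers_total": big_k,
                    "p_value": p,
                    "score": score,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def top_words(
    profile: pd.DataFrame,
    k: int = 10,
    seed_index: pd.DataFrame | None = None,
    end: str | None = None,
) -> pd.DataFrame:
    """Words ranked by peak |score|, annotated with seed-matching miRNAs.

    ``end`` restricts the peak search to enrichment peaks ("up", leading
    end of the ranking) or depletion peaks ("down"); by default the peak is
    taken over the full landscape. ``seed_index`` is the frame from
    :func:`build_seed_index`; matching miRNAs are joined on the word.
    """
    prof = profile
    if end == "up":
        prof = prof[prof["score"] > 0]
    elif end == "down":
        prof = prof[prof["score"] < 0]
    elif end is not None:
        raise ValueError("end must be 'up', 'down' or None")
    if len(prof) == 0:
        return pd.DataFrame(
            columns=["word", "peak_score", "peak_cutoff", "p_value", "mirnas"]
        )
    idx = prof.groupby("word")["score"].apply(lambda s: s.abs().idxmax())
    peaks = prof.loc[idx.to_numpy(), ["word", "score", "cutoff", "p_value"]]
    peaks = peaks.rename(columns={"score": "peak_score", "cutoff": "peak_cutoff"})
    peaks = peaks.reindex(
        peaks["peak_score"].abs().sort_values(ascending=False).index
    ).head(k)
    if seed_index is not None:
        match = (
            seed_index.groupby("word")["mirna_id"]
            .apply(lambda s: ",".join(sorted(set(s))))
            .rename("mirnas")
        )
        peaks = peaks.merge(match, left_on="word", right_index=True, how="left")
        peaks["mirnas"] = peaks["mirnas"].fillna("")
    return peaks.reset_index(drop=True)
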