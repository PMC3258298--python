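"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate a two-condition small-RNA + microarray experiment:
two miRNA count libraries of unequal sequencing depth with a subset of
truly changed miRNAs, a genes × replicates log-intensity matrix with
planted up/down genes, a sparse bipartite target map, and random 3' UTR
sequences with plantable seed-match sites. ``coupling_beta`` optionally
ties the direction of a targeted gene to (the opposite of) its regulating
miRNA's direction, creating exactly the coherent signal the
regulatory-density test is designed to detect; at ``coupling_beta = 0``
the system satisfies that test's null.

Every generator is a pure function of a :class:`SimConfig`; a fixed seed
reproduces every output byte-for-byte. Truth labels accompany each planted
effect so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .response import TargetMap

__all__ = [
    "SimConfig",
    "gen_mirna_counts",
    "gen_target_map",
    "gen_expression_matrix",
    "gen_utr_sequences",
    "mirna_names",
    "gene_names",
]

# substream tags: one independent RNG per generator, all derived from cfg.seed
_STREAM_COUNTS, _STREAM_TARGETS, _STREAM_EXPR, _STREAM_UTR = 0, 1, 2, 3

#: negative-binomial dispersion of library counts (var = μ + αμ²);
#: small-RNA libraries are overdispersed relative to Poisson.
NB_DISPERSION = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults mirror a zebrafish cold-acclimation experiment: 700 miRNAs and
    7356 arrayed genes, library depths of ~6.5M (NC) and ~10.8M (WC)
    reads, 25 truly changed miRNAs, 626 differential genes, 3 replicate
    samples per condition, and ~80 targets per miRNA (hence 7–8 regulating
    miRNAs per gene). ``coupling_beta = 0`` by default — no miRNA-driven
    coherent signal, the regime the study concluded it was in.
    """

    n_mirnas: int = 700
    n_genes: int = 7356
    depth_nc: int = 6_473_829
    depth_wc: int = 10_799_032
    frac_de_mirna: float = 25 / 700
    mirna_lfc: float = 2.0
    n_samples_per_condition: int = 3
    frac_de_gene: float = 626 / 7356
    gene_lfc: float = 1.0
    noise_sd: float = 0.25
    targets_per_mirna: float = 80.0
    coupling_beta: float = 0.0
    utr_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "depth_nc", "depth_wc",
                     "n_samples_per_condition", "utr_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_de_mirna", "frac_de_gene", "coupling_beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.targets_per_mirna < 0:
            raise ValueError("targets_per_mirna must be non-negative")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def mirna_names(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_mirnas))
    return [f"mir_{i + 1:0{width}d}" for i in range(cfg.n_mirnas)]


def gene_names(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"gene_{i + 1:0{width}d}" for i in range(cfg.n_genes)]


def _random_rna(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with mean μ and dispersion NB_DISPERSION."""
    size = 1.0 / NB_DISPERSION
    p = size / (size + np.maximum(mu, 1e-12))
    return rng.negative_binomial(size, p)


def gen_mirna_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-library miRNA count table with planted fold changes.

    Per-miRNA relative abundances follow a log-normal distribution (a
    heavy-tailed expression spectrum); expected library totals equal the
    configured depths. ``round(frac_de_mirna · n_mirnas)`` miRNAs carry an
    expected log2 fold change of ``mirna_lfc`` in WC relative to the
    library-wide scale, half up and half (the remainder) down.

    Returns ``(counts, truth)``: counts with columns ``mirna_id``,
    ``sequence``, ``count_nc``, ``count_wc``; truth with ``mirna_id``,
    ``is_de``, ``direction``, ``log2_fold``.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    names = mirna_names(cfg)
    weights = rng.lognormal(mean=0.0, sigma=2.0, size=cfg.n_mirnas)
    weights /= weights.sum()

    n_de = round(cfg.frac_de_mirna * cfg.n_mirnas)
    de_idx = rng.choice(cfg.n_mirnas, size=n_de, replace=False)
    lfc = np.zeros(cfg.n_mirnas)
    n_up = n_de // 2
    lfc[de_idx[:n_up]] = cfg.mirna_lfc
    lfc[de_idx[n_up:]] = -cfg.mirna_lfc

    mu_nc = cfg.depth_nc * weights
    mu_wc = cfg.depth_wc * weights * 2.0**lfc
    counts = pd.DataFrame(
        {
            "mirna_id": names,
            "sequence": [_random_rna(rng) for _ in names],
            "count_nc": _nb_draw(rng, mu_nc),
            "count_wc": _nb_draw(rng, mu_wc),
        }
    )
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    truth = pd.DataFrame(
        {"mirna_id": names, "is_de": lfc != 0, "direction": direction, "log2_fold": lfc}
    )
    return counts, truth


def gen_target_map(cfg: SimConfig) -> TargetMap:
    """Random sparse bipartite miRNA→gene map without duplicate pairs.

    Each miRNA receives a Poisson(``targets_per_mirna``) out-degree
    (capped at ``n_genes``) and its targets are drawn uniformly without
    replacement, so the mean in-degree is
    ``targets_per_mirna · n_mirnas / n_genes``.
    """
    rng = cfg.rng(_STREAM_TARGETS)
    genes = np.array(gene_names(cfg))
    pairs: list[tuple[str, str]] = []
    for m in mirna_names(cfg):
        k = min(int(rng.poisson(cfg.targets_per_mirna)), cfg.n_genes)
        if k == 0:
            continue
        chosen = rng.choice(cfg.n_genes, size=k, replace=False)
        pairs.extend((m, genes[j]) for j in sorted(chosen))
    return TargetMap.from_pairs(pairs)


def gen_expression_matrix(
    cfg: SimConfig,
    mirna_truth: pd.DataFrame | None = None,
    target_map: TargetMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated two-condition log-intensity matrix with planted effects.

    Baseline log2 intensities are Normal(8, 1.5) per gene; within-condition
    replicates add Normal(0, ``noise_sd``) noise. ``round(frac_de_gene ·
    n_genes)`` genes are intrinsically differential with random direction
    and shift ``gene_lfc`` in the WC condition.

    With ``coupling_beta > 0`` (requires ``mirna_truth`` and
    ``target_map``), each gene targeted by at least one truly changed
    miRNA is, with that probability, forced differential in the direction
    *opposite* to one of its changed regulators (chosen uniformly when
    they conflict) — the coherent, repression-consistent signal.

    Returns ``(matrix, truth)``: matrix indexed by gene with columns
    ``NC1..NCk, WC1..WCk``; truth with ``gene_id``, ``is_de``,
    ``direction``, ``log2_fold``, ``coupled``.
    """
    rng = cfg.rng(_STREAM_EXPR)
    genes = gene_names(cfg)
    n = cfg.n_genes
    k = cfg.n_samples_per_condition

    n_de = round(cfg.frac_de_gene * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    lfc[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * cfg.gene_lfc
    coupled = np.zeros(n, dtype=bool)

    if cfg.coupling_beta > 0:
        if mirna_truth is None or target_map is None:
            raise ValueError("coupling_beta > 0 requires mirna_truth and target_map")
        de_mirna_dir = dict(
            zip(
                mirna_truth.loc[mirna_truth["is_de"], "mirna_id"],
                mirna_truth.loc[mirna_truth["is_de"], "direction"],
            )
        )
        gene_pos = {g: i for i, g in enumerate(genes)}
        regulators: dict[int, list[str]] = {}
        for m, g in target_map.pairs:
            if m in de_mirna_dir and g in gene_pos:
                regulators.setdefault(gene_pos[g], []).append(m)
        for gi in sorted(regulators):
            if rng.random() < cfg.coupling_beta:
                m = regulators[gi][rng.integers(len(regulators[gi]))]
                sign = -1.0 if de_mirna_dir[m] == "up" else 1.0
                lfc[gi] = sign * cfg.gene_lfc
                coupled[gi] = True

    baseline = rng.normal(8.0, 1.5, size=n)
    cond_mean = np.column_stack([baseline] * k + [baseline + lfc] * k)
    noise = rng.normal(0.0, cfg.noise_sd, size=cond_mean.shape) if cfg.noise_sd > 0 else 0.0
    cols = [f"NC{i + 1}" for i in range(k)] + [f"WC{i + 1}" for i in range(k)]
    matrix = pd.DataFrame(cond_mean + noise, index=pd.Index(genes, name="gene_id"), columns=cols)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": lfc != 0,
            "direction": direction,
            "log2_fold": lfc,
            "coupled": coupled,
        }
    )
    return matrix, truth


def gen_utr_sequences(
    cfg: SimConfig,
    planted_sites: Iterable[tuple[str, str]] = (),
    genes: Sequence[str] | None = None,
) -> dict[str, str]:
    """Uniform-random 3' UTR sequences with optional planted words.

    Each planted ``(gene, word)`` overwrites a random window of that
    gene's UTR so the word occurs at least once. Words must be DNA
    (A/C/G/T) and no longer than ``utr_len``.
    """
    rng = cfg.rng(_STREAM_UTR)
    if genes is None:
        genes = gene_names(cfg)
    bases = np.array(list("ACGT"))
    utrs = {
        g: "".join(bases[rng.integers(0, 4, size=cfg.utr_len)]) for g in genes
    }
    for gene, word in planted_sites:
        if set(word) - set("ACGT"):
            raise ValueError(f"planted word {word!r} is not a DNA string")
        if len(word) > cfg.utr_len:
            raise ValueError("planted word longer than the UTR")
        if gene not in utrs:
            raise ValueError(f"unknown gene {gene!r} for planted site")
        pos = int(rng.integers(0, cfg.utr_len - len(word) + 1))
        s = utrs[gene]
        utrs[gene] = s[:pos] + word + s[pos + len(word):]
    return utrs
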