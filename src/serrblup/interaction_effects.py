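"""Backsolving interaction effects and variance-based column selection.

A kernel fit with the full epistasis matrix assigns a genetic value to every
line; the RRBLUP-GBLUP duality maps that fit back onto per-column effects of
the (implicit) dummy design:

    t_hat = (sigma2_g / D) * (M* - P*)' * (sigma2_g * Gamma_ERR
            + sigma2_eps * I)^{-1} * (y - 1 mu_hat)

with D the kernel normalizer sum p*(1-p*). The n x m* dummy matrix is never
built: all 4 combination effects of every pair (j, k) are linear in three
m x m matrices (genotype cross-products, optionally weighted), so the whole
t_hat vector streams out of two matrix products.

Per-column effect variances are sigma2_i = t_i^2 * 2 p*_i (1 - p*_i), and
selection keeps the top-pi proportion of columns by that score (or by
absolute effect), with ties at the cutoff broken toward the lower column id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix
from .kernels import InteractionEncoding, RelationshipMatrix

__all__ = [
    "InteractionEffects",
    "SelectionResult",
    "backsolve_effects",
    "effect_variances",
    "select_top_columns",
]


@dataclass
class InteractionEffects:
    """Backsolved per-column effects and (once filled) effect variances.

    ``column_ids is None`` means the vectors cover all m* columns in id
    order; otherwise they cover exactly the listed columns.
    """

    t_hat: np.ndarray
    m_star: int
    column_ids: np.ndarray | None = None
    sigma2_hat: np.ndarray | None = None
    source: dict | None = None

    def scores(self, criterion: str = "effect_variance") -> np.ndarray:
        if criterion == "effect_variance":
            if self.sigma2_hat is None:
                raise ValueError("run effect_variances first")
            return self.sigma2_hat
        if criterion == "absolute_effect":
            return np.abs(self.t_hat)
        raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class SelectionResult:
    """Top-pi interaction columns; ids stored sorted ascending."""

    pi: float
    criterion: str
    column_ids: np.ndarray
    threshold_score: float
    m_star: int

    def to_tsv(self, path, enc: InteractionEncoding, scores=None) -> None:
        j, k, combo = enc.decode(self.column_ids)
        with open(path, "w") as fh:
            fh.write("column_id\tmarker_j\tmarker_k\tcombo\tscore\n")
            for i, cid in enumerate(self.column_ids):
                s = "" if scores is None else repr(float(scores[i]))
                fh.write(f"{cid}\t{j[i]}\t{k[i]}\t{('00','02','20','22')[combo[i]]}\t{s}\n")


def backsolve_effects(g: GenotypeMatrix, enc: InteractionEncoding,
                      y: np.ndarray, mu_hat: float, sigma2_g: float,
                      sigma2_eps: float, gamma_err: RelationshipMatrix,
                      pair_block: int = 200_000) -> InteractionEffects:
    """Backsolve all m* interaction effects from an ERRBLUP fit.

    ``y`` must be complete and aligned with ``g.line_ids`` (the selection
    environment's full data); ``gamma_err`` must be built from the same
    genotypes and carry its normalizer.
    """
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    if list(gamma_err.line_ids) != list(g.line_ids):
        raise ValueError("mismatched line ordering between genotypes and kernel")
    y = np.asarray(y, dtype=np.float64)
    n = g.n_lines
    if y.shape != (n,):
        raise ValueError("y must cover every line exactly once")
    if enc.m != g.n_markers:
        raise ValueError("encoding does not match the genotype matrix")
    V = sigma2_g * gamma_err.values + sigma2_eps * np.eye(n)
    try:
        w = np.linalg.solve(V, y - mu_hat)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular mixed-model system: {e}") from None
    scale = sigma2_g / gamma_err.normalizer

    X = g.haplotypes()                      # n x m in {0,1}
    r = X.T @ w                             # per-marker weighted allele sums
    A = (X * w[:, None]).T @ X              # A[j,k] = sum_i x_ij x_ik w_i
    w_tot = float(w.sum())

    if enc.m_star > 40_000_000:
        raise MemoryError("m* too large to materialize the full effect vector")
    t = np.empty(enc.m_star, dtype=np.float64)
    for start, j, k in enc.iter_pair_blocks(pair_block):
        a_jk = A[j, k]
        s = np.stack([
            w_tot - r[j] - r[k] + a_jk,     # combo 00
            r[k] - a_jk,                    # combo 02
            r[j] - a_jk,                    # combo 20
            a_jk,                           # combo 22
        ], axis=1)
        p = enc.pair_block_frequencies(j, k)
        t[4 * start: 4 * (start + j.size)] = (scale * (s - p * w_tot)).ravel()
    return InteractionEffects(
        t_hat=t, m_star=enc.m_star,
        source={"mu_hat": mu_hat, "sigma2_g": sigma2_g,
                "sigma2_eps": sigma2_eps, "normalizer": gamma_err.normalizer})


def effect_variances(effects: InteractionEffects,
                     enc: InteractionEncoding) -> InteractionEffects:
    """Fill per-column effect variances sigma2_i = t_i^2 * 2 p*_i (1 - p*_i)."""
    if effects.column_ids is None:
        p = enc.p_star
    else:
        p = enc.p_star_block(effects.column_ids)
    effects.sigma2_hat = effects.t_hat ** 2 * 2.0 * p * (1.0 - p)
    return effects


def select_top_columns(scores: np.ndarray, pi: float,
                       criterion: str = "effect_variance") -> SelectionResult:
    """Keep the ceil(pi * m*) columns with the largest score.

    Ties at the cutoff are broken by ascending column id, which makes the
    kept set monotone in pi.
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError("pi must lie in (0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if criterion == "effect_variance" and (scores < 0).any():
        raise ValueError("effect-variance scores must be non-negative")
    m_star = scores.size
    keep = math.ceil(pi * m_star)
    order = np.lexsort((np.arange(m_star), -scores))  # score desc, id asc
    kept = np.sort(order[:keep])
    threshold = float(scores[order[keep - 1]])
    return SelectionResult(pi=pi, criterion=criterion, column_ids=kept,
                           threshold_score=threshold, m_star=m_star)
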