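"""Synthetic inbred-line genotypes and multi-environment phenotypes.

Real doubled-haploid panels with per-environment adjusted means are rarely
public, so every pipeline stage here is exercised on simulated data with a
known architecture. Genotypes are biallelic doses in {0, 2} with local LD
produced by a within-block Markov copying process; traits combine sparse
additive effects with combination-indexed pairwise epistatic effects — the
same parameterization the epistasis kernel uses, so interaction selection
has literal ground truth to recover. Environments share a common genetic
component mixed with an environment-specific one so that the genetic
correlation between any two environments equals ``rho_g``; residual noise
is scaled to hit a target heritability per environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeTable
from .kernels import InteractionEncoding

__all__ = [
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_multi_env_phenotypes",
]


@dataclass
class SimulationTruth:
    """Ground-truth architecture and realized quantities of one simulation."""

    additive_effects: dict          # marker id -> effect
    epistatic_effects: dict         # (marker j, marker k, combo) -> effect
    genetic_values: pd.DataFrame    # lines x environments
    h2: dict                        # environment -> target h2
    rho_g: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_text(self, path) -> None:
        payload = {
            "seed": self.seed, "rho_g": self.rho_g, "h2": self.h2,
            "params": self.params,
            "additive_effects": {str(k): v for k, v in self.additive_effects.items()},
            "epistatic_effects": {f"{j}|{k}|{c}": v for (j, k, c), v
                                  in self.epistatic_effects.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_genotypes(n: int, m: int, n_blocks: int = 100,
                       within_block_ld: float = 0.7,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0) -> GenotypeMatrix:
    """Finalized inbred genotypes with block-local linkage disequilibrium.

    Markers are split into ``n_blocks`` contiguous blocks. Within a block,
    each marker copies the previous marker's allele with probability
    ``within_block_ld`` and otherwise draws a fresh Bernoulli allele at that
    marker's frequency; block boundaries reset the chain. Allele
    frequencies are uniform in ``maf_range``. Doses are returned in {0, 2},
    minor-allele coded.
    """
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0.0 <= within_block_ld < 1.0:
        raise ValueError("within_block_ld must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    block_of = np.minimum(np.arange(m) * n_blocks // max(m, 1), n_blocks - 1)
    X = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n) < freqs[j]
        if j > 0 and block_of[j] == block_of[j - 1]:
            copy = rng.random(n) < within_block_ld
            X[:, j] = np.where(copy, X[:, j - 1], fresh)
        else:
            X[:, j] = fresh
    # minor-allele orientation (frequency tie keeps orientation)
    flip = X.mean(axis=0) > 0.5
    X[:, flip] = 1 - X[:, flip]
    line_ids = [f"L{i:04d}" for i in range(n)]
    marker_ids = [f"M{j:05d}" for j in range(m)]
    return GenotypeMatrix(line_ids, marker_ids, (2 * X).astype(np.int8),
                          finalized=True)


def _architecture_values(g: GenotypeMatrix, rng: np.random.Generator,
                         n_additive: int, pairs: np.ndarray
                         ) -> tuple[np.ndarray, dict, dict]:
    """Draw one architecture (effects) and return its genetic values."""
    n, m = g.n_lines, g.n_markers
    X = g.haplotypes()
    gv = np.zeros(n)
    add = {}
    if n_additive:
        loci = rng.choice(m, size=n_additive, replace=False)
        beta = rng.standard_normal(n_additive)
        gv += X[:, loci] @ beta
        add = {g.marker_ids[j]: float(b) for j, b in zip(loci, beta)}
    epi = {}
    if pairs.size:
        for j, k in pairs:
            eff = rng.standard_normal(4)
            combo = (2 * X[:, j] + X[:, k]).astype(int)  # 0..3 = 00,02,20,22
            gv += eff[combo]
            for c in range(4):
                epi[(g.marker_ids[j], g.marker_ids[k], c)] = float(eff[c])
    return gv, add, epi


def simulate_multi_env_phenotypes(g: GenotypeMatrix, n_additive: int,
                                  n_epistatic_pairs: int, h2,
                                  rho_g: float, n_env: int = 2,
                                  seed: int = 0
                                  ) -> tuple[PhenotypeTable, SimulationTruth]:
    """Correlated multi-environment phenotypes over a shared architecture.

    The per-environment genetic value is
    sqrt(rho_g) * z_shared + sqrt(1 - rho_g) * z_env, where z_shared and
    z_env are standardized genetic values from independently drawn effect
    sets on the same sampled loci and pairs; residual noise is scaled so the
    realized heritability matches the target. ``h2`` may be a scalar or a
    per-environment list; valid range is 0 < h2 <= 1 (h2 = 1 means
    noise-free phenotypes). Negative ``rho_g`` is supported for two
    environments only.
    """
    enc = InteractionEncoding.from_marker_count(g.n_markers)
    if n_epistatic_pairs > enc.n_pairs:
        raise ValueError("more epistatic pairs requested than exist")
    if n_additive > g.n_markers:
        raise ValueError("more additive loci requested than markers")
    if n_additive + n_epistatic_pairs == 0:
        raise ValueError("architecture needs at least one effect")
    h2_list = [float(h2)] * n_env if np.isscalar(h2) else [float(v) for v in h2]
    if len(h2_list) != n_env:
        raise ValueError("need one h2 per environment")
    for v in h2_list:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"infeasible heritability {v}")
    if not -1.0 <= rho_g <= 1.0:
        raise ValueError("rho_g must lie in [-1, 1]")
    if rho_g < 0 and n_env != 2:
        raise ValueError("negative rho_g is only well-defined for 2 environments")

    rng = np.random.default_rng(seed)
    m = g.n_markers
    # one set of causal loci/pairs, shared across effect draws
    ju, ku = np.triu_indices(m, k=1)
    pick = rng.choice(ju.size, size=n_epistatic_pairs, replace=False) \
        if n_epistatic_pairs else np.empty(0, dtype=int)
    pairs = np.stack([ju[pick], ku[pick]], axis=1) if n_epistatic_pairs \
        else np.empty((0, 2), dtype=int)

    def standardized(values: np.ndarray) -> np.ndarray:
        sd = values.std()
        if sd <= 0:
            raise ValueError("degenerate architecture: zero genetic variance")
        return (values - values.mean()) / sd

    z_shared, add, epi = _architecture_values(g, rng, n_additive, pairs)
    z_shared = standardized(z_shared)
    a = np.sqrt(abs(rho_g))
    b = np.sqrt(1.0 - abs(rho_g))
    env_ids = [f"E{e + 1}" for e in range(n_env)]
    gvals = {}
    records = []
    for e, env in enumerate(env_ids):
        z_env, _, _ = _architecture_values(g, rng, n_additive, pairs)
        sign = -1.0 if (rho_g < 0 and e == 1) else 1.0
        gv = sign * a * z_shared + b * standardized(z_env)
        gvals[env] = gv
        h2e = h2_list[e]
        var_g = float(gv.var())
        noise = np.zeros(g.n_lines) if h2e == 1.0 else \
            rng.normal(0.0, np.sqrt(var_g * (1.0 - h2e) / h2e), size=g.n_lines)
        y = gv + noise
        records += [{"line": l, "environment": env, "value": v}
                    for l, v in zip(g.line_ids, y)]
    truth = SimulationTruth(
        additive_effects=add, epistatic_effects=epi,
        genetic_values=pd.DataFrame(gvals, index=g.line_ids),
        h2=dict(zip(env_ids, h2_list)), rho_g=rho_g, seed=seed,
        params={"n_additive": n_additive, "n_epistatic_pairs": n_epistatic_pairs,
                "n_env": n_env})
    return PhenotypeTable(pd.DataFrame(records)), truth
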