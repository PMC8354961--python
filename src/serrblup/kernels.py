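"""Relationship matrices for additive and categorical-epistasis BLUP.

Three kernels are built here, all VanRaden-normalized cross-products of
(possibly implicit) centered design matrices:

* ``grm_vanraden`` — the additive genomic relationship matrix
  (M - P)(M - P)' / (2 * sum p_i (1 - p_i)) with doses coded as minor-allele
  counts of fully inbred lines.
* ``err_kernel`` — the full categorical-epistasis kernel. Every ordered
  pair of loci (j <= k, self-pairs included) contributes four dummy columns,
  one per genotype combination {00, 02, 20, 22}; with m markers there are
  m* = 2m(m+1) such columns. The kernel is
  (M* - P*)(M* - P*)' / sum p*_i (1 - p*_i), where p*_i is the population
  frequency of combination column i. The n x m* dummy matrix is never
  materialized: because each line activates exactly one combination per
  pair, the whole cross-product collapses to counts of genotype-pair
  matches between lines, computable from one n x n genotype match matrix.
* ``serr_kernel`` — the same construction restricted to a selected subset
  of combination columns (the top-pi columns by backsolved effect
  variance), accumulated blockwise over the selected columns only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "InteractionEncoding",
    "RelationshipMatrix",
    "allele_freqs",
    "grm_vanraden",
    "interaction_columns",
    "err_kernel",
    "serr_kernel",
]

#: genotype combinations (dose_j, dose_k) in fixed column order
COMBOS = ((0, 0), (0, 2), (2, 0), (2, 2))


@dataclass
class AlleleFrequencies:
    """Minor-allele frequencies p_i = column mean / 2 of a finalized matrix."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.size and (self.p.min() < 0 or self.p.max() > 0.5 + 1e-12):
            raise ValueError("minor-allele frequencies must lie in [0, 0.5]")


def allele_freqs(g: GenotypeMatrix) -> AlleleFrequencies:
    if not g.finalized:
        raise ValueError("genotypes must be finalized")
    return AlleleFrequencies(g.doses.mean(axis=0) / 2.0)


@dataclass
class RelationshipMatrix:
    """Symmetric PSD n x n kernel with the normalizer that produced it."""

    line_ids: list[str]
    values: np.ndarray
    kind: str  # one of {"VR", "ERR", "sERR"}
    normalizer: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match line ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, idx: np.ndarray) -> "RelationshipMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return RelationshipMatrix(
            [self.line_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)].copy(), self.kind, self.normalizer)

    def check_psd(self, rtol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        floor = -rtol * max(np.trace(self.values) / max(self.n_lines, 1), 1.0)
        if w.min() < floor:
            raise ValueError(f"kernel is not PSD (min eigenvalue {w.min():.3g})")

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#kind={self.kind}\tnormalizer={self.normalizer!r}\n")
            fh.write("line\t" + "\t".join(self.line_ids) + "\n")
            for lid, row in zip(self.line_ids, self.values):
                fh.write(lid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RelationshipMatrix":
        with open(path) as fh:
            meta = fh.readline().strip().lstrip("#").split("\t")
            kv = dict(item.split("=", 1) for item in meta)
            ids = fh.readline().strip().split("\t")[1:]
            vals = np.loadtxt(fh, usecols=range(1, len(ids) + 1), ndmin=2)
        return cls(ids, vals, kv["kind"], float(kv["normalizer"]))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("line_ids", data=np.array(self.line_ids, dtype="S"))
            f.attrs["kind"] = self.kind
            f.attrs["normalizer"] = self.normalizer

    @classmethod
    def from_hdf5(cls, path) -> "RelationshipMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            return cls([s.decode() for s in f["line_ids"][()]],
                       f["values"][()], f.attrs["kind"], float(f.attrs["normalizer"]))


@dataclass
class InteractionEncoding:
    """Ordered dummy-column scheme for all pairwise genotype combinations.

    Pairs (j, k) with j <= k are enumerated j-major; each pair owns four
    consecutive columns in the fixed combo order (00, 02, 20, 22) of
    (dose_j, dose_k), so column id = 4 * pair_rank(j, k) + combo. Columns
    are reconstructed on demand from the genotypes; the full n x m* matrix
    is never stored.
    """

    m: int
    genotypes: GenotypeMatrix | None = None
    _X: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one marker")
        if self.genotypes is not None:
            if self.genotypes.n_markers != self.m:
                raise ValueError("marker count mismatch")
            self._X = self.genotypes.haplotypes()  # n x m in {0,1}

    @classmethod
    def from_marker_count(cls, m: int) -> "InteractionEncoding":
        """Metadata-only encoding (counts and index bijection, no columns)."""
        return cls(m=m)

    # -- counting and the index bijection -----------------------------------

    @property
    def n_pairs(self) -> int:
        return self.m * (self.m + 1) // 2

    @property
    def m_star(self) -> int:
        return 2 * self.m * (self.m + 1)

    @cached_property
    def _pair_offsets(self) -> np.ndarray:
        j = np.arange(self.m, dtype=np.int64)
        return j * self.m - j * (j - 1) // 2

    def pair_rank(self, j: int, k: int) -> int:
        if not 0 <= j <= k < self.m:
            raise ValueError(f"invalid pair ({j}, {k})")
        return int(self._pair_offsets[j] + (k - j))

    def column_index(self, j: int, k: int, combo: int) -> int:
        if not 0 <= combo < 4:
            raise ValueError("combo must be in 0..3")
        return 4 * self.pair_rank(j, k) + combo

    def decode(self, column_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Column ids -> (marker j, marker k, combo) arrays."""
        ids = np.asarray(column_ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= self.m_star):
            raise ValueError("column id out of range")
        pair, combo = ids // 4, ids % 4
        j = np.searchsorted(self._pair_offsets, pair, side="right") - 1
        k = pair - self._pair_offsets[j] + j
        return j, k, combo

    # -- column materialization ---------------------------------------------

    def _require_genotypes(self) -> np.ndarray:
        if self._X is None:
            raise ValueError("metadata-only encoding has no genotype columns")
        return self._X

    @property
    def n_lines(self) -> int:
        return self._require_genotypes().shape[0]

    def indicator_block(self, column_ids) -> np.ndarray:
        """Materialize the requested dummy columns as an n x len(ids) matrix."""
        X = self._require_genotypes()
        j, k, combo = self.decode(column_ids)
        a = np.array([c[0] for c in COMBOS])[combo] // 2
        b = np.array([c[1] for c in COMBOS])[combo] // 2
        return ((X[:, j] == a) & (X[:, k] == b)).astype(np.float64)

    def p_star_block(self, column_ids) -> np.ndarray:
        return self.indicator_block(column_ids).mean(axis=0)

    def iter_pair_blocks(self, block_pairs: int = 250_000) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield (first pair rank, j indices, k indices) in enumeration order."""
        ju, ku = np.triu_indices(self.m)
        for start in range(0, self.n_pairs, block_pairs):
            stop = min(start + block_pairs, self.n_pairs)
            yield start, ju[start:stop], ku[start:stop]

    def pair_block_frequencies(self, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        """p* for the 4 combos of each listed pair, shape (len(j), 4)."""
        X = self._require_genotypes()
        n = X.shape[0]
        xj, xk = X[:, j], X[:, k]
        p11 = np.einsum("ij,ij->j", xj, xk) / n
        pj, pk = xj.mean(axis=0), xk.mean(axis=0)
        p10 = pj - p11
        p01 = pk - p11
        p00 = 1.0 - pj - pk + p11
        return np.stack([p00, p01, p10, p11], axis=1)

    @cached_property
    def p_star(self) -> np.ndarray:
        """Frequencies of all m* combination columns (materialized vector)."""
        if self.m_star > 50_000_000:
            raise MemoryError("p_star vector too large to materialize; "
                              "use p_star_block / pair_block_frequencies")
        out = np.empty(self.m_star, dtype=np.float64)
        for start, j, k in self.iter_pair_blocks():
            out[4 * start: 4 * (start + j.size)] = \
                self.pair_block_frequencies(j, k).ravel()
        return out

    @property
    def active_columns(self) -> np.ndarray:
        """Ids of non-constant columns (0 < p* < 1)."""
        p = self.p_star
        return np.nonzero((p > 0) & (p < 1))[0]


def interaction_columns(g: GenotypeMatrix) -> InteractionEncoding:
    """Encoding over all pairs j <= k, including self-pairs.

    Self-pair columns for the impossible combos {02} and {20} are
    constant-zero and therefore inert in every kernel, but they keep their
    ids so selections are portable.
    """
    if not g.finalized:
        raise ValueError("genotypes must be finalized")
    return InteractionEncoding(m=g.n_markers, genotypes=g)


# ---------------------------------------------------------------------------
# Kernels


def grm_vanraden(g: GenotypeMatrix) -> RelationshipMatrix:
    """Additive VanRaden genomic relationship matrix."""
    if not g.finalized:
        raise ValueError("genotypes must be finalized")
    M = g.doses.astype(np.float64)
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers are monomorphic (zero VanRaden denominator)")
    Mc = M - 2.0 * p
    return RelationshipMatrix(list(g.line_ids), (Mc @ Mc.T) / denom, "VR", denom)


def _match_count_matrix(X: np.ndarray) -> np.ndarray:
    """C[i,i'] = number of pairs (j <= k) where lines i and i' carry the
    same genotype combination; exact integer values in float64."""
    n, m = X.shape
    h = X.sum(axis=1)
    S = m - h[:, None] - h[None, :] + 2.0 * (X @ X.T)  # marker agreement counts
    return S * (S + 1.0) / 2.0


def err_kernel(g: GenotypeMatrix, method: str = "match",
               block_pairs: int = 100_000) -> RelationshipMatrix:
    """Full pairwise-interaction (categorical epistasis) kernel.

    ``method='match'`` uses the exact closed form based on genotype match
    counts (O(n^2 m), the default); ``method='block'`` accumulates the
    centered dummy cross-product blockwise over pairs. Both honor the
    contract that the n x m* dummy matrix is never materialized and agree
    to numerical precision.
    """
    if not g.finalized:
        raise ValueError("genotypes must be finalized")
    enc = interaction_columns(g)
    X = g.haplotypes()
    n = X.shape[0]
    if method == "match":
        C = _match_count_matrix(X)
        q = C.mean(axis=1)           # q_i = sum_c M*_ic p*_c
        sum_p2 = float(C.mean())     # sum_c p*_c^2
        denom = enc.n_pairs - sum_p2
        if denom <= 1e-12:
            raise ValueError("all combination columns are constant "
                             "(zero epistasis-kernel denominator)")
        values = C - q[:, None] - q[None, :] + sum_p2
        return RelationshipMatrix(list(g.line_ids), values / denom, "ERR", denom)
    if method == "block":
        num = np.zeros((n, n))
        denom = 0.0
        for _, j, k in enc.iter_pair_blocks(block_pairs):
            xj, xk = X[:, j], X[:, k]
            ind = np.concatenate([
                (1 - xj) * (1 - xk), (1 - xj) * xk, xj * (1 - xk), xj * xk,
            ], axis=1)
            p = ind.mean(axis=0)
            live = (p > 0) & (p < 1)  # constant columns contribute nothing
            ic = ind[:, live] - p[live]
            num += ic @ ic.T
            denom += float(np.sum(p[live] * (1.0 - p[live])))
        if denom <= 1e-12:
            raise ValueError("all combination columns are constant "
                             "(zero epistasis-kernel denominator)")
        return RelationshipMatrix(list(g.line_ids), num / denom, "ERR", denom)
    raise ValueError(f"unknown method {method!r}")


def serr_kernel(g: GenotypeMatrix, selected: Sequence[int],
                block_cols: int = 20_000) -> RelationshipMatrix:
    """Reduced epistasis kernel over a selected subset of combination columns.

    Selecting every column reproduces the full kernel exactly (delegated to
    :func:`err_kernel`, which is the identical computation).
    """
    if not g.finalized:
        raise ValueError("genotypes must be finalized")
    enc = interaction_columns(g)
    ids = np.unique(np.asarray(list(selected), dtype=np.int64))
    if ids.size == 0:
        raise ValueError("empty interaction selection")
    if ids.min() < 0 or ids.max() >= enc.m_star:
        raise ValueError("selected column id out of range")
    if ids.size == enc.m_star:
        full = err_kernel(g)
        return RelationshipMatrix(full.line_ids, full.values, "sERR",
                                  full.normalizer)
    n = enc.n_lines
    num = np.zeros((n, n))
    denom = 0.0
    for start in range(0, ids.size, block_cols):
        ind = enc.indicator_block(ids[start:start + block_cols])
        p = ind.mean(axis=0)
        live = (p > 0) & (p < 1)
        ic = ind[:, live] - p[live]
        num += ic @ ic.T
        denom += float(np.sum(p[live] * (1.0 - p[live])))
    if denom <= 1e-12:
        raise ValueError("all selected combination columns are constant")
    return RelationshipMatrix(list(g.line_ids), num / denom, "sERR", denom)
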