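"""Genotype and phenotype input, recoding, quality control and LD pruning.

Genotypes of fully inbred (doubled-haploid) lines are held as allele-dose
matrices. Before quality control a dose may be 0, 1 (heterozygous call,
necessarily a genotyping artifact in a DH line), 2, or missing; after
:func:`finalize_coding` every entry is 0 or 2 and every marker counts its
minor allele, which is the coding the interaction kernels assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "read_phenotypes",
    "finalize_coding",
    "vif_prune",
    "write_dosage_table",
]

MISSING = -1  # sentinel in the int8 dose matrix


@dataclass
class GenotypeMatrix:
    """n lines x m biallelic markers, doses coded as minor-allele counts.

    ``doses`` is an int8 array with entries in {0, 1, 2, MISSING} before
    finalization and {0, 2} after.
    """

    line_ids: list[str]
    marker_ids: list[str]
    doses: np.ndarray
    finalized: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if self.doses.ndim != 2:
            raise ValueError("doses must be a 2-D matrix")
        n, m = self.doses.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lengths do not match dose matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line id")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker id")
        valid = np.isin(self.doses, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.doses[~valid])
            raise ValueError(f"invalid dose values {bad.tolist()}")
        if self.finalized and not np.isin(self.doses, (0, 2)).all():
            raise ValueError("finalized matrix must contain only doses 0 and 2")

    @property
    def n_lines(self) -> int:
        return self.doses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.doses.shape[1]

    def line_index(self, ids) -> np.ndarray:
        """Positions of ``ids`` in this matrix's line order."""
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"unknown line id {e.args[0]!r}") from None

    def subset_lines(self, ids) -> "GenotypeMatrix":
        idx = self.line_index(ids)
        return replace(self, line_ids=list(ids), doses=self.doses[idx].copy())

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        idx = np.array([lookup[m] for m in marker_ids], dtype=np.intp)
        return replace(
            self, marker_ids=list(marker_ids), doses=self.doses[:, idx].copy()
        )

    def haplotypes(self) -> np.ndarray:
        """Finalized doses as a {0,1} float matrix (dose / 2)."""
        if not self.finalized:
            raise ValueError("genotypes must be finalized first")
        return (self.doses > 0).astype(np.float64)


@dataclass
class PhenotypeTable:
    """Per-line, per-environment adjusted means (BLUEs).

    Backed by a tidy DataFrame with columns ``line``, ``environment``,
    ``value``; at most one record per (line, environment).
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["line", "environment", "value"]))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=["line", "environment", "value"])
        df["value"] = df["value"].astype(float)
        if df.duplicated(["line", "environment"]).any():
            dup = df[df.duplicated(["line", "environment"])].iloc[0]
            raise ValueError(
                f"duplicate phenotype record for line {dup['line']!r} "
                f"in environment {dup['environment']!r}")
        self.data = df.reset_index(drop=True)

    @property
    def environments(self) -> list:
        return list(pd.unique(self.data["environment"]))

    @property
    def lines(self) -> list:
        return list(pd.unique(self.data["line"]))

    def env_series(self, environment) -> pd.Series:
        """Observed values for one environment, indexed by line id."""
        sub = self.data[self.data["environment"] == environment]
        if sub.empty:
            raise KeyError(f"unknown environment {environment!r}")
        return pd.Series(sub["value"].to_numpy(), index=sub["line"].to_numpy())

    def check_lines(self, genotypes: GenotypeMatrix) -> None:
        missing = set(self.data["line"]) - set(genotypes.line_ids)
        if missing:
            raise ValueError(f"phenotyped lines without genotypes: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_genotypes(path, format: str = "dosage_table") -> GenotypeMatrix:
    """Read genotypes from a VCF or a plain dosage table.

    Doses are counts of the alternative allele in {0, 1, 2}; dose 1 marks a
    heterozygous call that :func:`finalize_coding` will clear. Multiallelic
    VCF records and duplicate line ids are rejected.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate line id in VCF sample header")
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise ValueError(f"multiallelic record {rid} (ALT={rec.ALT})")
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        if "GT" in rec.FORMAT:
            gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
            alleles = gts[:, :2]
            dose = alleles.clip(min=0).sum(axis=1).astype(np.int8)
            dose[(alleles < 0).any(axis=1)] = MISSING
        elif "DS" in rec.FORMAT:
            # imputed dosages of inbred lines: threshold at 1 (DS < 1 -> 0)
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            dose = np.where(ds < 1.0, 0, 2).astype(np.int8)
            dose[~np.isfinite(ds)] = MISSING
        else:
            rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise ValueError(f"record {rid} has neither GT nor DS")
        cols.append(dose)
    vcf.close()
    doses = np.column_stack(cols) if cols else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, marker_ids, doses)


def _read_dosage_table(path) -> GenotypeMatrix:
    """Plain text table: header of marker ids, one row per line.

    Entries are in {0, 1, 2, NA}, whitespace- or comma-delimited; the first
    column holds the line id.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty dosage table {path}")
    delim = "," if "," in lines[0] else None
    header = lines[0].replace(",", " ").split()
    marker_ids = header[1:] if header[0].lower() in {"line", "id", "line_id"} else header
    line_ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.replace(",", " ").split() if delim else ln.split()
        line_ids.append(parts[0])
        row = np.array(
            [MISSING if p.upper() in {"NA", "NAN", "."} else int(p) for p in parts[1:]],
            dtype=np.int8,
        )
        if row.size != len(marker_ids):
            raise ValueError(f"row for line {parts[0]!r} has {row.size} entries, "
                             f"expected {len(marker_ids)}")
        rows.append(row)
    return GenotypeMatrix(line_ids, marker_ids, np.vstack(rows) if rows else
                          np.zeros((0, len(marker_ids)), np.int8))


def write_dosage_table(g: GenotypeMatrix, path, delimiter: str = " ") -> None:
    with open(path, "w") as fh:
        fh.write("line" + delimiter + delimiter.join(g.marker_ids) + "\n")
        for lid, row in zip(g.line_ids, g.doses):
            vals = ["NA" if v == MISSING else str(int(v)) for v in row]
            fh.write(lid + delimiter + delimiter.join(vals) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a delimited (line, environment, value) phenotype table.

    Rows with an empty value field are treated as unphenotyped and dropped;
    non-numeric values and duplicate (line, environment) pairs are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str},
                     names=["line", "environment", "value"], header=None,
                     skip_blank_lines=True)
    # tolerate a header row
    first = str(df.iloc[0]["value"]).strip().lower() if len(df) else ""
    if first in {"value", "blue", "phenotype"}:
        df = df.iloc[1:]
    df = df[~(df["value"].isna() | (df["value"].astype(str).str.strip() == ""))]
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric phenotype value in {path}: {e}") from None
    return PhenotypeTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Quality control


def finalize_coding(g: GenotypeMatrix) -> GenotypeMatrix:
    """Clear heterozygous calls, impute, and recode to minor-allele counts.

    Heterozygous doses are set to missing (DH lines cannot be heterozygous);
    each missing entry is imputed to its column's modal dose among {0, 2}
    (tie -> 0); columns whose counted-allele frequency exceeds 0.5 are
    flipped so every column counts the minor allele. Idempotent.
    """
    if g.finalized:
        raise ValueError("genotype matrix is already finalized")
    doses = g.doses.astype(np.int8).copy()
    doses[doses == 1] = MISSING
    n_missing_all = (doses == MISSING).all(axis=0)
    if n_missing_all.any():
        j = int(np.argmax(n_missing_all))
        raise ValueError(f"marker {g.marker_ids[j]!r} is entirely missing/heterozygous")
    obs = doses != MISSING
    # modal dose among {0,2}, tie -> 0
    n2 = ((doses == 2) & obs).sum(axis=0)
    n0 = obs.sum(axis=0) - n2
    mode = np.where(n2 > n0, 2, 0).astype(np.int8)
    miss_r, miss_c = np.nonzero(~obs)
    doses[miss_r, miss_c] = mode[miss_c]
    # minor-allele flip (frequency tie keeps original orientation)
    freq = doses.mean(axis=0) / 2.0
    flip = freq > 0.5
    doses[:, flip] = 2 - doses[:, flip]
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), doses, finalized=True)


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of x regressed on all the others (with intercept).

    Constant columns get VIF 0 (excluded from regressions, always retained).
    """
    n, k = x.shape
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    variable = sd > 0
    vifs = np.zeros(k)
    idx = np.nonzero(variable)[0]
    if idx.size < 2:
        return vifs
    z = xc[:, idx] / sd[idx]
    for pos, j in enumerate(idx):
        others = np.delete(z, pos, axis=1)
        target = z[:, pos]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        r2 = 1.0 - resid @ resid / (target @ target)
        r2 = min(max(r2, 0.0), 1.0)
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(g: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
              vif_threshold: float = 2.0) -> list[str]:
    """Sliding-window LD pruning by variance inflation factor.

    Within each window of ``window_snps`` still-retained markers the marker
    with the highest VIF = 1/(1-r²) is removed (greedily, recomputing after
    each removal) until all retained markers in the window have
    VIF <= ``vif_threshold``; the window then shifts by ``step_snps``.
    Returns retained marker ids in original order.
    """
    if not g.finalized:
        raise ValueError("genotypes must be finalized before pruning")
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must be > 1")
    m = g.n_markers
    retained = np.ones(m, dtype=bool)
    x_all = g.doses.astype(np.float64)
    start = 0
    while start < m:
        live = np.nonzero(retained[start:])[0] + start
        window = live[:window_snps]
        if window.size >= 2:
            while True:
                vifs = _window_vifs(x_all[:, window])
                worst = vifs.max()
                if worst <= vif_threshold:
                    break
                # ties at the max -> remove the later (largest-index) marker
                cand = np.nonzero(vifs == worst)[0]
                drop = window[cand.max()]
                retained[drop] = False
                window = window[window != drop]
                if window.size < 2:
                    break
        start += step_snps
    return [g.marker_ids[j] for j in np.nonzero(retained)[0]]
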