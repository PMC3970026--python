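"""SNP genotype matrices: I/O, quality control, imputation and LD diagnostics.

Genotypes are held as additive allele dosages (0/1/2, ``NaN`` = missing) in an
individuals-by-markers array.  The counted allele is whichever allele the input
file's dosage column refers to; its frequency ``p_i`` is the per-marker mean
dosage over observed entries divided by 2, and the minor allele frequency is
``min(p_i, 1 - p_i)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCConfig",
    "GenotypeFormatError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "impute_missing",
    "adjacent_r2",
]

#: Lead columns of a PLINK ``--recode A`` ("raw") file, before the SNP dosages.
_PLINK_LEAD_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")

#: Tokens accepted as missing dosage in either dialect.
_MISSING_TOKENS = {"NA", "na", "NaN", "nan", "-9", ""}


class GenotypeFormatError(ValueError):
    """An input file entry is not a valid dosage code (0/1/2/missing)."""


class GenotypeValidationError(ValueError):
    """A genotype matrix violates a structural requirement."""


@dataclass
class GenotypeMatrix:
    """Additive SNP dosages with marker/individual identifiers.

    Attributes
    ----------
    dosages
        ``(n_individuals, n_markers)`` float array with entries in {0, 1, 2}
        or NaN for missing.
    marker_ids, individual_ids
        Unique string labels for columns and rows.
    allele_freq
        Frequency of the counted allele per marker, mean(dosage)/2 over
        observed entries.
    """

    dosages: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]
    allele_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeValidationError("dosages must be a 2-D array")
        n, p = self.dosages.shape
        if n == 0:
            raise GenotypeValidationError("no individuals in genotype matrix")
        if p == 0:
            raise GenotypeValidationError("no markers in genotype matrix")
        if len(self.marker_ids) != p or len(self.individual_ids) != n:
            raise GenotypeValidationError("id lists do not match dosage shape")
        if len(set(self.marker_ids)) != p:
            raise GenotypeValidationError("duplicate marker ids")
        if len(set(self.individual_ids)) != n:
            raise GenotypeValidationError("duplicate individual ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise GenotypeFormatError(f"dosage entry {bad!r} not in {{0,1,2}}")
        import warnings as _warnings
        with _warnings.catch_warnings():
            # all-missing markers yield NaN frequency; rejected downstream
            _warnings.simplefilter("ignore", RuntimeWarning)
            self.allele_freq = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency, ``min(p, 1-p)`` per marker."""
        return np.minimum(self.allele_freq, 1.0 - self.allele_freq)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())


@dataclass
class QCConfig:
    """Marker quality-control settings.

    ``maf_threshold`` removes markers with MAF strictly below it (markers at
    exactly the threshold are kept); ``drop_monomorphic`` removes markers with
    p in {0, 1} even when the threshold is 0.
    """

    maf_threshold: float = 0.05
    drop_monomorphic: bool = True
    impute_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")


def _parse_token(tok: str, row: int, col: str) -> float:
    tok = tok.strip()
    if tok in _MISSING_TOKENS:
        return np.nan
    try:
        value = float(tok)
    except ValueError:
        raise GenotypeFormatError(
            f"unparseable dosage {tok!r} at row {row}, marker {col!r}"
        ) from None
    if value not in (0.0, 1.0, 2.0):
        raise GenotypeFormatError(
            f"dosage {tok!r} at row {row}, marker {col!r} not in {{0,1,2,NA}}"
        )
    return value


def read_genotypes(path, format: str = "matrix") -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    Parameters
    ----------
    path
        File path or file-like object.
    format
        ``"matrix"`` — header row of marker ids, first column individual id,
        whitespace/tab/comma delimited dosages.  ``"plink_raw"`` — PLINK
        additive-dosage export: header starting ``FID IID PAT MAT SEX
        PHENOTYPE`` followed by one column per SNP.

    Missing dosages may be coded ``NA``, ``-9`` or left blank.
    """
    if format not in ("matrix", "plink_raw"):
        raise ValueError(f"unknown genotype format {format!r}")
    sep = r"\s+|,|\t"
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise GenotypeValidationError("empty genotype file: no individuals")

    if format == "plink_raw":
        missing_lead = [c for c in _PLINK_LEAD_COLUMNS if c not in df.columns[:6].tolist()]
        if missing_lead:
            raise GenotypeFormatError(
                f"plink_raw header lacks lead columns {missing_lead}"
            )
        individual_ids = df["IID"].tolist()
        marker_cols = [c for c in df.columns if c not in _PLINK_LEAD_COLUMNS]
    else:
        individual_ids = df.iloc[:, 0].tolist()
        marker_cols = list(df.columns[1:])
    if not marker_cols:
        raise GenotypeValidationError("no marker columns found")

    n, p = len(individual_ids), len(marker_cols)
    dosages = np.empty((n, p))
    for j, col in enumerate(marker_cols):
        col_vals = df[col].to_numpy()
        for i in range(n):
            dosages[i, j] = _parse_token(col_vals[i], i + 1, col)
    return GenotypeMatrix(dosages, [str(c) for c in marker_cols],
                          [str(i) for i in individual_ids])


def write_genotypes(g: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the plain-matrix dialect (header = marker ids, first column id)."""
    with _open_write(path) as fh:
        fh.write("id" + sep + sep.join(g.marker_ids) + "\n")
        for i, iid in enumerate(g.individual_ids):
            row = g.dosages[i]
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(iid) + sep + sep.join(toks) + "\n")


def _open_write(path):
    if hasattr(path, "write"):
        class _NoClose:
            def __init__(self, fh):
                self.fh = fh
            def __enter__(self):
                return self.fh
            def __exit__(self, *a):
                return False
        return _NoClose(path)
    return open(path, "w")


def qc_filter(
    g: GenotypeMatrix, cfg: QCConfig | None = None, report_path=None
) -> GenotypeMatrix:
    """Remove low-MAF (and optionally monomorphic) markers.

    Markers with ``min(p, 1-p) >= maf_threshold`` are retained; with
    ``drop_monomorphic`` markers at p in {0, 1} are removed regardless of the
    threshold.  Marker order is preserved.  If ``report_path`` is given a TSV
    report (marker, p, kept, reason) is written.
    """
    cfg = cfg or QCConfig()
    p = g.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= cfg.maf_threshold
    reason = np.where(keep, "", "low_maf")
    if cfg.drop_monomorphic:
        mono = (p <= 0.0) | (p >= 1.0)
        reason = np.where(mono, "monomorphic", reason)
        keep &= ~mono
    if report_path is not None:
        rep = pd.DataFrame(
            {"marker": g.marker_ids, "p": p, "kept": keep, "reason": reason}
        )
        rep.to_csv(report_path, sep="\t", index=False)
    if not keep.any():
        raise GenotypeValidationError("QC removed every marker")
    if keep.all():
        return g
    return GenotypeMatrix(
        g.dosages[:, keep],
        [m for m, k in zip(g.marker_ids, keep) if k],
        list(g.individual_ids),
    )


def impute_missing(g: GenotypeMatrix, seed: int | None = None) -> GenotypeMatrix:
    """Fill missing dosages by sampling two alleles at the marginal frequency.

    Each missing entry in marker ``i`` is replaced by a Binomial(2, p_i) draw
    (two independent Bernoulli allele samples), with ``p_i`` estimated from the
    observed entries of that marker.  Observed entries are untouched.
    """
    if not g.has_missing:
        return g
    miss = np.isnan(g.dosages)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(g.marker_ids, all_missing) if a]
        raise GenotypeValidationError(
            f"markers with no observed genotypes (cannot estimate frequency): {bad[:5]}"
        )
    rng = np.random.default_rng(seed)
    dosages = g.dosages.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        rows = np.flatnonzero(miss[:, j])
        dosages[rows, j] = rng.binomial(2, g.allele_freq[j], size=rows.size)
    return GenotypeMatrix(dosages, list(g.marker_ids), list(g.individual_ids))


def adjacent_r2(g: GenotypeMatrix) -> dict:
    """Squared Pearson correlation of dosages for each adjacent marker pair.

    Pairs involving a monomorphic marker (zero dosage variance) are skipped.
    Returns ``{"mean": float, "pairs": DataFrame(marker_a, marker_b, r2)}``.
    """
    if g.has_missing:
        raise GenotypeValidationError("impute missing dosages before LD summaries")
    if g.n_markers < 2:
        raise GenotypeValidationError("need at least 2 markers for adjacent r^2")
    X = g.dosages
    sd = X.std(axis=0)
    rows = []
    for j in range(g.n_markers - 1):
        if sd[j] == 0.0 or sd[j + 1] == 0.0:
            continue
        r = np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
        rows.append((g.marker_ids[j], g.marker_ids[j + 1], r * r))
    if not rows:
        raise GenotypeValidationError("no usable (polymorphic) adjacent pairs")
    pairs = pd.DataFrame(rows, columns=["marker_a", "marker_b", "r2"])
    return {"mean": float(pairs["r2"].mean()), "pairs": pairs}
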