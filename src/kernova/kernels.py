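"""Parametric and Gaussian genomic kernels.

Six n-by-n similarity kernels over individuals are supported:

* ``G`` — VanRaden additive genomic relationship matrix, ``Z Z' / sum 2pq``
  with ``Z`` the 0/1/2 dosage matrix column-centered by ``2p``.
* ``D`` — dominance relationship matrix from centered heterozygosity
  indicators, standardized by ``sum 2pq(1 - 2pq)``.
* ``GD`` — their Hadamard (element-wise) product, modelling additive-by-
  dominance epistatic covariance under linkage equilibrium.
* ``GK_A`` / ``GK_D`` — Gaussian kernels ``exp(-theta ||x_i - x_j||^2)`` on
  the additive (0/1/2) and dominance (+-0.5) codings.
* ``GK_AD`` — Hadamard product of the two Gaussian kernels.

Gaussian bandwidths are calibrated so the mean off-diagonal kernel value hits
a target level: 0.12 for a "local" kernel (similarity decays quickly) and
0.90 for a "global" one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypeMatrix, GenotypeValidationError

__all__ = [
    "Kernel",
    "BandwidthSpec",
    "write_kernel",
    "read_kernel",
    "additive_coding",
    "dominance_coding",
    "gaussian_kernel",
    "vanraden_G",
    "dominance_D",
    "hadamard",
    "calibrate_bandwidth",
    "offdiag_stats",
    "build_kernel_set",
    "PSD_RTOL",
]

#: Relative floor for the minimum eigenvalue: lambda_min >= -PSD_RTOL*trace/n.
PSD_RTOL = 1e-8


@dataclass
class Kernel:
    """A named positive semi-definite n-by-n similarity matrix."""

    matrix: np.ndarray
    name: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def is_psd(self, rtol: float = PSD_RTOL) -> bool:
        floor = -rtol * np.trace(self.matrix) / self.n
        return self.min_eigenvalue() >= floor


@dataclass
class BandwidthSpec:
    """Target mean off-diagonal levels for the local/global Gaussian pair."""

    target_offdiag_local: float = 0.12
    target_offdiag_global: float = 0.90
    tolerance: float = 0.001

    def __post_init__(self) -> None:
        for t in (self.target_offdiag_local, self.target_offdiag_global):
            if not 0.0 < t < 1.0:
                raise ValueError("bandwidth targets must lie in (0, 1)")


def _require_complete(g: GenotypeMatrix) -> None:
    if g.has_missing:
        raise GenotypeValidationError(
            "genotypes contain missing dosages; run impute_missing first"
        )


def additive_coding(g: GenotypeMatrix) -> np.ndarray:
    """Additive coding X_A: the 0/1/2 dosages unchanged (aa=0, Aa=1, AA=2)."""
    _require_complete(g)
    return g.dosages.copy()


def dominance_coding(g: GenotypeMatrix) -> np.ndarray:
    """Dominance contrast X_D: heterozygotes +0.5, both homozygotes -0.5."""
    _require_complete(g)
    return np.where(g.dosages == 1.0, 0.5, -0.5)


def gaussian_kernel(X: np.ndarray, theta: float, name: str = "GK") -> Kernel:
    """Gaussian kernel K[i,j] = exp(-theta * ||x_i - x_j||^2).

    The diagonal is exactly 1 and off-diagonals lie in (0, 1]; larger theta
    means similarity decays faster with genotypic distance.
    """
    if theta <= 0:
        raise ValueError("bandwidth theta must be positive")
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("coded genotype matrix must be finite")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    K = np.exp(-theta * d2)
    np.fill_diagonal(K, 1.0)
    return Kernel(K, name, {"theta": float(theta), "n_markers": X.shape[1]})


def vanraden_G(g: GenotypeMatrix) -> Kernel:
    """VanRaden additive genomic relationship matrix (method 1).

    ``G = Z Z' / sum_i 2 p_i (1 - p_i)`` with ``Z`` the dosages centered by
    twice the observed allele frequency.  Requires polymorphic markers.
    """
    _require_complete(g)
    p = g.allele_freq
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise GenotypeValidationError(
            "monomorphic markers present; run qc_filter before building G"
        )
    Z = g.dosages - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return Kernel(G, "G", {"n_markers": g.n_markers, "denominator": denom})


def dominance_D(g: GenotypeMatrix) -> Kernel:
    """Dominance relationship matrix from heterozygosity indicators.

    Under Hardy-Weinberg equilibrium the heterozygosity indicator at locus i
    has mean ``2 p_i q_i`` and variance ``2 p_i q_i (1 - 2 p_i q_i)``; D is
    the cross-product of the centered indicators over the summed variance.
    """
    _require_complete(g)
    p = g.allele_freq
    tpq = 2.0 * p * (1.0 - p)
    var = tpq * (1.0 - tpq)
    if np.any(var <= 0.0):
        raise GenotypeValidationError(
            "markers with zero dominance variance (2pq(1-2pq)=0); run qc_filter"
        )
    het = (g.dosages == 1.0).astype(float)
    W = het - tpq
    denom = float(np.sum(var))
    D = (W @ W.T) / denom
    return Kernel(D, "D", {"n_markers": g.n_markers, "denominator": denom})


def hadamard(k1: Kernel, k2: Kernel, name: str | None = None) -> Kernel:
    """Element-wise (Hadamard) kernel product; PSD by the Schur product theorem."""
    if k1.n != k2.n:
        raise ValueError(f"kernel dimensions differ: {k1.n} vs {k2.n}")
    if name is None:
        name = k1.name + k2.name if {k1.name, k2.name} == {"G", "D"} else (
            f"{k1.name}#{k2.name}"
        )
    prov = {"factors": (k1.name, k2.name), **{f"{k1.name}_prov": k1.provenance,
                                              f"{k2.name}_prov": k2.provenance}}
    return Kernel(k1.matrix * k2.matrix, name, prov)


def _mean_offdiag_exp(theta: float, d2_flat: np.ndarray) -> float:
    return float(np.mean(np.exp(-theta * d2_flat)))


def calibrate_bandwidth(
    X: np.ndarray,
    target_offdiag: float,
    tolerance: float = 0.001,
    max_iter: int = 200,
) -> float:
    """Find theta so the Gaussian kernel's mean off-diagonal equals a target.

    The mean off-diagonal ``mean_ij exp(-theta d2_ij)`` is continuous and
    strictly decreasing in theta, so bisection on log(theta) converges; the
    bracket is ``[1e-12, 1e3] / mean(d2)``.
    """
    if not 0.0 < target_offdiag < 1.0:
        raise ValueError("target mean off-diagonal must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two individuals")
    d2 = pdist(X, metric="sqeuclidean")
    mean_d2 = float(d2.mean())
    if mean_d2 == 0.0:
        raise ValueError(
            "all rows identical: mean off-diagonal is 1 for every bandwidth"
        )
    lo, hi = 1e-12 / mean_d2, 1e3 / mean_d2
    f_lo = _mean_offdiag_exp(lo, d2)   # ~1
    f_hi = _mean_offdiag_exp(hi, d2)   # ~0
    if not (f_hi < target_offdiag < f_lo):
        raise RuntimeError(
            f"target {target_offdiag} outside attainable range "
            f"({f_hi:.3g}, {f_lo:.3g}) for bracket"
        )
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        f = _mean_offdiag_exp(np.exp(lmid), d2)
        if abs(f - target_offdiag) <= tolerance:
            return float(np.exp(lmid))
        if f > target_offdiag:   # kernel too "global": increase theta
            llo = lmid
        else:
            lhi = lmid
    raise RuntimeError(
        f"bandwidth bisection did not reach target {target_offdiag} "
        f"within {max_iter} iterations"
    )


def offdiag_stats(k1: Kernel, k2: Kernel | None = None) -> dict:
    """Summaries of strictly-upper-triangle kernel entries.

    Returns the mean absolute off-diagonal of ``k1`` and, when ``k2`` is
    given, the Pearson correlation between paired off-diagonal elements.
    """
    if k1.n < 2:
        raise ValueError("need at least two individuals")
    iu = np.triu_indices(k1.n, k=1)
    off1 = k1.matrix[iu]
    out = {"mean_abs_offdiag": float(np.mean(np.abs(off1)))}
    if k2 is not None:
        if k2.n != k1.n:
            raise ValueError("kernel dimensions differ")
        off2 = k2.matrix[iu]
        out["offdiag_correlation"] = float(np.corrcoef(off1, off2)[0, 1])
    return out


def write_kernel(k: Kernel, path, ids=None, sep: str = "\t") -> None:
    """Serialize a kernel as a square delimited matrix with an ID header
    row/column, plus a JSON sidecar (``<path>.json``) recording name and
    construction parameters."""
    import json
    import pandas as pd

    ids = list(ids) if ids is not None else [f"i{j}" for j in range(k.n)]
    pd.DataFrame(k.matrix, index=ids, columns=ids).to_csv(path, sep=sep)
    sidecar = {"name": k.name, "n": k.n, "provenance": k.provenance}
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_kernel(path, sep: str = "\t") -> Kernel:
    """Read a kernel written by :func:`write_kernel` (sidecar optional)."""
    import json
    import os
    import pandas as pd

    df = pd.read_csv(path, sep=sep, index_col=0)
    name, prov = "K", {}
    if os.path.exists(f"{path}.json"):
        with open(f"{path}.json") as fh:
            side = json.load(fh)
        name = side.get("name", name)
        prov = side.get("provenance", prov)
    return Kernel(df.to_numpy(dtype=float), name, prov)


# Named kernel sets compared in cross-validation.  Gaussian entries expand to
# a (local, global) bandwidth pair fitted jointly ("kernel averaging").
KERNEL_SET_NAMES = ("G", "GK_A", "GK_D", "GK_ALL", "ALL")


def build_kernel_set(
    g: GenotypeMatrix,
    set_name: str,
    bandwidths: BandwidthSpec | None = None,
) -> list[Kernel]:
    """Construct the kernels of a named comparison set.

    ``G`` — GBLUP benchmark; ``GK_A``/``GK_D`` — additive/dominance Gaussian
    kernels at both calibrated bandwidths; ``GK_ALL`` — all three Gaussian
    kernels (A, D, A#D) at both bandwidths; ``ALL`` — parametric G, D, G#D.
    """
    bandwidths = bandwidths or BandwidthSpec()
    if set_name == "G":
        return [vanraden_G(g)]
    if set_name == "ALL":
        G, D = vanraden_G(g), dominance_D(g)
        return [G, D, hadamard(G, D)]
    if set_name not in ("GK_A", "GK_D", "GK_ALL"):
        raise ValueError(f"unknown kernel set {set_name!r}; "
                         f"choose from {KERNEL_SET_NAMES}")

    out: list[Kernel] = []
    XA = additive_coding(g)
    XD = dominance_coding(g)
    for scope, target in (
        ("local", bandwidths.target_offdiag_local),
        ("global", bandwidths.target_offdiag_global),
    ):
        ka = kd = None
        if set_name in ("GK_A", "GK_ALL"):
            th = calibrate_bandwidth(XA, target, bandwidths.tolerance)
            ka = gaussian_kernel(XA, th, name=f"GK_A_{scope}")
        if set_name in ("GK_D", "GK_ALL"):
            th = calibrate_bandwidth(XD, target, bandwidths.tolerance)
            kd = gaussian_kernel(XD, th, name=f"GK_D_{scope}")
        out.extend(k for k in (ka, kd) if k is not None)
        if set_name == "GK_ALL":
            out.append(hadamard(ka, kd, name=f"GK_AD_{scope}"))
    return out
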