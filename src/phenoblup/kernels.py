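"""Relationship kernels for hybrid prediction.

Builds every covariance matrix the prediction models use: marker QC and
imputation, VanRaden general-combining-ability (GCA) kinships per
heterotic pool, spectra-derived H matrices, specific-combining-ability
(SCA) kernels over hybrid crosses, and the unit-sample-variance scaling
applied to all genomic and spectral kernels before model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import FactorialDesign
from .errors import ConfigurationError, KeyedError, StructuralError

VALID_CALLS = (0.0, 0.5, 1.0)


@dataclass
class GenotypeMatrix:
    """Inbred lines x biallelic markers, coded 0 / 0.5 / 1.

    ``values`` holds the reference-allele dosage halved to [0, 1]
    (0 and 1 the two homozygotes, 0.5 heterozygous); missing calls are
    NaN.  ``chrom`` and ``pos_cM`` are optional genetic-map coordinates
    used by the simulator.
    """

    values: np.ndarray
    line_ids: list[str]
    pools: list[str]
    marker_ids: list[str]
    chrom: np.ndarray | None = None
    pos_cM: np.ndarray | None = None
    imputed: bool = False  # frequency-imputed entries are fractional

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise StructuralError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(self.pools) != len(self.line_ids):
            raise StructuralError("one pool label per line required")
        obs = self.values[~np.isnan(self.values)]
        if self.imputed:
            if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
                raise StructuralError("imputed genotype calls outside [0, 1]")
        else:
            bad = obs[~np.isin(obs, VALID_CALLS)]
            if bad.size:
                raise StructuralError(
                    f"genotype calls outside {{0, 0.5, 1}}: e.g. {bad[:3]}"
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def pool_of(self) -> dict[str, str]:
        return dict(zip(self.line_ids, self.pools))

    def subset_pool(self, pool: str, drop_monomorphic: bool = True) -> "GenotypeMatrix":
        """Lines of one pool; optionally drop markers fixed within it."""
        rows = [i for i, p in enumerate(self.pools) if p == pool]
        if not rows:
            raise KeyedError(f"no lines in pool {pool!r}", keys=[pool])
        vals = self.values[rows]
        keep = slice(None)
        marker_ids = list(self.marker_ids)
        if drop_monomorphic:
            f = _allele_freq(vals)
            keep = np.where((f > 0.0) & (f < 1.0))[0]
            vals = vals[:, keep]
            marker_ids = [self.marker_ids[j] for j in keep]
        return GenotypeMatrix(
            vals,
            [self.line_ids[i] for i in rows],
            [pool] * len(rows),
            marker_ids,
            None if self.chrom is None else self.chrom[keep],
            None if self.pos_cM is None else self.pos_cM[keep],
            imputed=self.imputed,
        )

    def allele_freqs(self) -> np.ndarray:
        """Reference-allele frequency per marker, NaN-aware, over all lines."""
        return _allele_freq(self.values)


def _allele_freq(vals: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(vals, axis=0)


@dataclass
class KernelMatrix:
    """Symmetric relationship matrix over lines or hybrid crosses."""

    values: np.ndarray
    ids: list[str]
    source: str  # pedigree | genomic | spectral
    role: str  # GCA_dent | GCA_flint | SCA
    scaled: bool = False
    jitter: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise StructuralError(f"kernel shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise StructuralError("kernel ids are not unique")
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0.0):
            raise StructuralError("kernel is not symmetric (tolerance 1e-10)")

    def submatrix(self, rows, cols=None) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in rows if g not in idx]
        if cols is not None:
            missing += [g for g in cols if g not in idx]
        if missing:
            raise KeyedError(
                f"ids absent from kernel: {sorted(set(missing))[:5]}",
                keys=sorted(set(missing)),
            )
        ri = [idx[g] for g in rows]
        ci = ri if cols is None else [idx[g] for g in cols]
        return self.values[np.ix_(ri, ci)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def filter_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    max_het_dent: float = 0.05,
    max_het_flint: float = 0.10,
    min_maf: float = 0.05,
    dent_pool: str = "dent",
    flint_pool: str = "flint",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers by missingness, per-pool heterozygosity, and MAF.

    A marker is removed if its missing rate exceeds ``max_missing``
    within either pool, if its heterozygous-call (0.5) rate exceeds the
    pool-specific ceiling, or if it is not polymorphic at
    ``min_maf`` in at least one pool.  Returns the filtered matrix and
    an audit table with one row per marker and the rule(s) it violated.
    """
    het_limits = {dent_pool: max_het_dent, flint_pool: max_het_flint}
    pools = sorted(set(g.pools))
    masks = {p: np.array([q == p for q in g.pools]) for p in pools}

    n_mark = g.n_markers
    miss_bad = np.zeros(n_mark, bool)
    het_bad = np.zeros(n_mark, bool)
    maf_ok = np.zeros(n_mark, bool)
    for p in pools:
        vals = g.values[masks[p]]
        miss = np.isnan(vals).mean(axis=0)
        miss_bad |= miss > max_missing
        het = np.nanmean(vals == 0.5, axis=0)
        limit = het_limits.get(p)
        if limit is not None:
            het_bad |= het > limit
        f = _allele_freq(vals)
        with np.errstate(invalid="ignore"):
            maf = np.minimum(f, 1.0 - f)
        maf_ok |= np.nan_to_num(maf, nan=0.0) >= min_maf
    keep = ~miss_bad & ~het_bad & maf_ok

    audit = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "fail_missing": miss_bad,
            "fail_het": het_bad,
            "fail_maf": ~maf_ok,
            "kept": keep,
        }
    )
    if not keep.any():
        raise ConfigurationError(
            f"all {n_mark} markers removed by QC filters; audit:\n"
            f"{audit[['fail_missing', 'fail_het', 'fail_maf']].sum().to_dict()}"
        )
    idx = np.where(keep)[0]
    filtered = GenotypeMatrix(
        g.values[:, idx],
        list(g.line_ids),
        list(g.pools),
        [g.marker_ids[j] for j in idx],
        None if g.chrom is None else g.chrom[idx],
        None if g.pos_cM is None else g.pos_cM[idx],
    )
    return filtered, audit


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the pool allele frequency of the marker."""
    vals = g.values.copy()
    for p in sorted(set(g.pools)):
        mask = np.array([q == p for q in g.pools])
        block = vals[mask]
        entirely = np.isnan(block).all(axis=0)
        if entirely.any():
            j = int(np.where(entirely)[0][0])
            raise StructuralError(
                f"marker {g.marker_ids[j]!r} entirely missing in pool {p!r}; "
                "should have been removed by filter_markers"
            )
        f = _allele_freq(block)
        miss = np.isnan(block)
        block[miss] = np.broadcast_to(f, block.shape)[miss]
        vals[mask] = block
    return GenotypeMatrix(
        vals,
        list(g.line_ids),
        list(g.pools),
        list(g.marker_ids),
        g.chrom,
        g.pos_cM,
        imputed=True,
    )


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def vanraden_gca_kinship(g: GenotypeMatrix, role: str | None = None) -> KernelMatrix:
    """VanRaden (method 1) kinship for inbred lines of one pool.

    K(i,i') = sum_m (G_im - f_m)(G_i'm - f_m) / sum_m f_m (1 - f_m),
    with f_m the reference-allele frequency estimated within the pool.
    """
    pools = set(g.pools)
    if len(pools) != 1:
        raise StructuralError(
            f"kinship is computed within one pool; got {sorted(pools)}"
        )
    if np.isnan(g.values).any():
        raise StructuralError("genotypes contain missing calls; impute first")
    f = g.allele_freqs()
    if ((f <= 0.0) | (f >= 1.0)).any():
        j = int(np.where((f <= 0.0) | (f >= 1.0))[0][0])
        raise StructuralError(
            f"marker {g.marker_ids[j]!r} is monomorphic in this pool "
            "(f in {0,1}); filtering violated"
        )
    centered = g.values - f
    denom = float(np.sum(f * (1.0 - f)))
    k = centered @ centered.T / denom
    k = (k + k.T) / 2.0
    pool = next(iter(pools))
    return KernelMatrix(
        k, list(g.line_ids), "genomic", role or f"GCA_{pool}", scaled=False
    )


def spectral_relationship(pretreated, role: str, trial: str | None = None) -> KernelMatrix:
    """H matrix from pretreated spectra: H = S* S*' / L.

    ``pretreated`` is a :class:`~phenoblup.spectra.SpectraSet` in the
    ``derivative`` state with one spectrum per genotype (one tissue and
    trial).  Each wavelength column is centered and scaled to unit
    sample variance across genotypes before the cross product; columns
    with zero variance are dropped with a warning and L decremented.
    """
    if pretreated.state != "derivative":
        raise StructuralError(
            f"spectral_relationship requires state 'derivative', got "
            f"{pretreated.state!r}"
        )
    gids = list(pretreated.meta["genotype_id"])
    if len(set(gids)) != len(gids):
        raise StructuralError(
            "one spectrum per genotype required (aggregate trials/tissues first)"
        )
    s = np.asarray(pretreated.values, dtype=float)
    sd = s.std(axis=0, ddof=1)
    dead = sd == 0.0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} zero-variance wavelength column(s) "
            "before the H cross-product",
            stacklevel=2,
        )
        s = s[:, ~dead]
        sd = sd[~dead]
    if s.shape[1] == 0:
        raise StructuralError("no wavelength with variance; H undefined")
    star = (s - s.mean(axis=0)) / sd
    L = star.shape[1]
    h = star @ star.T / L
    h = (h + h.T) / 2.0
    meta = {"L": L, "trial": trial} if trial else {"L": L}
    return KernelMatrix(h, gids, "spectral", role, scaled=False, meta=meta)


def sca_kernel(
    kd: KernelMatrix, kf: KernelMatrix, design: FactorialDesign
) -> KernelMatrix:
    """SCA kernel over crosses: K_SCA((ij),(i'j')) = K_d(i,i') * K_f(j,j')."""
    if kd.source != kf.source:
        raise StructuralError(
            f"parental kernels must share a source; got {kd.source!r} vs "
            f"{kf.source!r}"
        )
    dents = [d for _, d, _ in design.hybrids]
    flints = [f for _, _, f in design.hybrids]
    d_block = kd.submatrix(dents)
    f_block = kf.submatrix(flints)
    k = d_block * f_block
    k = (k + k.T) / 2.0
    return KernelMatrix(k, design.hybrid_ids, kd.source, "SCA", scaled=False)


def scale_unit_variance(k: KernelMatrix) -> KernelMatrix:
    """Divide by the sample s.d. of all entries so their variance is 1."""
    if k.scaled:
        raise StructuralError(f"kernel {k.role} ({k.source}) is already scaled")
    sd = float(k.values.std(ddof=1))
    if sd == 0.0:
        raise ConfigurationError(
            f"kernel {k.role} ({k.source}) is constant; cannot scale to unit "
            "variance"
        )
    return replace(k, values=k.values / sd, scaled=True)


def two_level_pedigree_kernel(
    ids: list[str],
    family_of: dict[str, str],
    role: str,
    diag: float = 1.0,
    within: float = 0.5,
    between: float = 0.25,
) -> KernelMatrix:
    """Expected-relationship matrix from family membership alone.

    Lines of the same biparental family get ``within``, lines of
    different families ``between`` and the diagonal ``diag``.  Because
    every cross-family coefficient is identical, such a pedigree kernel
    carries no information for predicting hybrids whose parental
    families are absent from training — the situation the across-family
    cross-validation scenario isolates.
    """
    if not (diag >= within >= between >= 0):
        raise ConfigurationError(
            "pedigree coefficients must satisfy diag >= within >= between >= 0"
        )
    missing = [i for i in ids if i not in family_of]
    if missing:
        raise KeyedError(
            f"lines without family: {missing[:5]}", keys=missing
        )
    fams = np.asarray([family_of[i] for i in ids], dtype=object)
    same_fam = fams[:, None] == fams[None, :]
    k = np.where(same_fam, within, between).astype(float)
    np.fill_diagonal(k, diag)
    return KernelMatrix(k, list(ids), "pedigree", role, scaled=False)


def repair_psd(k: KernelMatrix, tol: float = 1e-8, pad: float = 1e-6) -> KernelMatrix:
    """Add diagonal jitter if the smallest eigenvalue is below ``-tol``.

    REML needs invertible covariances; numerically indefinite kernels
    (e.g. products of near-singular parental kernels) get
    ``|min eig| + pad`` added to the diagonal, recorded in ``jitter``.
    """
    lam = k.min_eigenvalue()
    if lam >= -tol:
        return k
    jit = abs(lam) + pad
    vals = k.values + np.eye(len(k.ids)) * jit
    return replace(k, values=vals, jitter=k.jitter + jit)
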