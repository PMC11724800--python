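"""Synthetic maize hybrid data with the structure the analysis assumes.

No public dataset accompanies the study design this package targets, so
this module generates one with the same statistical skeleton: two
heterotic pools (dent, flint) of inbred lines derived as six connected
biparental families from four founders per pool (doubled haploids for
dent, single-seed-descent selfing for flint); a sparse factorial in
which each parent contributes about four hybrids; hybrid phenotypes
driven by GCA + SCA + error; and multi-trial NIR-like spectra whose
per-wavelength genetic and genotype-by-trial variance shares follow
user-set profiles.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .design import FactorialDesign
from .errors import ConfigurationError, KeyedError, StructuralError
from .kernels import GenotypeMatrix, sca_kernel, vanraden_gca_kinship
from .spectra import SpectraSet


def _default_h2_profile(L: int) -> np.ndarray:
    # variable along the spectrum, spanning ~0 to ~0.9
    x = np.linspace(0.0, 1.0, L)
    return 0.45 * (1.0 - np.cos(2.0 * np.pi * x))


def _default_gxe_profile(L: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, L)
    return 0.05 + 0.18 * (1.0 - np.cos(4.0 * np.pi * x)) / 2.0


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated design: 2 pools x 6 families x 15
    lines (90 + 90 parents from 4 founders per pool), dent lines by
    doubled haploidization and flint lines by six selfing generations,
    ~4 hybrids per parent (~360 hybrids), hybrid traits with GCA
    variances 1.0 per pool, SCA variance 0.25 and error variance 1.0,
    and two spectra trials on a 150-point wavelength grid.
    """

    pools: tuple[str, str] = ("dent", "flint")
    founders_per_pool: int = 4
    families_per_pool: int = 6
    lines_per_family: int = 15
    derivation: dict = dc_field(
        default_factory=lambda: {"dent": "DH", "flint": "SSD"}
    )
    n_selfing_generations: int = 6
    n_chromosomes: int = 10
    markers_per_chromosome: int = 40
    map_length: float = 100.0  # cM per chromosome
    founder_freq_range: tuple[float, float] = (0.2, 0.8)
    hybrids_per_parent: int = 4
    n_traits: int = 1
    var_gca_dent: float = 1.0
    var_gca_flint: float = 1.0
    var_sca: float = 0.25
    var_error: float = 1.0
    wavelength_grid: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(400.0, 2490.0, 150)
    )
    h2_profile: np.ndarray | None = None
    gxe_profile: np.ndarray | None = None
    smooth_window: int = 9  # moving-average width for spectral loadings
    n_trials: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "founders_per_pool": self.founders_per_pool,
            "families_per_pool": self.families_per_pool,
            "lines_per_family": self.lines_per_family,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "hybrids_per_parent": self.hybrids_per_parent,
            "n_trials": self.n_trials,
            "n_traits": self.n_traits,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.map_length <= 0:
            raise ConfigurationError("map_length must be > 0")
        for name in ("var_gca_dent", "var_gca_flint", "var_sca", "var_error"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        self.wavelength_grid = np.asarray(self.wavelength_grid, float)
        L = len(self.wavelength_grid)
        if self.h2_profile is None:
            self.h2_profile = _default_h2_profile(L)
        if self.gxe_profile is None:
            self.gxe_profile = _default_gxe_profile(L)
        self.h2_profile = np.asarray(self.h2_profile, float)
        self.gxe_profile = np.asarray(self.gxe_profile, float)
        if len(self.h2_profile) != L or len(self.gxe_profile) != L:
            raise StructuralError(
                "h2_profile and gxe_profile must match the wavelength grid"
            )
        if (self.h2_profile < 0).any() or (self.gxe_profile < 0).any():
            raise ConfigurationError("variance-share profiles must be >= 0")
        if np.any(self.h2_profile + self.gxe_profile > 1.0 + 1e-12):
            raise ConfigurationError(
                "h2_profile + gxe_profile must be <= 1 at every wavelength"
            )
        if self.founders_per_pool < 2:
            raise ConfigurationError("need at least 2 founders per pool")

    def rng(self, *stream) -> np.random.Generator:
        """Independent, reproducible generator for a named substream."""
        keys = [int(self.seed) % (2**31)]
        keys += [zlib.crc32(str(s).encode()) for s in stream]
        return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig):
    m = cfg.markers_per_chromosome
    pos = (np.arange(m) + 0.5) / m * cfg.map_length
    chrom = np.repeat(np.arange(cfg.n_chromosomes), m)
    pos_all = np.tile(pos, cfg.n_chromosomes)
    ids = [f"chr{c + 1}_m{i + 1}" for c in range(cfg.n_chromosomes) for i in range(m)]
    return chrom, pos_all, ids


def simulate_founder_genomes(cfg: SimConfig) -> GenotypeMatrix:
    """Fully homozygous founder lines for both pools.

    Per-marker founder allele frequencies are drawn uniformly from
    ``cfg.founder_freq_range``; each founder's allele at each marker is
    a Bernoulli draw at that frequency, so entries are in {0, 1}.
    """
    rng = cfg.rng("founders")
    chrom, pos, ids = _marker_map(cfg)
    n_mark = len(ids)
    rows, line_ids, pools = [], [], []
    for pool in cfg.pools:
        lo, hi = cfg.founder_freq_range
        f = rng.uniform(lo, hi, n_mark)
        for i in range(cfg.founders_per_pool):
            rows.append((rng.random(n_mark) < f).astype(float))
            line_ids.append(f"{pool[0].upper()}F{i + 1}")
            pools.append(pool)
    return GenotypeMatrix(np.vstack(rows), line_ids, pools, ids, chrom, pos)


def _meiosis(h1: np.ndarray, h2: np.ndarray, chrom, pos, rng) -> np.ndarray:
    """One gamete from a haplotype pair, Haldane map (no interference)."""
    gamete = np.empty_like(h1)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        d = np.diff(pos[idx])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        switch = rng.random(len(d)) < r
        strand = (int(rng.integers(2)) + np.concatenate([[0], np.cumsum(switch)])) % 2
        gamete[idx] = np.where(strand == 0, h1[idx], h2[idx])
    return gamete


def derive_family(
    parentA: np.ndarray,
    parentB: np.ndarray,
    cfg: SimConfig,
    n_lines: int,
    method: str,
    chrom: np.ndarray,
    pos: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inbred progeny of an A x B cross as an (n_lines, markers) array.

    ``DH``: one meiosis from the F1 then chromosome doubling (fully
    homozygous).  ``SSD``: ``cfg.n_selfing_generations`` generations of
    selfing from the F1 by single-seed descent (residual
    heterozygosity, coded 0.5, is possible).
    """
    parentA = np.asarray(parentA, float)
    parentB = np.asarray(parentB, float)
    if parentA.shape != parentB.shape or len(parentA) != len(chrom):
        raise StructuralError("parents must share one marker map")
    for p in (parentA, parentB):
        if not np.isin(p, (0.0, 1.0)).all():
            raise StructuralError("parents must be fully homozygous ({0,1})")
    out = np.empty((n_lines, len(parentA)))
    for i in range(n_lines):
        if method == "DH":
            g = _meiosis(parentA, parentB, chrom, pos, rng)
            out[i] = g  # doubled: both haplotypes equal the gamete
        elif method == "SSD":
            h1, h2 = parentA.copy(), parentB.copy()
            for _ in range(cfg.n_selfing_generations):
                g1 = _meiosis(h1, h2, chrom, pos, rng)
                g2 = _meiosis(h1, h2, chrom, pos, rng)
                h1, h2 = g1, g2
            out[i] = (h1 + h2) / 2.0
        else:
            raise ConfigurationError(f"unknown derivation method {method!r}")
    return out


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict, dict]:
    """Both pools of inbred lines plus family maps.

    The six families per pool are all pairwise crosses of the four
    founders (a connected half-diallel), each derived into
    ``lines_per_family`` lines by the pool's derivation method.
    Returns (genotypes, dent_family_of, flint_family_of).
    """
    founders = simulate_founder_genomes(cfg)
    chrom, pos = founders.chrom, founders.pos_cM
    rng = cfg.rng("derive")
    pairs = [
        (a, b)
        for a in range(cfg.founders_per_pool)
        for b in range(a + 1, cfg.founders_per_pool)
    ]
    if cfg.families_per_pool > len(pairs):
        raise ConfigurationError(
            f"{cfg.families_per_pool} families need at least that many founder "
            f"pairs; {cfg.founders_per_pool} founders give {len(pairs)}"
        )
    rows, line_ids, pools = [], [], []
    family_of: dict[str, dict[str, str]] = {p: {} for p in cfg.pools}
    for pool in cfg.pools:
        mask = [i for i, q in enumerate(founders.pools) if q == pool]
        method = cfg.derivation.get(pool, "DH")
        for fam_i, (a, b) in enumerate(pairs[: cfg.families_per_pool]):
            fam = f"{pool[0].upper()}fam{fam_i + 1}"
            prog = derive_family(
                founders.values[mask[a]],
                founders.values[mask[b]],
                cfg,
                cfg.lines_per_family,
                method,
                chrom,
                pos,
                rng,
            )
            for j in range(cfg.lines_per_family):
                lid = f"{fam}_L{j + 1:02d}"
                rows.append(prog[j])
                line_ids.append(lid)
                pools.append(pool)
                family_of[pool][lid] = fam
    geno = GenotypeMatrix(
        np.vstack(rows), line_ids, pools, list(founders.marker_ids), chrom, pos
    )
    return geno, family_of[cfg.pools[0]], family_of[cfg.pools[1]]


# ---------------------------------------------------------------------------
# Factorial design
# ---------------------------------------------------------------------------

def simulate_factorial(
    dent_lines: list[str],
    flint_lines: list[str],
    cfg: SimConfig,
    dent_family_of: dict | None = None,
    flint_family_of: dict | None = None,
) -> FactorialDesign:
    """Sparse random bipartite crossing design.

    Each parent is aimed at ``cfg.hybrids_per_parent`` crosses via a
    configuration-model pairing of parent slots with swap repair of
    duplicate crosses; with equal pools and a feasible degree every
    parent hits the target exactly.  Unrepairable duplicates (rare) are
    dropped, so realized degrees can dip below target; audit with
    :func:`phenoblup.design.degree_audit`.
    """
    if not dent_lines or not flint_lines:
        raise ConfigurationError("both pools must be non-empty")
    k = cfg.hybrids_per_parent
    if k > len(flint_lines) or k > len(dent_lines):
        raise ConfigurationError(
            f"hybrids_per_parent={k} exceeds the opposite pool size"
        )
    rng = cfg.rng("factorial")
    n_slots = min(len(dent_lines), len(flint_lines)) * k
    d_slots = list(np.repeat(dent_lines, k))[:n_slots]
    f_slots = list(np.repeat(flint_lines, k))[:n_slots]
    rng.shuffle(d_slots)
    rng.shuffle(f_slots)
    pairs = list(zip(d_slots, f_slots))
    # swap repair: resolve duplicate crosses by exchanging flint slots
    for _ in range(200):
        seen: dict[tuple, int] = {}
        dup = None
        for i, p in enumerate(pairs):
            if p in seen:
                dup = i
                break
            seen[p] = i
        if dup is None:
            break
        j = int(rng.integers(len(pairs)))
        a, b = pairs[dup], pairs[j]
        pairs[dup], pairs[j] = (a[0], b[1]), (b[0], a[1])
    unique_pairs = list(dict.fromkeys(pairs))
    hybrids = [
        (f"H{i + 1:04d}", d, f) for i, (d, f) in enumerate(unique_pairs)
    ]
    return FactorialDesign(
        hybrids, dict(dent_family_of or {}), dict(flint_family_of or {})
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_hybrid_phenotypes(
    design: FactorialDesign,
    geno: GenotypeMatrix,
    cfg: SimConfig,
    mu: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Hybrid adjusted means with GCA + SCA + error structure.

    Y_ij = mu + GCA_d(i) + GCA_f(j) + SCA(i,j) + e.  GCA values are
    polygenic scores (i.i.d. normal marker effects on the
    pool-centered genotypes) rescaled so their variance over the
    pool's parents equals the target exactly; SCA is drawn directly
    from N(0, K_SCA var_sca) with the genomic SCA kernel.
    Returns a long-format table (hybrid_id, trait, value) and a
    bookkeeping dict of realized components per trait in which
    the parts and twice their pairwise covariances sum exactly to the
    total phenotypic variance.
    """
    pool_of = geno.pool_of()
    missing = [
        p
        for p in design.dent_parents + design.flint_parents
        if p not in pool_of
    ]
    if missing:
        raise KeyedError(
            f"design references lines absent from genotypes: {missing[:5]}",
            keys=missing,
        )
    rng = cfg.rng("phenotypes")
    dent = geno.subset_pool(cfg.pools[0])
    flint = geno.subset_pool(cfg.pools[1])
    kd = vanraden_gca_kinship(dent)
    kf = vanraden_gca_kinship(flint)
    ksca = sca_kernel(kd, kf, design)
    # kernel-implied SCA draws need a PSD factor
    w, U = np.linalg.eigh(ksca.values)
    w = np.clip(w, 0.0, None)
    sca_factor = U * np.sqrt(w)

    def polygenic(pool_geno, target_var):
        centered = pool_geno.values - pool_geno.allele_freqs()
        alpha = rng.standard_normal(pool_geno.n_markers)
        g = centered @ alpha
        v = g.var(ddof=1)
        if target_var == 0 or v == 0:
            return dict(zip(pool_geno.line_ids, np.zeros(len(g))))
        g = g * np.sqrt(target_var / v)
        return dict(zip(pool_geno.line_ids, g - g.mean()))

    rows = []
    realized: dict[str, dict] = {}
    nh = len(design.hybrids)
    for t in range(cfg.n_traits):
        trait = f"trait{t + 1}"
        gca_d = polygenic(dent, cfg.var_gca_dent)
        gca_f = polygenic(flint, cfg.var_gca_flint)
        if cfg.var_sca > 0:
            s = np.sqrt(cfg.var_sca) * (sca_factor @ rng.standard_normal(nh))
        else:
            s = np.zeros(nh)
        e = (
            rng.standard_normal(nh) * np.sqrt(cfg.var_error)
            if cfg.var_error > 0
            else np.zeros(nh)
        )
        parts = np.column_stack(
            [
                [gca_d[d] for _, d, _ in design.hybrids],
                [gca_f[f] for _, _, f in design.hybrids],
                s,
                e,
            ]
        )
        y = mu + parts.sum(axis=1)
        cov = np.cov(parts, rowvar=False, ddof=1)
        realized[trait] = {
            "var_gca_dent": float(cov[0, 0]),
            "var_gca_flint": float(cov[1, 1]),
            "var_sca": float(cov[2, 2]),
            "var_error": float(cov[3, 3]),
            "cov_cross_terms": float(cov.sum() - np.trace(cov)),
            "var_total": float(np.var(y, ddof=1)),
        }
        for (h, _, _), val in zip(design.hybrids, y):
            rows.append({"hybrid_id": h, "trait": trait, "value": float(val)})
    return pd.DataFrame(rows), realized


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _smooth_rows(x: np.ndarray, width: int) -> np.ndarray:
    """Moving-average smoothing along the last axis (reflect padding)."""
    if width <= 1:
        return x
    kern = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    return np.apply_along_axis(lambda r: np.convolve(r, kern, "valid"), -1, xp)


def _standardize_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def simulate_spectra(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    layout: bool = False,
    spatial_sd: float = 0.5,
    n_reps: int = 2,
    tissue: str = "leaf",
) -> SpectraSet:
    """Multi-trial spectra with wavelength-varying genetic structure.

    Per wavelength ``l`` and trial ``t`` the genotype value is

        baseline(l) + sqrt(h2[l]) A[:, l] + sqrt(gxe[l]) B_t[:, l]
        + sqrt(1 - h2[l] - gxe[l]) E_t[:, l],

    where A is a polygenic score with marker loadings smooth across
    wavelengths (shared across trials: the genetic part), B_t an
    independent per-trial polygenic score (genotype x trial
    interaction) and E_t smooth correlated noise, all standardized per
    wavelength so the variance shares across genotypes match the
    profiles.  With ``layout=True`` each genotype is planted in
    ``n_reps`` plots on a row x column grid with additive random row
    and column effects of s.d. ``spatial_sd`` (state ``raw``); without
    a layout the genotype-by-trial values are returned directly (state
    ``adjusted``).
    """
    pools = set(geno.pools)
    if len(pools) != 1:
        raise StructuralError("simulate_spectra expects a single-pool genotype set")
    pool = next(iter(pools))
    L = len(cfg.wavelength_grid)
    h2, gxe = cfg.h2_profile, cfg.gxe_profile
    res = 1.0 - h2 - gxe
    rng = cfg.rng("spectra", pool, tissue)
    n = geno.n_lines
    centered = geno.values - geno.allele_freqs()

    def polygenic_matrix():
        W = _smooth_rows(rng.standard_normal((geno.n_markers, L)), cfg.smooth_window)
        return _standardize_cols(centered @ W)

    A = polygenic_matrix()
    baseline = 0.8 + 0.3 * np.sin(np.linspace(0, 3 * np.pi, L))
    vals, meta = [], []
    res_sd = np.sqrt(np.clip(res, 0, None))
    for t in range(cfg.n_trials):
        trial = f"trial{t + 1}"
        B = polygenic_matrix()
        g_t = baseline + np.sqrt(h2) * A + np.sqrt(gxe) * B
        if not layout:
            # residual share enters at the genotype-mean level
            E = _standardize_cols(
                _smooth_rows(rng.standard_normal((n, L)), cfg.smooth_window)
            )
            g_t = g_t + res_sd * E
            for i, lid in enumerate(geno.line_ids):
                vals.append(g_t[i])
                meta.append(
                    {
                        "sample_id": f"{trial}|{lid}",
                        "genotype_id": lid,
                        "pool": pool,
                        "trial_id": trial,
                        "row": np.nan,
                        "column": np.nan,
                    }
                )
            continue
        n_plots = n * n_reps
        ncol = int(np.ceil(np.sqrt(n_plots)))
        nrow = int(np.ceil(n_plots / ncol))
        row_eff = rng.normal(0, spatial_sd, nrow)
        col_eff = rng.normal(0, spatial_sd, ncol)
        order = rng.permutation(np.repeat(np.arange(n), n_reps))
        # residual share enters per plot so replicates genuinely differ
        E_plot = _standardize_cols(
            _smooth_rows(rng.standard_normal((len(order), L)), cfg.smooth_window)
        )
        for p, gi in enumerate(order):
            r, c = divmod(p, ncol)
            lid = geno.line_ids[gi]
            vals.append(g_t[gi] + row_eff[r] + col_eff[c] + res_sd * E_plot[p])
            meta.append(
                {
                    "sample_id": f"{trial}|{lid}|p{p}",
                    "genotype_id": lid,
                    "pool": pool,
                    "trial_id": trial,
                    "row": r,
                    "column": c,
                }
            )
    return SpectraSet(
        cfg.wavelength_grid,
        np.vstack(vals),
        pd.DataFrame(meta),
        state="raw" if layout else "adjusted",
    )
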