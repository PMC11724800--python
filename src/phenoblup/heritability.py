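"""Per-wavelength genomic variance decomposition of spectra.

For every wavelength the absorbance across genotypes is treated as a
polygenic trait.  With two trials a bivariate model with genomic kernel
K is fitted and its components mapped to across-trial genetic,
genotype-by-environment and residual variances (Yamada decomposition);
with a single trial a univariate G-BLUP model gives genomic
heritability and no G x E term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError
from .kernels import KernelMatrix
from .reml import (
    RandomEffect,
    fit_bivariate,
    fit_reml,
    yamada_decomposition,
)
from .spectra import SpectraSet

COLUMNS = [
    "wavelength",
    "sigma2_G",
    "sigma2_GxE",
    "sigma2_e",
    "prop_G",
    "prop_GxE",
    "prop_e",
    "converged",
]


@dataclass
class HeritabilityScan:
    """Wavelength-wise variance components and proportions."""

    table: pd.DataFrame  # COLUMNS
    model: str  # bivariate | univariate
    pool: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise StructuralError(f"scan table lacks columns {missing}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.table["wavelength"].to_numpy()


def _scan_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=COLUMNS)


def scan_bivariate(
    s1: SpectraSet, s2: SpectraSet, K: KernelMatrix, pool: str = "", tissue: str = ""
) -> HeritabilityScan:
    """Two-trial decomposition at every common wavelength.

    Both inputs must be adjusted per-genotype spectra on the same grid.
    Wavelengths where the bivariate REML does not converge are flagged
    (``converged = False``) with missing components, never fabricated.
    """
    s1.require_state("adjusted", "normalized")
    s2.require_state("adjusted", "normalized")
    if len(s1.wavelengths) != len(s2.wavelengths) or not np.allclose(
        s1.wavelengths, s2.wavelengths
    ):
        raise StructuralError("trials are not on a common wavelength grid")
    g1 = list(s1.meta["genotype_id"])
    g2 = list(s2.meta["genotype_id"])
    if not set(g1) & set(g2):
        raise StructuralError("disjoint genotype sets between trials")
    rows = []
    for j, wl in enumerate(s1.wavelengths):
        try:
            comp = fit_bivariate(s1.values[:, j], s2.values[:, j], g1, g2, K)
            dec = yamada_decomposition(comp)
            rows.append(
                [wl, dec["sigma2_G"], dec["sigma2_GxE"], dec["sigma2_e"],
                 dec["prop_G"], dec["prop_GxE"], dec["prop_e"], comp.converged]
            )
        except Exception:
            rows.append([wl, *([np.nan] * 6), False])
    return HeritabilityScan(_scan_table(rows), "bivariate", pool, tissue)


def scan_univariate(
    s: SpectraSet, K: KernelMatrix, pool: str = "", tissue: str = ""
) -> HeritabilityScan:
    """Single-trial genomic heritability per wavelength.

    Genomic heritability is sigma2_g / (sigma2_g + sigma2_e); the G x E
    component is not estimable from one trial and is reported missing.
    """
    s.require_state("adjusted", "normalized")
    geno = list(s.meta["genotype_id"])
    if len(set(geno)) < 10:
        raise ConfigurationError(
            f"only {len(set(geno))} genotypes; univariate scans need >= 10"
        )
    rows = []
    for j, wl in enumerate(s.wavelengths):
        try:
            fm = fit_reml(
                s.values[:, j], [RandomEffect("genotype", geno, K)]
            )
            s2g, s2e = fm.varcomp["genotype"], fm.varcomp["residual"]
            tot = s2g + s2e
            h2 = s2g / tot if tot > 0 else np.nan
            rows.append([wl, s2g, np.nan, s2e, h2, np.nan, 1 - h2, fm.converged])
        except Exception:
            rows.append([wl, *([np.nan] * 6), False])
    return HeritabilityScan(_scan_table(rows), "univariate", pool, tissue)


def summarize_scan(
    h: HeritabilityScan, bands: list[tuple[float, float]] | None = None
) -> dict:
    """Averages, ranges and optional per-band means of the proportions.

    Averages are over converged wavelengths only, with the count shown.
    """
    t = h.table
    ok = t[t["converged"].astype(bool)]
    if len(t) == 0:
        raise StructuralError("empty scan")
    out = {
        "model": h.model,
        "n_wavelengths": len(t),
        "n_converged": int(len(ok)),
    }
    for c in ("prop_G", "prop_GxE", "prop_e"):
        vals = ok[c].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        out[f"mean_{c}"] = float(vals.mean()) if vals.size else np.nan
        out[f"min_{c}"] = float(vals.min()) if vals.size else np.nan
        out[f"max_{c}"] = float(vals.max()) if vals.size else np.nan
    if bands:
        out["bands"] = []
        for lo, hi in bands:
            sel = ok[(ok["wavelength"] >= lo) & (ok["wavelength"] <= hi)]
            out["bands"].append(
                {
                    "band": (lo, hi),
                    "mean_prop_G": float(sel["prop_G"].mean()),
                    "mean_prop_GxE": float(sel["prop_GxE"].mean()),
                    "n": int(len(sel)),
                }
            )
    return out


def plot_scan(h: HeritabilityScan, ax=None, path: str | None = None):
    """Stacked genetic / GxE / residual proportion bands along the grid."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = h.table[h.table["converged"].astype(bool)]
    wl = t["wavelength"]
    g = np.clip(t["prop_G"].to_numpy(float), 0, 1)
    gxe = np.nan_to_num(np.clip(t["prop_GxE"].to_numpy(float), 0, 1))
    ax.stackplot(
        wl, g, gxe, np.clip(1 - g - gxe, 0, 1),
        labels=["genetic", "G x E", "residual"],
        colors=["tab:red", "tab:green", "tab:blue"],
        alpha=0.8,
    )
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("variance proportion")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
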