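"""NIR spectra containers and pretreatment.

The pretreatment chain turns raw replicated field spectra into the
per-genotype matrix the H relationship kernel is built from:

    raw -> (average technical replicates) -> adjusted per-genotype
    means from a wavelength-wise spatial mixed model -> per-spectrum
    normalization (SNV) -> Savitzky-Golay first derivative.

State tags enforce the order; out-of-order calls raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .errors import ConfigurationError, StructuralError
from .reml import RandomEffect, fit_reml

STATES = ("raw", "averaged", "adjusted", "normalized", "derivative")
META_COLUMNS = ("sample_id", "genotype_id", "pool", "trial_id", "row", "column")


@dataclass
class SpectraSet:
    """Samples x wavelengths absorbance with per-sample metadata.

    ``meta`` carries sample_id, genotype_id, pool, trial_id and (for
    field data) row/column plot coordinates; ``state`` records the
    pretreatment stage reached.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in STATES:
            raise StructuralError(f"unknown state {self.state!r}; one of {STATES}")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise StructuralError("wavelengths must be strictly increasing")
        if self.values.shape != (len(self.meta), len(self.wavelengths)):
            raise StructuralError(
                f"spectra shape {self.values.shape} does not match "
                f"{len(self.meta)} samples x {len(self.wavelengths)} wavelengths"
            )
        if np.isnan(self.values).any():
            raise StructuralError("missing absorbance values are not allowed")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StructuralError(
                f"operation requires state in {allowed}, got {self.state!r}"
            )

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return replace(
            self, values=self.values[mask], meta=self.meta.loc[mask].reset_index(drop=True)
        )

    def is_uniform_grid(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=rtol))

    def resample_uniform(self, step: float | None = None) -> "SpectraSet":
        """Linear interpolation onto a uniform grid (for SG filtering)."""
        w = self.wavelengths
        step = step or float(np.min(np.diff(w)))
        grid = np.arange(w[0], w[-1] + step / 2, step)
        vals = np.vstack([np.interp(grid, w, row) for row in self.values])
        return replace(self, wavelengths=grid, values=vals)


@dataclass
class WavelengthH2:
    """Per-wavelength broad-sense heritability (repeatability)."""

    wavelengths: np.ndarray
    h2: np.ndarray  # NaN where not identifiable

    def __post_init__(self) -> None:
        ok = self.h2[~np.isnan(self.h2)]
        if ok.size and (np.any(ok < -1e-9) or np.any(ok > 1 + 1e-9)):
            raise StructuralError("heritability out of [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength": self.wavelengths, "H2": self.h2})


def average_technical_replicates(s: SpectraSet) -> SpectraSet:
    """Mean of the technical spectra within each microplot.

    Plots are identified by (trial_id, genotype_id, row, column).
    """
    s.require_state("raw")
    keys = ["trial_id", "genotype_id", "row", "column"]
    groups = s.meta.groupby(keys, sort=False, dropna=False).indices
    metas, rows = [], []
    for key, idx in groups.items():
        if len(idx) == 0:
            raise StructuralError(f"plot {key} has no spectra")
        rows.append(s.values[idx].mean(axis=0))
        rec = s.meta.iloc[idx[0]].copy()
        rec["sample_id"] = "|".join(str(k) for k in key)
        metas.append(rec)
    return SpectraSet(
        s.wavelengths, np.vstack(rows), pd.DataFrame(metas), state="averaged"
    )


def _fit_wavelength(y, geno, row, col, genotype_as):
    """One wavelength: y = genotype + row + column + error."""
    spatial = [
        RandomEffect("row", list(row)),
        RandomEffect("column", list(col)),
    ]
    glevels = list(geno)
    guniq = list(dict.fromkeys(glevels))
    if genotype_as == "fixed":
        X = np.array([[1.0 if g == u else 0.0 for u in guniq] for g in glevels])
        fm = fit_reml(y, spatial, X=X)
        return dict(zip(guniq, fm.beta.astype(float))), None
    fm = fit_reml(y, [RandomEffect("genotype", glevels)] + spatial)
    s2g = fm.varcomp["genotype"]
    s2e = fm.varcomp["residual"]
    nrep = len(glevels) / len(guniq)
    h2 = s2g / (s2g + s2e / nrep) if (s2g + s2e) > 0 else np.nan
    return None, min(max(h2, 0.0), 1.0)


def adjust_wavelength_means(
    s: SpectraSet, genotype_as: str = "fixed"
) -> tuple[SpectraSet, WavelengthH2]:
    """Spatially adjusted genotype means and heritability per wavelength.

    For each trial and wavelength a mixed model with random row and
    column effects is fitted twice: genotype fixed (adjusted marginal
    means, returned as the new spectra) and genotype random
    (broad-sense heritability sigma2_g / (sigma2_g + sigma2_e/n_rep)).
    With a fully unreplicated trial the genotype-random model is not
    identifiable; heritability is then reported missing with a warning.

    ``genotype_as`` selects which of the two outputs drives the
    returned spectra when you only need one fit; both are computed by
    default semantics ("fixed" means: adjusted means from the fixed
    fit, heritability still from the random fit).
    """
    s.require_state("raw", "averaged")
    for c in ("row", "column", "genotype_id", "trial_id"):
        if c not in s.meta.columns or s.meta[c].isna().any():
            raise StructuralError(f"metadata column {c!r} missing or incomplete")
    if genotype_as not in ("fixed", "random"):
        raise ConfigurationError("genotype_as must be 'fixed' or 'random'")

    out_vals, out_meta = [], []
    h2_by_trial = []
    for trial, tm in s.meta.groupby("trial_id", sort=False):
        idx = tm.index.to_numpy()
        geno = tm["genotype_id"].to_numpy()
        row = tm["row"].to_numpy()
        col = tm["column"].to_numpy()
        guniq = list(dict.fromkeys(geno))
        replicated = len(geno) > len(guniq)
        h2 = np.full(len(s.wavelengths), np.nan)
        means = {g: np.empty(len(s.wavelengths)) for g in guniq}
        if not replicated:
            # saturated design: one plot per genotype leaves nothing to
            # separate genotype from plot, so pass observations through
            warnings.warn(
                f"trial {trial!r} is unreplicated; spatial adjustment and "
                "broad-sense heritability are not identifiable (means passed "
                "through, heritability reported missing)",
                stacklevel=2,
            )
            for g, i in zip(geno, idx):
                means[g] = s.values[i].copy()
        else:
            for j in range(len(s.wavelengths)):
                y = s.values[idx, j]
                adj, _ = _fit_wavelength(y, geno, row, col, "fixed")
                for g in guniq:
                    means[g][j] = adj[g]
                _, h2[j] = _fit_wavelength(y, geno, row, col, "random")
        h2_by_trial.append(h2)
        pool = tm["pool"].iloc[0] if "pool" in tm else ""
        for g in guniq:
            out_vals.append(means[g])
            out_meta.append(
                {
                    "sample_id": f"{trial}|{g}",
                    "genotype_id": g,
                    "pool": pool,
                    "trial_id": trial,
                    "row": np.nan,
                    "column": np.nan,
                }
            )
    adjusted = SpectraSet(
        s.wavelengths, np.vstack(out_vals), pd.DataFrame(out_meta), state="adjusted"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN wavelengths
        h2 = WavelengthH2(s.wavelengths, np.nanmean(np.vstack(h2_by_trial), axis=0))
    return adjusted, h2


def normalize(s: SpectraSet) -> SpectraSet:
    """Standard-normal-variate: each spectrum centered and scaled.

    Every row ends with mean 0 and (sample) standard deviation 1.
    """
    s.require_state("adjusted")
    sd = s.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        i = int(np.where(sd == 0)[0][0])
        gid = s.meta["genotype_id"].iloc[i]
        raise StructuralError(
            f"constant spectrum for genotype {gid!r}; cannot normalize"
        )
    vals = (s.values - s.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(s, values=vals, state="normalized")


def savitzky_golay_first_derivative(
    s: SpectraSet, window: int = 37, polyorder: int = 2
) -> SpectraSet:
    """Savitzky-Golay first derivative per spectrum.

    A local least-squares polynomial of order ``polyorder`` is fitted
    in a sliding window of ``window`` points; its slope at the window
    center is the derivative.  Edge points where the full window does
    not fit are dropped, so the wavelength grid shrinks by
    ``window - 1`` points.  Requires a uniform grid (resample first via
    :meth:`SpectraSet.resample_uniform` if the instrument grid is not).
    """
    s.require_state("normalized")
    if window % 2 == 0 or window <= polyorder:
        raise ConfigurationError(
            f"window must be odd and > polyorder; got window={window}, "
            f"polyorder={polyorder}"
        )
    if window >= len(s.wavelengths):
        raise ConfigurationError(
            f"window {window} >= {len(s.wavelengths)} wavelengths"
        )
    if not s.is_uniform_grid():
        raise StructuralError(
            "wavelength grid is not uniform; resample to a uniform grid "
            "(SpectraSet.resample_uniform) before the SG derivative"
        )
    delta = float(s.wavelengths[1] - s.wavelengths[0])
    # convolution kernel; np.convolve flips it, matching scipy's 'use=conv'
    coeffs = savgol_coeffs(window, polyorder, deriv=1, delta=delta, use="conv")
    vals = np.vstack([np.convolve(row, coeffs, mode="valid") for row in s.values])
    half = window // 2
    return SpectraSet(
        s.wavelengths[half:-half], vals, s.meta.copy(), state="derivative"
    )


def pretreat(
    s: SpectraSet, window: int = 37, polyorder: int = 2, genotype_as: str = "fixed"
) -> tuple[SpectraSet, WavelengthH2]:
    """Full chain: replicate averaging, spatial adjustment, SNV, SG."""
    if s.state == "raw":
        s = average_technical_replicates(s)
    if s.state in ("averaged",):
        s, h2 = adjust_wavelength_means(s, genotype_as=genotype_as)
    else:
        h2 = WavelengthH2(s.wavelengths, np.full(len(s.wavelengths), np.nan))
    if not s.is_uniform_grid():
        s = s.resample_uniform()
    s = normalize(s)
    s = savitzky_golay_first_derivative(s, window=window, polyorder=polyorder)
    return s, h2
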