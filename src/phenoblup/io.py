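"""Readers and writers for the package's plain-text formats.

All dialects are CSV with mandatory headers.  Readers validate and
reject malformed input rather than coercing it; writers emit JSON
sidecars carrying provenance (state, source/role/scale flags, config
hash, seed) next to the data files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import FactorialDesign
from .errors import KeyedError, StructuralError
from .kernels import GenotypeMatrix, KernelMatrix, VALID_CALLS
from .spectra import META_COLUMNS, SpectraSet

_MISSING = {"", "NA", "NaN", "nan"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_sidecar(path, **meta) -> None:
    payload = {k: v for k, v in meta.items() if v is not None}
    _sidecar(Path(path)).write_text(json.dumps(payload, indent=1, default=str))


def read_sidecar(path) -> dict:
    p = _sidecar(Path(path))
    return json.loads(p.read_text()) if p.exists() else {}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.values, columns=g.marker_ids)
    df.insert(0, "pool", g.pools)
    df.insert(0, "line_id", g.line_ids)
    df.to_csv(path, index=False, na_rep="NA")
    write_sidecar(path, kind="genotypes", n_lines=g.n_lines, n_markers=g.n_markers)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("line_id", "pool"):
        if col not in df.columns:
            raise StructuralError(f"genotype CSV lacks required column {col!r}")
    marker_ids = [c for c in df.columns if c not in ("line_id", "pool")]
    vals = np.empty((len(df), len(marker_ids)))
    for j, m in enumerate(marker_ids):
        col = df[m].str.strip()
        for i, cell in enumerate(col):
            if cell in _MISSING:
                vals[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                v = None
            if v is None or v not in VALID_CALLS:
                raise StructuralError(
                    f"invalid genotype call {cell!r} at line "
                    f"{df['line_id'].iloc[i]!r}, marker {m!r}"
                )
            vals[i, j] = v
    return GenotypeMatrix(
        vals, list(df["line_id"]), list(df["pool"]), marker_ids
    )


def read_genotypes_vcf(path, pool_of: dict[str, str]) -> GenotypeMatrix:
    """Collapse biallelic VCF genotypes to the {0, 0.5, 1} coding.

    0/0 -> 0, 0/1 -> 0.5, 1/1 -> 1 (reference-allele-count halved);
    missing calls become NaN.  ``pool_of`` assigns each VCF sample to a
    heterotic pool.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pool_of]
    if missing:
        raise KeyedError(f"samples without pool label: {missing[:5]}", keys=missing)
    cols, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise StructuralError(
                f"marker {var.ID or var.POS} is not biallelic"
            )
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, 1.0, np.where(gt == 1, 0.5, np.where(gt == 3, 0.0, np.nan)))
        cols.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vals = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(
        vals, samples, [pool_of[s] for s in samples], ids
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectra(s: SpectraSet, path) -> None:
    df = pd.concat(
        [
            s.meta[list(META_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(s.values, columns=[f"{w:.10g}" for w in s.wavelengths]),
        ],
        axis=1,
    )
    df.to_csv(path, index=False)
    write_sidecar(path, kind="spectra", state=s.state, n_samples=s.n_samples)


def read_spectra(path, state: str | None = None) -> SpectraSet:
    df = pd.read_csv(path)
    meta_cols, wl_cols = [], []
    for c in df.columns:
        try:
            float(c)
            wl_cols.append(c)
        except ValueError:
            meta_cols.append(c)
    required = set(META_COLUMNS) - {"row", "column"}
    missing = required - set(meta_cols)
    if missing:
        raise StructuralError(f"spectra CSV lacks metadata columns {sorted(missing)}")
    for c in ("row", "column"):
        if c not in df.columns:
            df[c] = np.nan
    wl = np.array([float(c) for c in wl_cols])
    order = np.argsort(wl)
    vals = df[wl_cols].to_numpy(float)[:, order]
    state = state or read_sidecar(path).get("state", "raw")
    return SpectraSet(wl[order], vals, df[list(META_COLUMNS)], state=state)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def write_kernel(k: KernelMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.ids, columns=k.ids).to_csv(path)
    write_sidecar(
        path, kind="kernel", source=k.source, role=k.role, scaled=k.scaled,
        jitter=k.jitter,
    )


def read_kernel(path, source: str | None = None, role: str | None = None) -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise StructuralError("kernel row and column ids differ")
    vals = df.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-8, rtol=0.0):
        raise StructuralError("kernel asymmetric beyond 1e-8; rejected")
    side = read_sidecar(path)
    return KernelMatrix(
        (vals + vals.T) / 2.0,
        ids,
        source or side.get("source", "unknown"),
        role or side.get("role", "unknown"),
        scaled=bool(side.get("scaled", False)),
        jitter=float(side.get("jitter", 0.0)),
    )


# ---------------------------------------------------------------------------
# Design & phenotypes
# ---------------------------------------------------------------------------

def write_design(d: FactorialDesign, path) -> None:
    d.to_frame().to_csv(path, index=False)
    write_sidecar(path, kind="design", n_hybrids=len(d.hybrids))


def read_design(path) -> FactorialDesign:
    df = pd.read_csv(path, dtype=str)
    for col in ("hybrid_id", "dent_parent", "flint_parent"):
        if col not in df.columns:
            raise StructuralError(f"design CSV lacks column {col!r}")
    hybrids = list(
        df[["hybrid_id", "dent_parent", "flint_parent"]].itertuples(
            index=False, name=None
        )
    )
    dfam = ffam = {}
    if "dent_family" in df.columns and "flint_family" in df.columns:
        dfam = dict(zip(df["dent_parent"], df["dent_family"]))
        ffam = dict(zip(df["flint_parent"], df["flint_family"]))
    return FactorialDesign(hybrids, dfam, ffam)


def write_phenotypes(ph: pd.DataFrame, path) -> None:
    ph.to_csv(path, index=False)
    write_sidecar(path, kind="phenotypes", n_rows=len(ph))


def read_phenotypes(path, design: FactorialDesign | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("hybrid_id", "trait", "value"):
        if col not in df.columns:
            raise StructuralError(f"phenotype CSV lacks column {col!r}")
    if df.duplicated(["hybrid_id", "trait"]).any():
        raise StructuralError("duplicate (hybrid, trait) phenotype rows")
    if design is not None:
        unknown = sorted(set(df["hybrid_id"]) - set(design.hybrid_ids))
        if unknown:
            raise KeyedError(
                f"phenotypes reference unknown hybrids: {unknown[:5]}", keys=unknown
            )
    return df


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise StructuralError(f"config {path} is not a mapping")
    return cfg
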