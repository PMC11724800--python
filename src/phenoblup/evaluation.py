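"""Model catalog, cross-validation scenarios, and predictive ability.

Two scenarios are implemented:

* ``CV_SparseTesting`` — plain k-fold cross-validation over hybrids,
  repeated with reshuffles, ignoring family structure.
* ``CV_newDentFlint`` — for each (dent family, flint family) pair, the
  predicted set is the hybrids whose two parents are in those families
  and the calibration set excludes every hybrid with a parent in
  either family, so predicted hybrids are genetically new on both
  sides.  Only partitions with enough predicted hybrids are kept.

All models are evaluated on byte-identical partitions; predictive
ability is the Pearson correlation between predictions and observed
adjusted means per fold, reported missing (with the reason) when
predictions are constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import FactorialDesign
from .errors import ConfigurationError, ConvergenceError, KeyedError, StructuralError
from .kernels import KernelMatrix
from .reml import RandomEffect, fit_reml, predict

ROLES = ("gca_dent", "gca_flint", "sca")


@dataclass
class CVPartition:
    scenario: str
    partition_id: str
    repeat: int
    train_ids: tuple[str, ...]
    pred_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.pred_ids):
            raise StructuralError(
                f"partition {self.partition_id}: train and predicted sets overlap"
            )


@dataclass
class ModelCatalogEntry:
    """A named BLUP model: which kernel set supplies which random effects.

    ``effects`` lists (role, kernel_source_key) pairs; the kernel
    bundle maps source keys (e.g. ``"genomic"``, ``"leaf_plou"``) to a
    dict with keys among ``gca_dent``, ``gca_flint``, ``sca``.
    Sources with a missing pool contribute only the roles they have
    (e.g. a silage source without flint spectra yields a single dent
    GCA effect).
    """

    name: str
    effects: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for role, _ in self.effects:
            if role not in ROLES:
                raise ConfigurationError(f"unknown kernel role {role!r}")


def standard_model_catalog(
    bundle: dict[str, dict[str, KernelMatrix]],
    combine: dict[str, list[str]] | None = None,
) -> list[ModelCatalogEntry]:
    """Build the usual model set from a kernel bundle.

    One model per source (P-BLUP for ``pedigree``, G-BLUP for
    ``genomic``, ``H.<SOURCE>`` for each spectral source), using every
    role the source provides; plus combined models pooling the effects
    of several spectral sources, given as ``combine`` (name -> list of
    source keys).
    """
    catalog = []
    named = {"pedigree": "P-BLUP", "genomic": "G-BLUP"}
    for key, kset in bundle.items():
        name = named.get(key, f"H.{key.upper()}")
        effects = [(role, key) for role in ROLES if role in kset]
        if effects:
            catalog.append(ModelCatalogEntry(name, effects))
    for name, keys in (combine or {}).items():
        effects = []
        for key in keys:
            effects += [(role, key) for role in ROLES if role in bundle.get(key, {})]
        catalog.append(ModelCatalogEntry(name, effects))
    names = [m.name for m in catalog]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate model names in catalog: {names}")
    return catalog


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def make_cv_sparse(
    design: FactorialDesign, k: int = 5, reps: int = 5, seed: int = 0
) -> list[CVPartition]:
    """Random k-fold partitions of the hybrids, repeated ``reps`` times.

    Fold sizes differ by at most one; after a seeded shuffle the
    remainder hybrids go to the lowest-index folds.
    """
    ids = list(design.hybrid_ids)
    n = len(ids)
    if k > n:
        raise ConfigurationError(f"k={k} folds but only {n} hybrids")
    rng = np.random.default_rng([int(seed) % (2**31), 0x5FA12])
    parts = []
    for rep in range(reps):
        order = [ids[i] for i in rng.permutation(n)]
        base, extra = divmod(n, k)
        folds, start = [], 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            folds.append(order[start : start + size])
            start += size
        for f, fold in enumerate(folds):
            train = [h for h in order if h not in set(fold)]
            parts.append(
                CVPartition(
                    "CV_SparseTesting",
                    f"rep{rep + 1}_fold{f + 1}",
                    rep + 1,
                    tuple(train),
                    tuple(fold),
                )
            )
    return parts


def make_cv_new_dent_flint(
    design: FactorialDesign, min_predicted: int = 10
) -> list[CVPartition]:
    """Across-family partitions: both parents of predicted hybrids new.

    For each (dent family D, flint family F) pair, predicted = hybrids
    with dent parent in D and flint parent in F; calibration = hybrids
    whose dent parent is not in D *and* flint parent is not in F.
    Pairs with fewer than ``min_predicted`` predicted hybrids are
    dropped.
    """
    if not design.dent_family_of or not design.flint_family_of:
        raise StructuralError("family maps are required for CV_newDentFlint")
    dfam = design.dent_family_of
    ffam = design.flint_family_of
    d_families = sorted(set(dfam.values()))
    f_families = sorted(set(ffam.values()))
    if len(d_families) < 2 or len(f_families) < 2:
        import warnings

        warnings.warn(
            "fewer than two families in a pool: no across-family partition "
            "leaves anything to train on",
            stacklevel=2,
        )
        return []
    parts = []
    for D in d_families:
        for F in f_families:
            pred = [
                h for h, d, f in design.hybrids if dfam[d] == D and ffam[f] == F
            ]
            if len(pred) < min_predicted:
                continue
            train = [
                h for h, d, f in design.hybrids if dfam[d] != D and ffam[f] != F
            ]
            if not train:
                continue
            parts.append(
                CVPartition(
                    "CV_newDentFlint", f"{D}x{F}", 1, tuple(train), tuple(pred)
                )
            )
    return parts


# ---------------------------------------------------------------------------
# Predictive ability
# ---------------------------------------------------------------------------

def predictive_ability(pred, obs) -> float:
    """Pearson correlation between predictions and observed means.

    Returns NaN (undefined, e.g. constant predictions) rather than
    coercing to 0; raises on fewer than 3 pairs.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise StructuralError("prediction/observation length mismatch")
    if len(pred) < 3:
        raise ConfigurationError("need at least 3 pairs for a correlation")
    # constant up to numerical noise (e.g. equal relationship to all
    # training hybrids): the correlation is undefined, not ~noise
    def _constant(x):
        return np.ptp(x) <= 1e-6 * max(1.0, float(np.max(np.abs(x))))

    if _constant(pred) or _constant(obs):
        return np.nan
    return float(stats.pearsonr(pred, obs).statistic)


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

def _model_effects(
    entry: ModelCatalogEntry,
    bundle: dict[str, dict[str, KernelMatrix]],
    design: FactorialDesign,
    hybrid_ids: list[str],
) -> list[RandomEffect]:
    parents = {h: (d, f) for h, d, f in design.hybrids}
    effects = []
    for role, key in entry.effects:
        if key not in bundle or role not in bundle[key]:
            raise KeyedError(
                f"model {entry.name!r} needs kernel ({role}, {key}) missing "
                "from the bundle",
                keys=[(role, key)],
            )
        kern = bundle[key][role]
        if role == "gca_dent":
            levels = [parents[h][0] for h in hybrid_ids]
        elif role == "gca_flint":
            levels = [parents[h][1] for h in hybrid_ids]
        else:
            levels = list(hybrid_ids)
        effects.append(RandomEffect(f"{role}:{key}", levels, kern))
    return effects


def run_scenario(
    catalog: list[ModelCatalogEntry],
    partitions: list[CVPartition],
    design: FactorialDesign,
    phenotypes: pd.DataFrame,
    bundle: dict[str, dict[str, KernelMatrix]],
) -> pd.DataFrame:
    """Fit every model on every partition and score predictions.

    ``phenotypes`` is long-format (hybrid_id, trait, value).  Returns
    one row per (trait, model, partition) with the realized predictive
    ability; fit failures are recorded per cell and the run continues.
    The partition membership is logged per row so reuse across models
    is auditable.
    """
    if not partitions:
        raise ConfigurationError("no partitions to evaluate")
    ph = phenotypes.pivot(index="hybrid_id", columns="trait", values="value")
    missing = set(design.hybrid_ids) - set(ph.index)
    if missing:
        raise KeyedError(
            f"hybrids without phenotype: {sorted(missing)[:5]}", keys=sorted(missing)
        )
    rows = []
    for trait in ph.columns:
        y_all = ph[trait]
        for part in partitions:
            train = list(part.train_ids)
            pred_ids = list(part.pred_ids)
            y_train = y_all.loc[train].to_numpy(float)
            for entry in catalog:
                rec = {
                    "trait": trait,
                    "model": entry.name,
                    "scenario": part.scenario,
                    "partition": part.partition_id,
                    "repeat": part.repeat,
                    "n_train": len(train),
                    "n_pred": len(pred_ids),
                    "ability": np.nan,
                    "converged": False,
                    "note": "",
                    "partition_hash": hash((part.train_ids, part.pred_ids)),
                }
                try:
                    effects = _model_effects(entry, bundle, design, train)
                    fm = fit_reml(y_train, effects)
                    new_levels = {
                        e.name: lv
                        for e, lv in zip(
                            effects,
                            (
                                _new_levels(role, design, pred_ids)
                                for role, _ in entry.effects
                            ),
                        )
                    }
                    yhat = predict(fm, new_levels)
                    ab = predictive_ability(yhat, y_all.loc[pred_ids].to_numpy(float))
                    rec["ability"] = ab
                    rec["converged"] = fm.converged
                    if np.isnan(ab):
                        rec["note"] = "undefined: constant predictions"
                except ConvergenceError as err:
                    rec["note"] = f"fit failed: {err}"
                except (KeyedError, StructuralError) as err:
                    rec["note"] = f"error: {err}"
                rows.append(rec)
    return pd.DataFrame(rows)


def _new_levels(role: str, design: FactorialDesign, hybrid_ids: list[str]):
    parents = {h: (d, f) for h, d, f in design.hybrids}
    if role == "gca_dent":
        return [parents[h][0] for h in hybrid_ids]
    if role == "gca_flint":
        return [parents[h][1] for h in hybrid_ids]
    return list(hybrid_ids)


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/median ability per (trait, model, scenario) over defined folds."""
    def agg(g):
        vals = g["ability"].dropna()
        return pd.Series(
            {
                "mean_ability": vals.mean() if len(vals) else np.nan,
                "median_ability": vals.median() if len(vals) else np.nan,
                "n_folds": len(g),
                "n_defined": len(vals),
            }
        )

    return (
        results.groupby(["trait", "model", "scenario"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
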