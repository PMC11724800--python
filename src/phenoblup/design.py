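"""Sparse factorial crossing designs between two heterotic pools.

A :class:`FactorialDesign` records which dent line was crossed to which
flint line to produce each hybrid, together with the biparental family
each parental line belongs to.  Family membership drives the
across-family cross-validation scenario and the pedigree kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import KeyedError, StructuralError


@dataclass
class FactorialDesign:
    """Bipartite list of dent x flint crosses with family maps.

    Parameters
    ----------
    hybrids:
        List of ``(hybrid_id, dent_line_id, flint_line_id)`` tuples.
    dent_family_of, flint_family_of:
        Maps from parental line id to its biparental family label.
    """

    hybrids: list[tuple[str, str, str]]
    dent_family_of: dict[str, str] = field(default_factory=dict)
    flint_family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(d, f) for _, d, f in self.hybrids]
        if len(set(pairs)) != len(pairs):
            raise StructuralError("duplicate dent x flint cross in design")
        ids = [h for h, _, _ in self.hybrids]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate hybrid id in design")
        dents = {d for _, d, _ in self.hybrids}
        flints = {f for _, _, f in self.hybrids}
        if dents & flints:
            raise StructuralError(
                f"dent and flint line ids overlap: {sorted(dents & flints)[:5]}"
            )
        if self.dent_family_of or self.flint_family_of:
            missing = sorted(dents - set(self.dent_family_of)) + sorted(
                flints - set(self.flint_family_of)
            )
            if missing:
                raise KeyedError(
                    f"lines with no family assignment: {missing[:5]}", keys=missing
                )

    # -- accessors -------------------------------------------------------
    @property
    def hybrid_ids(self) -> list[str]:
        return [h for h, _, _ in self.hybrids]

    @property
    def dent_parents(self) -> list[str]:
        """Distinct dent parents, in order of first appearance."""
        return list(dict.fromkeys(d for _, d, _ in self.hybrids))

    @property
    def flint_parents(self) -> list[str]:
        return list(dict.fromkeys(f for _, _, f in self.hybrids))

    def parents_of(self, hybrid_id: str) -> tuple[str, str]:
        for h, d, f in self.hybrids:
            if h == hybrid_id:
                return d, f
        raise KeyedError(f"unknown hybrid {hybrid_id!r}", keys=[hybrid_id])

    def subset(self, hybrid_ids) -> "FactorialDesign":
        keep = set(hybrid_ids)
        unknown = keep - set(self.hybrid_ids)
        if unknown:
            raise KeyedError(
                f"unknown hybrids {sorted(unknown)[:5]}", keys=sorted(unknown)
            )
        return FactorialDesign(
            [t for t in self.hybrids if t[0] in keep],
            dict(self.dent_family_of),
            dict(self.flint_family_of),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.hybrids, columns=["hybrid_id", "dent_parent", "flint_parent"]
        )
        if self.dent_family_of:
            df["dent_family"] = df["dent_parent"].map(self.dent_family_of)
            df["flint_family"] = df["flint_parent"].map(self.flint_family_of)
        return df


def degree_audit(design: FactorialDesign) -> pd.DataFrame:
    """Per-parent cross counts (the realized degree sequence)."""
    df = design.to_frame()
    rows = []
    for pool, col in (("dent", "dent_parent"), ("flint", "flint_parent")):
        for line, n in df[col].value_counts().items():
            rows.append({"line_id": line, "pool": pool, "degree": int(n)})
    return pd.DataFrame(rows)
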