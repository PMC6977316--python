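"""Scaffold-library diagnostics: database coverage and the class-assignment
heat map, the two quantities used to choose which scaffold levels to keep.

Coverage of a database Y at level m is the fraction of its compounds
matched (aromatic-strict substructure) by at least one level-m scaffold of
any class; a compound matching several classes is counted in exactly one,
chosen as the class whose matched scaffold has the most rings (ties broken
by library class order).  The heat map instead multi-assigns: a compound of
true class i contributes to P[i, j] for every class j whose level-m
scaffolds match it, so the matrix is generally asymmetric and rows need
not sum to 1; the ideal is identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem

from .chem import CompoundRecord, match_substructure, preprocess
from .scaffold import ScaffoldLibrary

logger = logging.getLogger(__name__)


@dataclass
class CoverageTable:
    """Coverage of one compound set at one scaffold level."""

    level: int
    n_compounds: int
    matched_per_class: dict[str, int]
    per_class_fraction: dict[str, float] = field(init=False)
    coverage: float = field(init=False)

    def __post_init__(self):
        self.per_class_fraction = {
            cls: n / self.n_compounds for cls, n in self.matched_per_class.items()
        }
        self.coverage = sum(self.per_class_fraction.values())


@dataclass
class HeatMap:
    """Class-assignment proportions at one level, true class i in rows,
    assigned class j in columns."""

    level: int
    matrix: pd.DataFrame  # P[i, j], floats in [0, 1]
    class_sizes: dict[str, int]
    assignment_counts: pd.DataFrame  # n[i -> j], integers

    def diagonal(self) -> pd.Series:
        import numpy as np
        return pd.Series(np.diag(self.matrix), index=self.matrix.index)


def _scaffold_mols(lib: ScaffoldLibrary, level: int) -> dict[str, list]:
    per_class = {}
    for cls in lib.classes:
        per_class[cls] = [(s, s.mol()) for s in lib.at_level(level, cls)]
    return per_class


def _matching_classes(mol: Chem.Mol, per_class: dict[str, list]) -> dict[str, int]:
    """class -> max ring count among its scaffolds matching the compound."""
    prepared = preprocess(mol)
    hits: dict[str, int] = {}
    for cls, scaffolds in per_class.items():
        best = -1
        for scf, scf_mol in scaffolds:
            if prepared.mol.HasSubstructMatch(scf_mol):
                best = max(best, scf.ring_count)
        if best >= 0:
            hits[cls] = best
    return hits


def db_coverage(lib: ScaffoldLibrary, level: int,
                db: Sequence[CompoundRecord]) -> CoverageTable:
    """Coverage of a compound set by the level-``level`` scaffolds.

    Each compound is counted in at most one class: the matching class
    whose matched scaffold has the largest ring count, ties broken by
    library class order.  The total coverage is the sum of the per-class
    fractions.
    """
    if not db:
        raise ValueError("compound set is empty")
    if level not in lib.levels:
        raise ValueError(f"library has no scaffolds at level {level}")
    per_class = _scaffold_mols(lib, level)
    matched = {cls: 0 for cls in lib.classes}
    for rec in db:
        hits = _matching_classes(rec.mol, per_class)
        if not hits:
            continue
        best_rings = max(hits.values())
        # library class order is the deterministic tie-break
        winner = next(c for c in lib.classes
                      if hits.get(c) == best_rings)
        matched[winner] += 1
    return CoverageTable(level=level, n_compounds=len(db),
                         matched_per_class=matched)


def coverage_profile(lib: ScaffoldLibrary, levels: Sequence[int],
                     db: Sequence[CompoundRecord],
                     db_name: str = "db") -> pd.DataFrame:
    """Coverage of one compound set across several levels, as a tidy table
    (db, level, coverage percent)."""
    rows = []
    for lv in levels:
        table = db_coverage(lib, lv, db)
        rows.append({"db": db_name, "level": lv,
                     "coverage_pct": 100.0 * table.coverage,
                     "n": table.n_compounds})
    return pd.DataFrame(rows)


def classification_heatmap(lib: ScaffoldLibrary, level: int,
                           labeled: Sequence[CompoundRecord],
                           dedup: bool = False) -> HeatMap:
    """Class-assignment heat map of a labeled compound set at one level.

    By default each compound contributes to every class whose scaffolds
    match it (multi-assignment).  With ``dedup=True`` the coverage
    assignment rule (largest matched ring count, class-order tie-break)
    is applied so each compound lands in at most one column.
    """
    classes = lib.classes
    known = set(classes)
    for rec in labeled:
        if rec.class_label not in known:
            raise ValueError(f"record {rec.id!r} has unknown class "
                             f"{rec.class_label!r}")
    per_class = _scaffold_mols(lib, level)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    sizes = {cls: 0 for cls in classes}
    for rec in labeled:
        sizes[rec.class_label] += 1
        hits = _matching_classes(rec.mol, per_class)
        if not hits:
            continue
        if dedup:
            best = max(hits.values())
            winner = next(c for c in classes if hits.get(c) == best)
            counts.loc[rec.class_label, winner] += 1
        else:
            for cls in hits:
                counts.loc[rec.class_label, cls] += 1
    matrix = counts.astype(float)
    for cls in classes:
        if sizes[cls] > 0:
            matrix.loc[cls] = matrix.loc[cls] / sizes[cls]
        else:
            matrix.loc[cls] = 0.0
    return HeatMap(level=level, matrix=matrix, class_sizes=sizes,
                   assignment_counts=counts)


def plot_heatmap(hm: HeatMap, path=None):  # pragma: no cover - optional viz
    """Render a heat map to a matplotlib axes (optionally saved to path)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(hm.matrix.values, vmin=0, vmax=1, cmap="RdYlBu")
    ax.set_xticks(range(len(hm.matrix.columns)),
                  labels=hm.matrix.columns, rotation=90)
    ax.set_yticks(range(len(hm.matrix.index)), labels=hm.matrix.index)
    ax.set_xlabel("assigned class")
    ax.set_ylabel("true class")
    ax.set_title(f"class assignment, scaffold level {hm.level}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
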