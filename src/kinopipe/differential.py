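"""Per-peptide differential phosphorylation between treatment and control.

The biological unit is the per-subject peptide mean (one array per animal,
technical replicates already averaged by the QC step), so each group
contributes n biological values per peptide.  Significance is a two-tailed
Welch t-test (unequal variances, Welch-Satterthwaite degrees of freedom) at
raw p < alpha — no multiple-testing correction is applied to peptide-level
p-values, matching the published procedure.

Fold change uses the signed-ratio convention: the treatment/control ratio r
of mean intensities, reported as -1/r when r < 1, so values never lie in
(-1, 1).  Because normalized (arsinh) intensities can be non-positive, the
ratio is taken on intensities back-shifted to a positive scale by
``1 - min(all profile values)`` (no shift if already >= 1's floor); the same
dataset-wide shift is used for both groups, which preserves the
treatment/control antisymmetry FC -> -FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ArrayDesign, DifferentialRecord

__all__ = ["ContrastSpec", "welch_t", "fold_change", "positive_shift",
           "call_differential", "table_records", "compare_sets"]


@dataclass(frozen=True)
class ContrastSpec:
    """One treatment-vs-control comparison within a tissue.

    The control is always the tissue-matched PBS group.
    """

    treatment: str
    tissue: str
    control: str = "PBS"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite dof, two-tailed p.

    Degenerate inputs: two zero-variance samples with equal means give
    ``(0, nan, 1)`` by convention; zero variance with unequal means gives the
    infinite-t limit ``p = 0``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float("nan"), 1.0
        return float(np.sign(diff) * np.inf), float("nan"), 0.0
    t = diff / np.sqrt(se2)
    nu = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    p = 2.0 * stats.t.sf(abs(t), nu)
    return float(t), float(nu), float(p)


def positive_shift(profiles: pd.DataFrame) -> float:
    """Dataset-wide back-shift making all mean intensities >= 1."""
    lo = float(profiles["mean_intensity"].min())
    return 1.0 - lo if lo < 1.0 else 0.0


def fold_change(mean_treated: float, mean_control: float, shift: float = 0.0) -> float:
    """Signed fold change of back-shifted positive intensities.

    ``r = (mean_treated + shift) / (mean_control + shift)``; returns ``r`` if
    ``r >= 1`` else ``-1/r``, so ``|FC| >= 1`` always.
    """
    t, c = mean_treated + shift, mean_control + shift
    if c <= 0 or t <= 0:
        raise ValueError(
            f"non-positive mean after shift (treated={t}, control={c}); "
            f"increase the back-shift"
        )
    r = t / c
    return r if r >= 1.0 else -1.0 / r


def call_differential(profiles: pd.DataFrame, contrast: ContrastSpec,
                      design: ArrayDesign) -> pd.DataFrame:
    """Call differentially phosphorylated peptides for one contrast.

    ``profiles`` is the per-(array, peptide) mean table from
    :func:`kinopipe.qc.average_replicates` (consistent peptides only — the
    first of the two published criteria is enforced upstream).  Returns one
    row per called peptide with fold change, Welch statistic/dof/p and
    direction, ordered by the table-writer convention (increased block by
    fold change descending, then decreased ascending).
    """
    annot = design.annotation_frame().set_index("peptide_id")
    grp_t = profiles[(profiles["treatment"] == contrast.treatment)
                     & (profiles["tissue"] == contrast.tissue)]
    grp_c = profiles[(profiles["treatment"] == contrast.control)
                     & (profiles["tissue"] == contrast.tissue)]
    if grp_t.empty:
        raise ValueError(f"no profiles for group ({contrast.treatment}, {contrast.tissue})")
    if grp_c.empty:
        raise ValueError(f"no profiles for control ({contrast.control}, {contrast.tissue})")

    shift = positive_shift(pd.concat([grp_t, grp_c]))
    piv_t = grp_t.pivot(index="peptide_id", columns="array_id", values="mean_intensity")
    piv_c = grp_c.pivot(index="peptide_id", columns="array_id", values="mean_intensity")
    common = piv_t.index.intersection(piv_c.index)

    rows = []
    for pid in common:
        xt = piv_t.loc[pid].dropna().to_numpy()
        xc = piv_c.loc[pid].dropna().to_numpy()
        t, nu, p = welch_t(xt, xc)
        if p >= contrast.alpha:
            continue
        fc = fold_change(float(xt.mean()), float(xc.mean()), shift)
        ann = annot.loc[pid]
        rows.append(
            {
                "peptide_id": pid,
                "protein_name": ann["protein_name"],
                "phosphosite": ann["phosphosite"],
                "uniprot_accession": ann["uniprot_accession"],
                "fold_change": fc,
                "p_value": p,
                "direction": "INCREASED" if fc >= 1.0 else "DECREASED",
                "t": t,
                "nu": nu,
            }
        )
    table = pd.DataFrame(
        rows, columns=["peptide_id", "protein_name", "phosphosite",
                       "uniprot_accession", "fold_change", "p_value",
                       "direction", "t", "nu"]
    )
    if len(table):
        inc = table[table["direction"] == "INCREASED"].sort_values(
            "fold_change", ascending=False, kind="stable")
        dec = table[table["direction"] == "DECREASED"].sort_values(
            "fold_change", ascending=True, kind="stable")
        table = pd.concat([inc, dec], ignore_index=True)
    return table


def table_records(table: pd.DataFrame) -> list[DifferentialRecord]:
    """Convert a differential call table to validated records."""
    return [
        DifferentialRecord(
            peptide_id=row.peptide_id,
            protein_name=row.protein_name,
            phosphosite=row.phosphosite,
            uniprot_accession=row.uniprot_accession,
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
            direction=row.direction,
        )
        for row in table.itertuples(index=False)
    ]


def compare_sets(tables: dict[str, pd.DataFrame | list]) -> dict[str, int]:
    """Venn-region counts of peptide identities across named call sets.

    Accepts differential tables (DataFrames with a ``peptide_id`` column),
    record lists, or plain id iterables.  Returns a mapping from a
    ``+``-joined region label (names present in the region) to its exclusive
    count.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 call sets to compare")
    sets: dict[str, set[str]] = {}
    for name, t in tables.items():
        if isinstance(t, pd.DataFrame):
            sets[name] = set(t["peptide_id"])
        else:
            sets[name] = {getattr(r, "peptide_id", r) for r in t}
    names = list(sets)
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set(universe)
        for n in inside:
            region &= sets[n]
        for n in outside:
            region -= sets[n]
        regions["+".join(inside)] = len(region)
    return regions
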