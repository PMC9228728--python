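"""Relative gene expression from qPCR cycle thresholds (2^-ddCt).

CT tables are long-form: one row per (sample, gene, technical replicate)
with a group label (CONTROL / TREATED).  Technical duplicates are averaged
first, then biological samples, then groups:

    dCt_group  = mean CT_target - mean CT_reference   (within group)
    ddCt       = dCt_treated - dCt_control
    fold change = 2 ** -ddCt

Amplification efficiency is fixed at 2 (the method's defining assumption).
The reference gene is chosen data-driven as the candidate with the smallest
CT standard deviation across all samples (simplest defensible stability
criterion); because the reference cancels in ddCt, any sample-wide CT shift
(loading, global efficiency) leaves the fold change unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FoldChangeResult", "select_reference_gene", "ddct_fold_change"]

CT_COLUMNS = ("sample_id", "group", "gene", "ct", "technical_replicate")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    reference_gene: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def _sample_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: one CT per (sample, group, gene)."""
    missing = [c for c in ("sample_id", "group", "gene", "ct") if c not in records.columns]
    if missing:
        raise ValueError(f"CT table missing columns {missing}")
    return (
        records.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )


def select_reference_gene(records: pd.DataFrame, candidates: list[str]
                          ) -> tuple[str, pd.DataFrame]:
    """Pick the most stable reference gene among candidates.

    Stability = standard deviation of per-sample CT across all samples and
    groups; smallest wins (ties by gene name).  Every candidate must be
    measured in every sample.  Returns ``(gene, report)`` where the report
    lists per-candidate sd.
    """
    if not candidates:
        raise ValueError("no candidate reference genes")
    means = _sample_means(records)
    samples = set(zip(means["sample_id"], means["group"]))
    rows = []
    for gene in candidates:
        sub = means[means["gene"] == gene]
        have = set(zip(sub["sample_id"], sub["group"]))
        lacking = samples - have
        if lacking:
            raise ValueError(
                f"candidate {gene!r} not measured in sample(s) {sorted(lacking)[:5]}"
            )
        rows.append({"gene": gene, "ct_sd": float(sub["ct"].std(ddof=1))})
    report = pd.DataFrame(rows).sort_values(["ct_sd", "gene"], ignore_index=True)
    return str(report["gene"].iloc[0]), report


def ddct_fold_change(records: pd.DataFrame, target: str, reference: str
                     ) -> FoldChangeResult:
    """2^-ddCt fold change of ``target`` (TREATED vs CONTROL) normalized to
    ``reference``."""
    means = _sample_means(records)
    dct = {}
    for group in ("TREATED", "CONTROL"):
        sub = means[means["group"] == group]
        if sub.empty:
            raise ValueError(f"no records for group {group}")
        t = sub[sub["gene"] == target]["ct"]
        r = sub[sub["gene"] == reference]["ct"]
        if t.empty:
            raise ValueError(f"target {target!r} not measured in group {group}")
        if r.empty:
            raise ValueError(f"reference {reference!r} not measured in group {group}")
        dct[group] = float(t.mean() - r.mean())
    ddct = dct["TREATED"] - dct["CONTROL"]
    return FoldChangeResult(
        gene=target,
        reference_gene=reference,
        delta_ct_treated=dct["TREATED"],
        delta_ct_control=dct["CONTROL"],
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
    )
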