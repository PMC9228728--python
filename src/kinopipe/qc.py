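"""Technical-replicate consistency filtering and replicate averaging.

Peptides whose on-array technical replicates vary more than the array-wide
replicate noise are removed before any cross-array analysis.  Per (array,
peptide) the statistic is

    chi2 = (R - 1) * s2_pk / sigma2_k

where ``s2_pk`` is the sample variance of the R replicate values on the
normalized scale and ``sigma2_k`` is a robust array-wide replicate-variance
scale: the median of ``s2_pk`` over that array's peptides, divided by the
median of the chi2_{R-1}/(R-1) distribution so that the statistic is
calibrated against chi2 with R-1 degrees of freedom under homogeneous noise.
The median denominator keeps planted/real outlier peptides from inflating
the scale and masking themselves.

A peptide failing the test (upper-tail p <= alpha, default 0.01) on *any*
array of the dataset under comparison is dropped from the whole comparison:
fold changes, tests and clustering all need a common peptide universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chi2_consistency", "consistent_peptides", "average_replicates"]


def chi2_consistency(norm: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Chi-squared replicate-consistency test per (array, peptide).

    ``norm`` must carry ``array_id``, ``peptide_id`` and
    ``normalized_intensity`` columns with R >= 2 replicate rows per
    (array, peptide).  Returns a frame with columns ``array_id``,
    ``peptide_id``, ``chi2``, ``dof``, ``p_value``, ``keep``
    (``keep = p_value > alpha``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    g = norm.groupby(["array_id", "peptide_id"], sort=True)["normalized_intensity"]
    stats_df = g.agg(n="size", s2="var").reset_index()
    if (stats_df["n"] < 2).any():
        bad = stats_df[stats_df["n"] < 2].iloc[0]
        raise ValueError(
            f"replicate consistency test undefined for R=1 "
            f"(array {bad.array_id}, peptide {bad.peptide_id})"
        )
    out = []
    for array_id, sub in stats_df.groupby("array_id", sort=True):
        dof = sub["n"].to_numpy(int) - 1
        # bias-correct the median so chi2/dof has median 1 under the null
        med_factor = stats.chi2.median(dof) / dof
        s2 = sub["s2"].to_numpy(float)
        sigma2 = np.median(s2 / med_factor)
        if sigma2 <= 0:
            raise ValueError(f"array {array_id!r}: degenerate replicate variance scale")
        chi2 = dof * s2 / sigma2
        p = stats.chi2.sf(chi2, dof)
        out.append(
            pd.DataFrame(
                {
                    "array_id": array_id,
                    "peptide_id": sub["peptide_id"].to_numpy(),
                    "chi2": chi2,
                    "dof": dof,
                    "p_value": p,
                    "keep": p > alpha,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def consistent_peptides(consistency: pd.DataFrame) -> list[str]:
    """Peptides that pass the consistency test on every array considered."""
    ok = consistency.groupby("peptide_id", sort=True)["keep"].all()
    return sorted(ok.index[ok])


def average_replicates(norm: pd.DataFrame, consistency: pd.DataFrame) -> pd.DataFrame:
    """Average the technical replicates of kept peptides per (array, peptide).

    Removed peptides are absent from the output; kept peptides keep all R
    replicates (filtering is per peptide, never per spot).  Returns a frame
    with ``array_id``, ``treatment``, ``tissue``, ``subject_id``,
    ``peptide_id``, ``mean_intensity``, ``n_used``.
    """
    kept = consistent_peptides(consistency)
    sub = norm[norm["peptide_id"].isin(kept)]
    keys = [c for c in ("array_id", "treatment", "tissue", "subject_id", "peptide_id")
            if c in norm.columns]
    out = (
        sub.groupby(keys, sort=True)["normalized_intensity"]
        .agg(mean_intensity="mean", n_used="size")
        .reset_index()
    )
    out["n_used"] = out["n_used"].astype(int)
    return out
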