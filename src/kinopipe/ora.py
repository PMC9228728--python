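"""Hypergeometric pathway over-representation analysis with BH correction.

Differentially phosphorylated peptides are mapped to their proteins'
UniProt accessions (multiple phosphosites on one protein count once); each
pathway gene set, intersected with the measurable universe (the accessions
of all consistently phosphorylated peptides), is tested for enrichment with
the one-sided hypergeometric upper tail; p-values are adjusted across all
tested sets by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["OraQuery", "map_peptides_to_accessions", "hypergeometric_upper_tail",
           "benjamini_hochberg", "run_ora"]


@dataclass(frozen=True)
class OraQuery:
    """Query and universe accession sets plus the gene-set collection.

    The query must be a subset of the universe; gene sets are intersected
    with the universe before testing.
    """

    query: frozenset[str]
    universe: frozenset[str]
    gene_sets: GeneSetCollection = field(default_factory=GeneSetCollection)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        extra = self.query - self.universe
        if extra:
            raise ValueError(f"query accessions outside universe: {sorted(extra)[:5]}")


def map_peptides_to_accessions(records, annotation: pd.DataFrame | None = None
                               ) -> frozenset[str]:
    """De-duplicated accession set of a record list.

    ``records`` may be DifferentialRecords (accession attribute used
    directly) or bare peptide ids resolved through ``annotation``
    (a frame with ``peptide_id`` and ``uniprot_accession`` columns).
    """
    accessions = []
    lookup = None
    if annotation is not None:
        lookup = annotation.set_index("peptide_id")["uniprot_accession"]
    for r in records:
        acc = getattr(r, "uniprot_accession", None)
        if acc is None:
            if lookup is None or r not in lookup.index:
                raise ValueError(f"peptide {r!r} has no annotation")
            acc = lookup[r]
        accessions.append(acc)
    return frozenset(accessions)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the chance that a random
    size-n draw from a universe of N containing K marked items hits at least
    k of them.  Computed in log space by scipy's survival function."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(query: OraQuery, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Test every gene set with nonzero in-universe size.

    Returns a frame sorted by raw p ascending (ties by pathway id) with the
    published table layout plus the hypergeometric counts: pathway id/name/
    source, overlap k, in-universe set size K, query size n, universe size
    N, raw and BH-adjusted p, and a significance flag at
    ``p_adjusted < fdr_threshold``.
    """
    N = len(query.universe)
    n = len(query.query)
    rows = []
    for pid in sorted(query.gene_sets.sets):
        name, source, members = query.gene_sets.sets[pid]
        in_universe = members & query.universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query.query)
        p = hypergeometric_upper_tail(N, K, n, k)
        rows.append(
            {"pathway_id": pid, "pathway_name": name, "source_name": source,
             "overlap": k, "set_size_in_universe": K, "query_size": n,
             "universe_size": N, "p_raw": p}
        )
    result = pd.DataFrame(
        rows, columns=["pathway_id", "pathway_name", "source_name", "overlap",
                       "set_size_in_universe", "query_size", "universe_size",
                       "p_raw"]
    )
    if len(result):
        result["p_adjusted"] = benjamini_hochberg(result["p_raw"].to_numpy())
        result = result.sort_values(
            ["p_raw", "pathway_id"], kind="stable", ignore_index=True
        )
        result["significant"] = result["p_adjusted"] < fdr_threshold
    else:
        result["p_adjusted"] = []
        result["significant"] = []
    return result
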