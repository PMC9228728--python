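"""Domain types and tabular readers/writers for kinome peptide-array data.

Spot-level intensity tables, peptide annotations, differential-phosphorylation
tables (the shape of the published result tables), and GMT gene-set files are
all plain TSV.  In-memory containers are :class:`pandas.DataFrame` objects with
fixed column schemas plus small frozen dataclasses for structured metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PeptideAnnotation",
    "ArrayDesign",
    "DifferentialRecord",
    "GeneSetCollection",
    "SPOT_COLUMNS",
    "FIXTURE_NAMES",
    "default_peptide_catalogue",
    "read_spot_table",
    "write_spot_table",
    "load_fixture_table",
    "read_gmt",
    "write_gmt",
    "write_differential_table",
    "read_differential_table",
    "records_to_frame",
]

#: Column order of a spot-level table (long form, one row per printed spot).
SPOT_COLUMNS = (
    "array_id",
    "treatment",
    "tissue",
    "subject_id",
    "peptide_id",
    "replicate_index",
    "raw_intensity",
)

#: Packaged transcriptions of the published differential-peptide tables.
FIXTURE_NAMES = {
    "MUSCLE_PCEP": "muscle_pcep.tsv",
    "NODE_PCEP": "node_pcep.tsv",
    "NODE_ALUM": "node_alum.tsv",
}

TREATMENTS = ("PBS", "PCEP", "ALUM")
TISSUES = ("MUSCLE", "LYMPH_NODE")


@dataclass(frozen=True)
class PeptideAnnotation:
    """One array peptide: a phosphosite on a named protein.

    The same UniProt accession may map to several peptide ids (distinct
    sites on one protein), but peptide ids are unique within a catalogue.
    """

    peptide_id: str
    protein_name: str
    phosphosite: str
    uniprot_accession: str

    def __post_init__(self) -> None:
        if not self.uniprot_accession:
            raise ValueError(f"peptide {self.peptide_id!r}: empty accession")


@dataclass(frozen=True)
class ArrayDesign:
    """Physical layout of one array: the peptide catalogue printed in
    ``n_tech_replicates`` spots each (default 282 peptides x 9 replicates)."""

    catalogue: tuple[PeptideAnnotation, ...]
    n_tech_replicates: int = 9

    def __post_init__(self) -> None:
        if self.n_tech_replicates < 2:
            raise ValueError("n_tech_replicates must be >= 2")
        ids = [p.peptide_id for p in self.catalogue]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide_id in catalogue: {dupes}")

    @property
    def n_peptides(self) -> int:
        return len(self.catalogue)

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(p.peptide_id for p in self.catalogue)

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [p.peptide_id for p in self.catalogue],
                "protein_name": [p.protein_name for p in self.catalogue],
                "phosphosite": [p.phosphosite for p in self.catalogue],
                "uniprot_accession": [p.uniprot_accession for p in self.catalogue],
            }
        )


@dataclass(frozen=True)
class DifferentialRecord:
    """One differentially phosphorylated peptide with signed fold change.

    The signed convention reports treatment/control intensity ratios below 1
    as the negative reciprocal, so ``fold_change`` never lies in (-1, 1) and
    the direction flag is redundant with (but validated against) its sign.
    """

    peptide_id: str
    protein_name: str
    phosphosite: str
    uniprot_accession: str
    fold_change: float
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("INCREASED", "DECREASED"):
            raise ValueError(f"bad direction {self.direction!r}")
        if -1.0 < self.fold_change < 1.0:
            raise ValueError(
                f"{self.peptide_id}: fold_change {self.fold_change} in (-1, 1)"
            )
        expected = "INCREASED" if self.fold_change >= 1.0 else "DECREASED"
        if self.direction != expected:
            raise ValueError(
                f"{self.peptide_id}: direction {self.direction} inconsistent "
                f"with fold_change {self.fold_change}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.peptide_id}: p_value {self.p_value} not in (0,1]")


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathway gene sets: pathway_id -> (name, source, member accessions)."""

    sets: Mapping[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, _, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return dict(self.sets) == dict(other.sets)


# ---------------------------------------------------------------------------
# spot tables


def _validate_spots(df: pd.DataFrame, design: ArrayDesign, source: str) -> None:
    dup = df.duplicated(subset=["array_id", "peptide_id", "replicate_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{source}: duplicate (array, peptide, replicate) key "
            f"({row.array_id}, {row.peptide_id}, {row.replicate_index})"
        )
    known = set(design.peptide_ids)
    unknown = sorted(set(df["peptide_id"]) - known)
    if unknown:
        raise ValueError(f"{source}: peptide ids not in design: {unknown[:10]}")
    bad_rep = df[
        (df["replicate_index"] < 1) | (df["replicate_index"] > design.n_tech_replicates)
    ]
    if len(bad_rep):
        row = bad_rep.iloc[0]
        raise ValueError(
            f"{source}: replicate_index {row.replicate_index} outside "
            f"1..{design.n_tech_replicates} for "
            f"(array {row.array_id}, peptide {row.peptide_id})"
        )
    neg = df[df["raw_intensity"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValueError(
            f"{source}: negative raw_intensity {row.raw_intensity} "
            f"for (array {row.array_id}, peptide {row.peptide_id})"
        )


def array_completeness(spots: pd.DataFrame, design: ArrayDesign) -> pd.Series:
    """Fraction of design spots (peptides x replicates) present, per array."""
    full = design.n_peptides * design.n_tech_replicates
    return spots.groupby("array_id", sort=True).size() / full


def read_spot_table(path, design: ArrayDesign) -> pd.DataFrame:
    """Read a long-form TSV of spot measurements and validate it against
    the array design.  Returns a DataFrame with :data:`SPOT_COLUMNS`."""
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "subject_id": str,
                                            "peptide_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[list(SPOT_COLUMNS)].copy()
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["raw_intensity"] = df["raw_intensity"].astype(float)
    _validate_spots(df, design, str(path))
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False, columns=list(SPOT_COLUMNS),
                 float_format="%.17g")


# ---------------------------------------------------------------------------
# differential tables


def _sorted_records(records: Sequence[DifferentialRecord]) -> list[DifferentialRecord]:
    inc = [r for r in records if r.direction == "INCREASED"]
    dec = [r for r in records if r.direction == "DECREASED"]
    # stable sorts: ties keep input order, matching the printed table layout
    inc.sort(key=lambda r: -r.fold_change)
    dec.sort(key=lambda r: r.fold_change)
    return inc + dec


def _format_number(x: float) -> str:
    return f"{x:.4g}"


def write_differential_table(records: Sequence[DifferentialRecord], path,
                             extra: Mapping[str, Sequence] | None = None) -> None:
    """Write records in the published layout: the increased block sorted by
    fold change descending, then the decreased block ascending.  P-values and
    fold changes are written with 4 significant digits."""
    ordered = _sorted_records(records)
    cols = ["peptide_id", "protein_name", "phosphosite", "uniprot_accession",
            "fold_change", "p_value", "direction"]
    lines = ["\t".join(cols + list(extra or ()))]
    index = {r.peptide_id: i for i, r in enumerate(records)}
    for r in ordered:
        row = [r.peptide_id, r.protein_name, r.phosphosite, r.uniprot_accession,
               _format_number(r.fold_change), _format_number(r.p_value), r.direction]
        if extra:
            for name in extra:
                row.append(_format_number(float(extra[name][index[r.peptide_id]])))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _records_from_frame(df: pd.DataFrame) -> list[DifferentialRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DifferentialRecord(
                peptide_id=str(row.peptide_id),
                protein_name=str(row.protein_name),
                phosphosite=str(row.phosphosite),
                uniprot_accession=str(row.uniprot_accession),
                # printed tables may use a unicode minus; normalize on ingest
                fold_change=float(str(row.fold_change).replace("−", "-")),
                p_value=float(str(row.p_value).replace("−", "-")),
                direction=str(row.direction),
            )
        )
    return out


def read_differential_table(path) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return _records_from_frame(df)


def records_to_frame(records: Iterable[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide_id": r.peptide_id,
                "protein_name": r.protein_name,
                "phosphosite": r.phosphosite,
                "uniprot_accession": r.uniprot_accession,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in records
        ]
    )


def load_fixture_table(name: str) -> list[DifferentialRecord]:
    """Load one of the packaged transcriptions of the published tables
    (``MUSCLE_PCEP``, ``NODE_PCEP``, ``NODE_ALUM``)."""
    try:
        fname = FIXTURE_NAMES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_NAMES)}")
    ref = resources.files("kinopipe") / "fixtures" / fname
    with resources.as_file(ref) as p:
        return read_differential_table(p)


def default_peptide_catalogue(n_peptides: int = 282) -> tuple[PeptideAnnotation, ...]:
    """Synthetic peptide catalogue used when no annotation table is supplied.

    Real arrays carry curated phosphosites; for simulation we only need
    unique ids and a plausible site/accession structure (two sites per
    pseudo-protein, mirroring multi-site proteins on real arrays).
    """
    peptides = []
    for i in range(n_peptides):
        prot = f"PROT{i // 2 + 1:03d}"
        site = f"{'SY'[i % 2]}{100 + i}"
        peptides.append(
            PeptideAnnotation(
                peptide_id=f"pep{i + 1:03d}",
                protein_name=prot,
                phosphosite=site,
                uniprot_accession=f"X{i // 2 + 1:05d}",
            )
        )
    return tuple(peptides)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``pathway_id<TAB>description<TAB>member...``.  The description field may
    carry ``pathway_name|source_name``; a missing source is left empty.
    Members are de-duplicated within a set (first occurrence order kept)."""
    sets: dict[str, tuple[str, str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            pid, desc = fields[0], fields[1]
            if pid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            name, _, source = desc.partition("|")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {pid!r} has no members")
            sets[pid] = (name, source, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.sets):
            name, source, members = collection.sets[pid]
            desc = f"{name}|{source}" if source else name
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")
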