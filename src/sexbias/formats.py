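"""Readers and writers for every file dialect the pipeline touches.

Containers are thin wrappers over pandas objects.  Coordinate convention
is 1-based inclusive everywhere internally (the miRBase GFF3 convention);
any conversion would be confined to this module.

Dialects
--------
* expression matrix: TSV, rows = miRNA names, columns = sample IDs
* sample metadata: TSV with columns ``sample_id``, ``sex`` (F/M) and
  optionally ``disease``, ``dataset_id``
* annotation: GFF3, miRBase dialect -- precursor records have type
  ``miRNA_primary_transcript``, mature records have type ``miRNA`` with a
  ``Derives_from`` link to the precursor's ID
* families: miFam dialect (``AC``/``ID``/``MI`` lines, ``//`` terminator)
* associations: CSV with columns ``mirna,disease``
* category sets: TSV with columns ``category_class``, ``category_name``,
  ``mirna``
* tissue-specificity scores: TSV with columns ``mirna``, ``tsi``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexbias.names import normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "MiRNAAnnotation",
    "AssociationTable",
    "CategorySetCollection",
    "read_expression",
    "write_expression",
    "read_gff3",
    "read_mature_map",
    "write_gff3",
    "read_mifam",
    "write_mifam",
    "read_associations",
    "write_associations",
    "read_category_sets",
    "write_category_sets",
    "read_tsi",
    "write_tsi",
    "DISEASE_GROUPS",
    "TISSUE_CLASSES",
]

#: The eight ICD-11-derived disease categories datasets are binned into.
DISEASE_GROUPS = (
    "Infectious",
    "Neoplasms",
    "Endocrine diseases",
    "Mental disorders",
    "Epilepsy",
    "Retinopathy",
    "Developmental anomalies",
    "Injury",
)

TISSUE_CLASSES = ("peripheral_blood", "brain", "neoplasms", "other")

CONSERVATION_GROUPS = ("G1", "G2", "G3", "G4", "G5")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionDataset:
    """Normalized miRNA x sample matrix with sex/disease metadata.

    ``matrix`` is indexed by harmonized miRNA name with one column per
    sample; ``sample_sex`` maps every column to ``"F"`` or ``"M"``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    sample_sex: dict[str, str]
    disease: str = ""
    disease_group: str = ""
    tissue_class: str = ""

    def __post_init__(self) -> None:
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 2:
            raise ValueError(
                f"{self.dataset_id}: expression matrix needs >=1 miRNA and >=2 samples, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.dataset_id}: duplicate miRNA names after harmonization: {dups}")
        missing = [s for s in self.matrix.columns if s not in self.sample_sex]
        if missing:
            raise ValueError(f"{self.dataset_id}: samples missing from metadata: {missing}")
        bad = {s: v for s, v in self.sample_sex.items() if v not in ("F", "M")}
        if bad:
            raise ValueError(f"{self.dataset_id}: sex labels must be F or M, got {bad}")

    def sex_columns(self, sex: str) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_sex[s] == sex]

    @property
    def n_female(self) -> int:
        return len(self.sex_columns("F"))

    @property
    def n_male(self) -> int:
        return len(self.sex_columns("M"))


@dataclass
class MiRNAAnnotation:
    """Per-precursor genomic and evolutionary annotation.

    ``table`` is indexed by precursor name with columns ``chromosome``,
    ``start``, ``end`` (1-based inclusive), ``strand``, and optionally
    ``conservation_group`` (G1..G5) and ``family_accession``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if (self.table["start"] > self.table["end"]).any():
            bad = self.table.index[self.table["start"] > self.table["end"]].tolist()
            raise ValueError(f"annotation rows with start > end: {bad}")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-' for every precursor")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate precursor names in annotation")

    @property
    def universe(self) -> set[str]:
        return set(self.table.index)

    def subset(self, names) -> pd.DataFrame:
        """Rows for the given precursor names; absent names are logged and skipped."""
        names = [normalize_name(n) for n in names]
        present = [n for n in names if n in self.table.index]
        absent = sorted(set(names) - set(present))
        if absent:
            logger.info("%d miRNAs absent from annotation, skipped: %s...", len(absent), absent[:5])
        return self.table.loc[present]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AssociationTable:
    """miRNA <-> disease links (HMDD-style)."""

    pairs: set[tuple[str, str]]
    disease_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.disease_universe = set(self.disease_universe) | {d for _, d in self.pairs}

    def diseases_of(self, mirna: str) -> set[str]:
        name = normalize_name(mirna)
        return {d for m, d in self.pairs if m == name}


@dataclass
class CategorySetCollection:
    """Named miRNA sets of one category class (function / disease / TF)."""

    class_name: str
    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empties = [name for name, s in self.sets.items() if not s]
        if empties:
            raise ValueError(f"empty category sets in class {self.class_name!r}: {empties}")

    @property
    def member_universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


# ---------------------------------------------------------------------------
# expression


def read_expression(
    tsv_path,
    metadata_path,
    dataset_id: str | None = None,
    disease: str = "",
    disease_group: str = "",
    tissue_class: str = "",
) -> ExpressionDataset:
    """Load an expression matrix and its sample metadata.

    Rows whose values are all null are dropped; duplicate rows mapping to
    the same harmonized miRNA name are averaged.  Both counts are logged.
    A matrix column absent from the metadata, or a sex label outside
    {F, M}, is a hard error.
    """
    matrix = pd.read_csv(tsv_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "sex" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata needs 'sample_id' and 'sex' columns")
    meta = meta.set_index("sample_id")

    missing = [str(c) for c in matrix.columns if str(c) not in meta.index]
    if missing:
        raise ValueError(f"{tsv_path}: samples missing from metadata: {missing}")

    n_raw = len(matrix)
    matrix = matrix.dropna(how="all")
    n_dropped = n_raw - len(matrix)

    matrix.index = [normalize_name(n) for n in matrix.index]
    n_before_merge = len(matrix)
    if matrix.index.duplicated().any():
        matrix = matrix.groupby(level=0, sort=False).mean()
    n_merged = n_before_merge - len(matrix)
    if n_dropped or n_merged:
        logger.info(
            "%s: dropped %d all-null rows, mean-merged %d duplicate rows",
            tsv_path,
            n_dropped,
            n_merged,
        )

    if dataset_id is None:
        dataset_id = (
            meta["dataset_id"].iloc[0] if "dataset_id" in meta.columns else str(tsv_path)
        )
    if not disease and "disease" in meta.columns:
        disease = meta["disease"].iloc[0]
    sample_sex = {str(s): meta.loc[str(s), "sex"] for s in matrix.columns}
    return ExpressionDataset(
        dataset_id=dataset_id,
        matrix=matrix,
        sample_sex=sample_sex,
        disease=disease,
        disease_group=disease_group,
        tissue_class=tissue_class,
    )


def write_expression(dataset: ExpressionDataset, tsv_path, metadata_path) -> None:
    dataset.matrix.to_csv(tsv_path, sep="\t", index_label="mirna")
    meta = pd.DataFrame(
        {
            "sample_id": list(dataset.matrix.columns),
            "sex": [dataset.sample_sex[s] for s in dataset.matrix.columns],
            "disease": dataset.disease,
            "dataset_id": dataset.dataset_id,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 (miRBase dialect)


def _parse_gff3_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"{path}:{lineno}: malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _iter_gff3_records(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line ({len(fields)} fields, expected 9)"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gff3_attributes(attr_text, path, lineno)
            yield lineno, chrom, ftype, start_i, end_i, strand, attrs


def read_gff3(path) -> MiRNAAnnotation:
    """Parse precursor (``miRNA_primary_transcript``) records.

    The ``Name`` attribute becomes the precursor name; 1-based inclusive
    coordinates are preserved as-is.  Optional ``conservation_group`` and
    ``family`` attributes (emitted by the synthetic generator) populate
    the corresponding annotation columns.
    """
    rows = []
    for lineno, chrom, ftype, start, end, strand, attrs in _iter_gff3_records(path):
        if ftype != "miRNA_primary_transcript":
            continue
        if "Name" not in attrs:
            raise ValueError(f"{path}:{lineno}: precursor record lacks a Name attribute")
        rows.append(
            {
                "precursor_name": normalize_name(attrs["Name"]),
                "chromosome": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "conservation_group": attrs.get("conservation_group", ""),
                "family_accession": attrs.get("family", ""),
            }
        )
    if not rows:
        raise ValueError(f"{path}: no miRNA_primary_transcript records found")
    table = pd.DataFrame(rows).set_index("precursor_name")
    return MiRNAAnnotation(table=table)


def read_mature_map(path) -> dict[str, list[str]]:
    """Precursor name -> mature-name list, via ``Derives_from`` links."""
    id_to_name: dict[str, str] = {}
    derived: list[tuple[str, str]] = []
    for lineno, _chrom, ftype, _s, _e, _strand, attrs in _iter_gff3_records(path):
        if ftype == "miRNA_primary_transcript":
            if "ID" in attrs and "Name" in attrs:
                id_to_name[attrs["ID"]] = normalize_name(attrs["Name"])
        elif ftype == "miRNA":
            if "Derives_from" not in attrs or "Name" not in attrs:
                raise ValueError(f"{path}:{lineno}: mature record needs Name and Derives_from")
            derived.append((attrs["Derives_from"], normalize_name(attrs["Name"])))
    mapping: dict[str, list[str]] = {}
    for precursor_id, mature in derived:
        if precursor_id not in id_to_name:
            raise ValueError(f"{path}: Derives_from references unknown precursor {precursor_id}")
        mapping.setdefault(id_to_name[precursor_id], []).append(mature)
    return mapping


def write_gff3(annotation: MiRNAAnnotation, path, mature_map: dict[str, list[str]] | None = None) -> None:
    """Emit the miRBase GFF3 dialect; precursor IDs are generated as MI%07d."""
    mature_map = mature_map or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        mimat = 1
        for i, (name, row) in enumerate(annotation.table.iterrows(), start=1):
            precursor_id = f"MI{i:07d}"
            attrs = [f"ID={precursor_id}", f"Name={name}"]
            if row.get("conservation_group", ""):
                attrs.append(f"conservation_group={row['conservation_group']}")
            if row.get("family_accession", ""):
                attrs.append(f"family={row['family_accession']}")
            fh.write(
                "\t".join(
                    [
                        str(row["chromosome"]),
                        ".",
                        "miRNA_primary_transcript",
                        str(int(row["start"])),
                        str(int(row["end"])),
                        ".",
                        str(row["strand"]),
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for mature in mature_map.get(name, []):
                fh.write(
                    "\t".join(
                        [
                            str(row["chromosome"]),
                            ".",
                            "miRNA",
                            str(int(row["start"])),
                            str(int(row["end"])),
                            ".",
                            str(row["strand"]),
                            ".",
                            f"ID=MIMAT{mimat:07d};Name={mature};Derives_from={precursor_id}",
                        ]
                    )
                    + "\n"
                )
                mimat += 1


# ---------------------------------------------------------------------------
# miFam dialect


def read_mifam(path) -> dict[str, list[str]]:
    """Family accession -> member-name list.

    Records look like::

        AC   MIPF0000001
        ID   mir-17
        MI   MI0000071  hsa-mir-17
        //

    A record not closed by ``//`` is an error.  The species prefix of a
    member is its first hyphen-delimited token (``hsa-mir-17`` -> ``hsa``).
    """
    families: dict[str, list[str]] = {}
    accession: str | None = None
    members: list[str] = []
    open_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                if accession is None:
                    raise ValueError(f"{path}:{lineno}: record terminator without AC line")
                families[accession] = members
                accession, members, open_record = None, [], False
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            if tag == "AC":
                if open_record:
                    raise ValueError(f"{path}:{lineno}: record missing '//' terminator")
                accession = rest
                open_record = True
            elif tag == "ID":
                continue
            elif tag == "MI":
                parts = rest.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: MI line needs an id and a member name")
                members.append(normalize_name(parts[1]))
            else:
                raise ValueError(f"{path}:{lineno}: unknown miFam tag {tag!r}")
    if open_record:
        raise ValueError(f"{path}: last record missing '//' terminator")
    return families


def write_mifam(families: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for i, (accession, members) in enumerate(families.items(), start=1):
            fh.write(f"AC   {accession}\n")
            fh.write(f"ID   fam-{accession.lower()}\n")
            for j, member in enumerate(members, start=1):
                fh.write(f"MI   MI{i:04d}{j:03d}  {member}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# simple tables


def read_associations(path) -> AssociationTable:
    df = pd.read_csv(path)
    if df.empty:
        return AssociationTable(pairs=set())
    if not {"mirna", "disease"} <= set(df.columns):
        raise ValueError(f"{path}: association CSV needs 'mirna' and 'disease' columns")
    pairs = {(normalize_name(m), str(d)) for m, d in zip(df["mirna"], df["disease"])}
    return AssociationTable(pairs=pairs)


def write_associations(table: AssociationTable, path) -> None:
    df = pd.DataFrame(sorted(table.pairs), columns=["mirna", "disease"])
    df.to_csv(path, index=False)


def read_category_sets(path) -> dict[str, CategorySetCollection]:
    """TSV with columns category_class, category_name, mirna -> per-class collections."""
    df = pd.read_csv(path, sep="\t")
    required = {"category_class", "category_name", "mirna"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: category-set TSV needs columns {sorted(required)}")
    out: dict[str, CategorySetCollection] = {}
    for class_name, class_df in df.groupby("category_class", sort=True):
        sets = {
            str(cat): {normalize_name(m) for m in sub["mirna"]}
            for cat, sub in class_df.groupby("category_name", sort=True)
        }
        out[str(class_name)] = CategorySetCollection(class_name=str(class_name), sets=sets)
    return out


def write_category_sets(collections: dict[str, CategorySetCollection], path) -> None:
    rows = [
        {"category_class": coll.class_name, "category_name": cat, "mirna": m}
        for coll in collections.values()
        for cat, members in sorted(coll.sets.items())
        for m in sorted(members)
    ]
    pd.DataFrame(rows, columns=["category_class", "category_name", "mirna"]).to_csv(
        path, sep="\t", index=False
    )


def read_tsi(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"mirna", "tsi"} <= set(df.columns):
        raise ValueError(f"{path}: TSI table needs 'mirna' and 'tsi' columns")
    scores = {normalize_name(m): float(v) for m, v in zip(df["mirna"], df["tsi"])}
    bad = {m: v for m, v in scores.items() if not (0.0 <= v <= 1.0) or not np.isfinite(v)}
    if bad:
        raise ValueError(f"{path}: TSI scores outside [0, 1]: {bad}")
    return scores


def write_tsi(scores: dict[str, float], path) -> None:
    df = pd.DataFrame(sorted(scores.items()), columns=["mirna", "tsi"])
    df.to_csv(path, sep="\t", index=False)
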