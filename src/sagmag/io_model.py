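"""Shared domain types, table schemas, and TSV/FASTA input-output.

Every stage of the pipeline exchanges plain tab-separated tables with a
mandatory header row (UTF-8, ``#``-prefixed comment lines permitted, empty
cell = missing; ``.`` is never a numeric placeholder).  The schemas declared
here are the single source of truth for column names, types, bounds and
uniqueness constraints; :func:`read_table` and :func:`write_table` enforce
them in both directions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# --------------------------------------------------------------------------
# Ranked taxonomy
# --------------------------------------------------------------------------

#: The seven ranks, highest first.  GUNC reports "kingdom" for the first
#: slot; :func:`normalize_rank` maps it onto ``domain``.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

_RANK_PREFIX = {
    "domain": "d__", "phylum": "p__", "class": "c__", "order": "o__",
    "family": "f__", "genus": "g__", "species": "s__",
}

#: Ranks strictly above genus (used by the consensus chimera caller).
RANKS_ABOVE_GENUS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family")


def normalize_rank(rank: str) -> str:
    """Map estimator rank vocabulary onto the seven-slot vocabulary."""
    r = rank.strip().lower()
    if r == "kingdom":
        return "domain"
    if r not in RANKS:
        raise ValueError(f"unknown taxonomic rank: {rank!r}")
    return r


@dataclasses.dataclass(frozen=True)
class RankedTaxonomy:
    """A seven-rank taxonomy; an empty label means unassigned at that rank.

    Comparisons must treat an empty label as unassigned: it is never equal
    to anything, including another empty label (see :meth:`agrees_at`).
    """

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def label(self, rank: str) -> str:
        rank = normalize_rank(rank)
        return getattr(self, "class_" if rank == "class" else rank)

    def labels(self) -> tuple[str, ...]:
        return tuple(self.label(r) for r in RANKS)

    def agrees_at(self, other: "RankedTaxonomy", rank: str) -> bool | None:
        """True/False if both sides are assigned at *rank*, else None."""
        a, b = self.label(rank), other.label(rank)
        if not a or not b:
            return None
        return a == b

    @classmethod
    def from_string(cls, text: str) -> "RankedTaxonomy":
        """Parse a GTDB-style string ``d__X;p__Y;...``.

        Missing trailing ranks are tolerated; a bare prefix (``g__``) is an
        empty label.  Fields must appear in rank order when present.
        """
        labels = dict.fromkeys(RANKS, "")
        text = text.strip()
        if text:
            last_idx = -1
            for field in text.split(";"):
                field = field.strip()
                if not field:
                    continue
                prefix, _, label = field.partition("__")
                prefix += "__"
                for idx, rank in enumerate(RANKS):
                    if _RANK_PREFIX[rank] == prefix:
                        if idx <= last_idx:
                            raise ValueError(f"ranks out of order in {text!r}")
                        last_idx = idx
                        labels[rank] = label
                        break
                else:
                    raise ValueError(f"unknown rank prefix in field {field!r}")
        return cls(
            domain=labels["domain"], phylum=labels["phylum"],
            class_=labels["class"], order=labels["order"],
            family=labels["family"], genus=labels["genus"],
            species=labels["species"],
        )

    def to_string(self) -> str:
        return ";".join(_RANK_PREFIX[r] + self.label(r) for r in RANKS)


# --------------------------------------------------------------------------
# Table schemas
# --------------------------------------------------------------------------

class TableSchemaError(ValueError):
    """A table violated its schema (bad column, type, bound or uniqueness)."""


@dataclasses.dataclass(frozen=True)
class Column:
    name: str
    kind: str  # "str" | "int" | "float" | "bool"
    lo: float | None = None
    hi: float | None = None
    allowed: frozenset[str] | None = None


@dataclasses.dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]
    unique: tuple[tuple[str, ...], ...] = ()
    frame_checks: tuple[Callable[[pd.DataFrame], str | None], ...] = ()

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


def _check_cluster_reps(df: pd.DataFrame) -> str | None:
    for cluster_id, grp in df.groupby("cluster_id", sort=False):
        n_rep = int(grp["is_representative"].sum())
        if n_rep != 1:
            return f"cluster {cluster_id!r} has {n_rep} representatives (need 1)"
    return None


def _check_taxonomy_column(col: str) -> Callable[[pd.DataFrame], str | None]:
    def check(df: pd.DataFrame) -> str | None:
        for i, value in enumerate(df[col]):
            try:
                RankedTaxonomy.from_string(value)
            except ValueError as exc:
                return f"row {i}: bad taxonomy: {exc}"
        return None
    return check


COLLECTIONS = frozenset({"SAG", "MAG", "ISOLATE"})
METHODS = frozenset({"SAG", "MAG", "AMPLICON", "SHOTGUN"})
REGIONS = frozenset({"open_ocean", "coastal", "inland_sea"})
_GUNC_RANKS = frozenset(RANKS) | {"kingdom"}

SCHEMAS: dict[str, TableSchema] = {}


def _register(schema: TableSchema) -> TableSchema:
    SCHEMAS[schema.name] = schema
    return schema


GENOMES = _register(TableSchema(
    name="genomes",
    columns=(
        Column("genome_id", "str"),
        Column("collection", "str", allowed=COLLECTIONS),
        Column("taxonomy", "str"),
        Column("completeness", "float", lo=0.0, hi=100.0),
        Column("contamination", "float", lo=0.0, hi=100.0),
        Column("sample_id", "str"),
        Column("depth_m", "float", lo=0.0),
        Column("latitude_deg", "float", lo=-90.0, hi=90.0),
        Column("region_flag", "str", allowed=REGIONS),
    ),
    unique=(("genome_id",),),
    frame_checks=(_check_taxonomy_column("taxonomy"),),
))

COUNTS = _register(TableSchema(
    name="counts",
    columns=(
        Column("method", "str", allowed=METHODS),
        Column("sample_id", "str"),
        Column("rank", "str", allowed=frozenset(RANKS)),
        Column("lineage", "str"),
        Column("count", "int", lo=0),
    ),
    unique=(("method", "sample_id", "rank", "lineage"),),
))

ANNOTATIONS = _register(TableSchema(
    name="annotations",
    columns=(
        Column("genome_id", "str"),
        Column("gene_id", "str"),
        Column("ko_id", "str"),
    ),
    unique=(("genome_id", "gene_id", "ko_id"),),
))

MODULES = _register(TableSchema(
    name="modules",
    columns=(
        Column("module_id", "str"),
        Column("ko_id", "str"),
    ),
    unique=(("module_id", "ko_id"),),
))

GUNC = _register(TableSchema(
    name="gunc",
    columns=(
        Column("genome_id", "str"),
        Column("rank", "str", allowed=_GUNC_RANKS),
        Column("css", "float", lo=0.0, hi=1.0),
        Column("rrs", "float", lo=0.0, hi=1.0),
        Column("contamination_portion", "float", lo=0.0, hi=1.0),
    ),
    unique=(("genome_id", "rank"),),
))

MDM = _register(TableSchema(
    name="mdm",
    columns=(
        Column("genome_id", "str"),
        Column("contamination_fraction", "float", lo=0.0, hi=1.0),
    ),
    unique=(("genome_id",),),
))

RRNA = _register(TableSchema(
    name="rrna",
    columns=(
        Column("genome_id", "str"),
        Column("seq_id", "str"),
        Column("taxonomy", "str"),
    ),
    unique=(("genome_id", "seq_id"),),
    frame_checks=(_check_taxonomy_column("taxonomy"),),
))

ALIGNMENTS = _register(TableSchema(
    name="alignments",
    columns=(
        Column("sample_id", "str"),
        Column("reference_set", "str", allowed=frozenset({"SAG", "MAG"})),
        Column("read_id", "str"),
        Column("best_identity", "float", lo=0.0, hi=1.0),
        Column("aln_length", "int", lo=1),
        Column("sample_total_reads", "int", lo=1),
    ),
    unique=(("sample_id", "reference_set", "read_id"),),
))

CLUSTERS = _register(TableSchema(
    name="clusters",
    columns=(
        Column("member_id", "str"),
        Column("cluster_id", "str"),
        Column("is_representative", "bool"),
    ),
    unique=(("member_id",),),
    frame_checks=(_check_cluster_reps,),
))


# --------------------------------------------------------------------------
# Read / write / validate
# --------------------------------------------------------------------------

def _coerce_column(raw: pd.Series, col: Column, schema: str) -> pd.Series:
    if col.kind == "str":
        return raw.astype(str)
    if col.kind == "bool":
        lowered = raw.str.lower()
        bad = ~lowered.isin(("true", "false"))
        if bad.any():
            row = int(bad.idxmax())
            raise TableSchemaError(
                f"{schema}: row {row}, column {col.name!r}: "
                f"expected true/false, got {raw.iloc[row]!r}")
        return lowered == "true"
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise TableSchemaError(
            f"{schema}: row {row}, column {col.name!r}: "
            f"not a number: {raw.iloc[row]!r}")
    if col.kind == "int":
        as_int = numeric.astype("int64")
        if not (as_int == numeric).all():
            row = int((as_int != numeric).idxmax())
            raise TableSchemaError(
                f"{schema}: row {row}, column {col.name!r}: "
                f"not an integer: {raw.iloc[row]!r}")
        return as_int
    return numeric.astype(float)


def validate_table(df: pd.DataFrame, schema: TableSchema | str) -> pd.DataFrame:
    """Validate *df* against *schema*; returns the (unchanged) frame."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    missing = [c for c in schema.column_names if c not in df.columns]
    unknown = [c for c in df.columns if c not in schema.column_names]
    if missing or unknown:
        raise TableSchemaError(
            f"{schema.name}: column mismatch (missing={missing}, unknown={unknown})")
    for col in schema.columns:
        series = df[col.name]
        if col.kind in ("int", "float"):
            if col.lo is not None and (series < col.lo).any():
                row = int((series < col.lo).idxmax())
                raise TableSchemaError(
                    f"{schema.name}: row {row}, column {col.name!r}: "
                    f"value {series.iloc[row]} below minimum {col.lo}")
            if col.hi is not None and (series > col.hi).any():
                row = int((series > col.hi).idxmax())
                raise TableSchemaError(
                    f"{schema.name}: row {row}, column {col.name!r}: "
                    f"value {series.iloc[row]} above maximum {col.hi}")
        if col.allowed is not None:
            bad = ~series.isin(col.allowed)
            if bad.any():
                row = int(bad.idxmax())
                raise TableSchemaError(
                    f"{schema.name}: row {row}, column {col.name!r}: "
                    f"{series.iloc[row]!r} not in {sorted(col.allowed)}")
    for key in schema.unique:
        dup = df.duplicated(subset=list(key))
        if dup.any():
            row = int(dup.idxmax())
            raise TableSchemaError(
                f"{schema.name}: row {row}: duplicate key on {key}")
    for check in schema.frame_checks:
        message = check(df)
        if message is not None:
            raise TableSchemaError(f"{schema.name}: {message}")
    return df


def read_table(path: str | Path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate one of the declared tab-separated tables.

    Lines starting with ``#`` are comments.  Column order in the file must
    match the schema header; row order is preserved.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, comment="#",
        keep_default_na=False, na_values=[],
    )
    if tuple(raw.columns) != schema.column_names:
        raise TableSchemaError(
            f"{schema.name}: header {tuple(raw.columns)} != "
            f"expected {schema.column_names}")
    raw = raw.reset_index(drop=True)
    out = pd.DataFrame(index=raw.index)
    for col in schema.columns:
        out[col.name] = _coerce_column(raw[col.name], col, schema.name)
    return validate_table(out, schema)


def _format_cell(value: object, kind: str) -> str:
    if kind == "bool":
        return "true" if value else "false"
    if kind == "float":
        # %.17g round-trips IEEE doubles exactly
        return "%.17g" % float(value)
    return str(value)


def write_table(df: pd.DataFrame, path: str | Path,
                schema: TableSchema | str,
                header_comments: Sequence[str] = ()) -> Path:
    """Validate then write a table; ``read_table`` inverts it exactly."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    validate_table(df, schema)
    path = Path(path)
    lines = [f"# {comment}" for comment in header_comments]
    lines.append("\t".join(schema.column_names))
    kinds = {c.name: c.kind for c in schema.columns}
    for _, row in df.iterrows():
        lines.append("\t".join(
            _format_cell(row[name], kinds[name]) for name in schema.column_names))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA; returns (seq_id, description, residues) per record."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, rec.description, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    """Write (seq_id, description, residues) records as FASTA."""
    path = Path(path)
    seqs = [
        SeqRecord(Seq(residues), id=seq_id, description=description)
        for seq_id, description, residues in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
    return path


# --------------------------------------------------------------------------
# Genome metadata filtering
# --------------------------------------------------------------------------

def filter_genomes_metadata(
    genomes: pd.DataFrame,
    max_depth_m: float = 100.0,
    lat_min: float = -40.0,
    lat_max: float = 40.0,
    exclude_regions: Iterable[str] = ("coastal", "inland_sea"),
) -> pd.DataFrame:
    """Keep epipelagic, (sub)tropical, open-ocean genomes.

    Retains genomes with ``depth_m <= max_depth_m``, latitude within
    ``[lat_min, lat_max]`` and a region flag outside *exclude_regions*
    (coastal areas and inland seas are excluded by default).  Row order is
    preserved; the result is a subset of the input, so the filter is
    idempotent.
    """
    excluded = frozenset(exclude_regions)
    keep = (
        (genomes["depth_m"] <= max_depth_m)
        & (genomes["latitude_deg"] >= lat_min)
        & (genomes["latitude_deg"] <= lat_max)
        & ~genomes["region_flag"].isin(excluded)
    )
    return genomes.loc[keep].reset_index(drop=True)


def parse_taxonomies(genomes: pd.DataFrame) -> dict[str, RankedTaxonomy]:
    """genome_id -> RankedTaxonomy for a validated genomes table."""
    return {
        row.genome_id: RankedTaxonomy.from_string(row.taxonomy)
        for row in genomes.itertuples(index=False)
    }
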