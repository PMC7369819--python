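"""Readers, writers and validated containers for every artifact the pipeline touches.

All tables are plain tab-separated text.  Methylation is stored as beta
values (fraction methylated, in [0, 1]); genotypes as additive dosages in
{0, 1, 2} with missing allowed.  Joins across tables are always by
sample identifier, never by row order.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROMOTER_FEATURES = ("TSS1500", "TSS200", "5UTR")
GENOMIC_FEATURES = PROMOTER_FEATURES + ("1stExon", "Body", "3UTR", "intergenic")
SMOKING_LEVELS = ("never", "former", "current")
URATE_GROUPS = ("normouricemia", "hyperuricemia", "gout")
CANDIDATE_CATEGORIES = ("il1b_production", "expressed_macrophage_il1b", "gouty_inflammation")

MISSING = "NA"

# sha256 of the packaged candidate-table fixture; guards against corruption
_CANDIDATE_FIXTURE_SHA256 = "c6b72918fb7071eaacd520d93335a53a6f7592df65ee4b3439607df68486afbc"


class TableFormatError(ValueError):
    """Raised when an input file violates the dialect or a value constraint."""


# ---------------------------------------------------------------------------
# float formatting: shortest decimal string that round-trips exactly
# ---------------------------------------------------------------------------

def _fmt_value(v) -> str:
    if v is None:
        return MISSING
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return MISSING
        return repr(float(v))
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (list, tuple)):
        return ",".join(str(x) for x in v)
    return str(v)


def _parse_typed(s: str, typ: str):
    if s == MISSING:
        return math.nan if typ == "float" else None
    if typ == "float":
        return float(s)
    if typ == "int":
        return int(s)
    if typ == "bool":
        return s == "true"
    if typ == "list":
        return s.split(",") if s else []
    return s


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation beta values in [0, 1]."""

    values: pd.DataFrame  # index = sample ids, columns = probe ids, float

    def __post_init__(self):
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise TableFormatError(f"duplicate probe id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise TableFormatError(
                f"beta value {vals[i, j]} out of [0, 1] for probe "
                f"{cols[j]!r}, sample {idx[i]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of additive allele dosages in {0, 1, 2}."""

    values: pd.DataFrame  # index = sample ids, columns = variant ids, float (NaN missing)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise TableFormatError("duplicate sample id in genotype matrix")
        if self.values.columns.has_duplicates:
            raise TableFormatError("duplicate variant id in genotype matrix")
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1) | (vals == 2)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise TableFormatError(
                f"dosage {vals[i, j]} not in {{0,1,2}} for variant "
                f"{self.values.columns[j]!r}, sample {self.values.index[i]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.columns)


SAMPLE_COLUMNS = (
    "sex", "age", "pack_years", "smoking_status", "alcohol", "gout",
    "urate_group", "bmi", "hba1c", "total_cholesterol",
)


@dataclass
class SampleTable:
    """Per-sample covariates, phenotypes and (optional) cell proportions.

    Cell-proportion columns are named ``cell_<type>`` and may be filled in
    by the deconvolution stage.
    """

    data: pd.DataFrame  # index = sample id

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise TableFormatError("duplicate sample id in sample table")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"sample table missing columns {missing}")
        bad = set(self.data["smoking_status"].dropna()) - set(SMOKING_LEVELS)
        if bad:
            raise TableFormatError(f"unknown smoking_status {sorted(bad)}")
        bad = set(self.data["urate_group"].dropna()) - set(URATE_GROUPS)
        if bad:
            raise TableFormatError(f"unknown urate_group {sorted(bad)}")
        gg = self.data["urate_group"] == "gout"
        if (self.data.loc[gg, "gout"] != 1).any():
            raise TableFormatError("urate_group 'gout' requires gout flag = 1")
        props = self.cell_columns
        if props:
            w = self.data[props].to_numpy(dtype=float)
            if np.nanmin(w) < -1e-8 or np.nanmax(w) > 1 + 1e-8:
                raise TableFormatError("cell proportions must lie in [0, 1]")
            s = np.nansum(w, axis=1)
            if np.nanmax(s) > 1 + 1e-6:
                raise TableFormatError("cell proportions sum above 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cell_")]

    def with_cell_proportions(self, props: pd.DataFrame) -> "SampleTable":
        """Return a copy whose cell_<type> columns are taken from ``props``."""
        data = self.data.drop(columns=self.cell_columns).copy()
        renamed = props.rename(columns=lambda c: c if c.startswith("cell_") else f"cell_{c}")
        return SampleTable(data.join(renamed, how="left"))


@dataclass
class CpGAnnotation:
    """Probe manifest: genomic position (1-based), gene and feature class."""

    data: pd.DataFrame  # index = probe id
    assembly: str = "hg19"

    def __post_init__(self):
        need = ["chromosome", "position", "gene", "genomic_feature", "cpg_island"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"annotation missing columns {missing}")
        if (self.data["position"] < 1).any():
            raise TableFormatError("annotation positions must be >= 1")
        bad = set(self.data["genomic_feature"]) - set(GENOMIC_FEATURES)
        if bad:
            raise TableFormatError(f"unknown genomic_feature {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def promoter_probes(self) -> list[str]:
        mask = self.data["genomic_feature"].isin(PROMOTER_FEATURES)
        return list(self.data.index[mask])


@dataclass
class VariantAnnotation:
    """Variant manifest: rsid-style id, position and alleles."""

    data: pd.DataFrame  # index = variant id

    def __post_init__(self):
        need = ["chromosome", "position", "ref", "alt"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"variant annotation missing columns {missing}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CandidateTable:
    """Curated candidate CpG table (the published nine-row worked example)."""

    data: pd.DataFrame  # index = probe id

    def __post_init__(self):
        need = [
            "delta_beta_percent", "p", "chromosome", "position", "gene",
            "genomic_feature", "meqtl_flag", "cit_flag", "category",
            "il1b_direction",
        ]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"candidate table missing columns {missing}")
        y = self.data["meqtl_flag"] == "Y"
        if (self.data.loc[y, "cit_flag"] != "not_applicable").any():
            raise TableFormatError(
                "meqtl_flag Y (no shared variant) requires cit_flag not_applicable"
            )
        bad = set(self.data["category"]) - set(CANDIDATE_CATEGORIES)
        if bad:
            raise TableFormatError(f"unknown candidate category {sorted(bad)}")


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------

def _read_numeric_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, comment="#")
    cols = {}
    for col in raw.columns:
        converted = []
        for rid, s in raw[col].items():
            if s == MISSING or s == "":
                converted.append(np.nan)
                continue
            try:
                converted.append(float(s))
            except ValueError:
                raise TableFormatError(
                    f"non-numeric cell {s!r} at row {rid!r}, column {col!r} in {path}"
                ) from None
        cols[col] = converted
    out = pd.DataFrame(cols, index=raw.index.astype(str))
    out.index.name = None
    out.columns.name = None
    return out


def read_beta_matrix(path, orientation_hint: str = "probes_by_samples") -> BetaMatrix:
    """Read a tab-separated beta matrix.

    ``orientation_hint`` says which axis of the file is which:
    ``probes_by_samples`` (rows are probes, the conventional layout) or
    ``samples_by_probes``.
    """
    if orientation_hint not in ("probes_by_samples", "samples_by_probes"):
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    df = _read_numeric_table(path)
    if orientation_hint == "probes_by_samples":
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    """Write in the canonical probes-by-samples dialect."""
    _write_matrix(bm.values.T, "probe_id", path)


def _write_matrix(df: pd.DataFrame, index_name: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(index_name + "\t" + "\t".join(map(str, df.columns)) + "\n")
        vals = df.to_numpy()
        for rid, row in zip(df.index, vals):
            fh.write(str(rid) + "\t" + "\t".join(_fmt_value(v) for v in row) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field, biallelic records only) or a
    tab-separated dosage table (rows = variants, columns = samples)."""
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return _read_genotypes_vcf(path)
    df = _read_numeric_table(path)  # variants x samples
    return GenotypeMatrix(df.T)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise TableFormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # gts012=True: 0/1/2 = alt-allele count, 3 = missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        ids.append(vid)
        rows.append(g)
    vcf.close()
    df = pd.DataFrame(rows, index=ids, columns=samples)
    return GenotypeMatrix(df.T)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the canonical variants-by-samples dosage table."""
    _write_matrix(gm.values.T, "variant_id", path)


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    df.index = df.index.astype(str)
    numeric = {"sex", "age", "pack_years", "alcohol", "gout", "bmi",
               "hba1c", "total_cholesterol"}
    cols = {}
    for col in df.columns:
        if col in numeric or col.startswith("cell_"):
            cols[col] = [np.nan if s in (MISSING, "") else float(s) for s in df[col]]
        else:
            cols[col] = [None if s in (MISSING, "") else s for s in df[col]]
    out = pd.DataFrame(cols, index=df.index)
    out.index.name = None
    return SampleTable(out)


def write_sample_table(st: SampleTable, path) -> None:
    _write_matrix(st.data, "sample_id", path)


def read_cpg_annotation(path, assembly: str = "hg19") -> CpGAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    df.index = df.index.astype(str)
    df["position"] = df["position"].astype(int)
    df["cpg_island"] = df["cpg_island"] == "true"
    return CpGAnnotation(df, assembly=assembly)


def write_cpg_annotation(ann: CpGAnnotation, path) -> None:
    _write_matrix(ann.data, "probe_id", path)


def read_variant_annotation(path) -> VariantAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    df.index = df.index.astype(str)
    df["position"] = df["position"].astype(int)
    return VariantAnnotation(df)


def write_variant_annotation(ann: VariantAnnotation, path) -> None:
    _write_matrix(ann.data, "variant_id", path)


# ---------------------------------------------------------------------------
# generic results tables (record collections)
# ---------------------------------------------------------------------------

def _record_schema(rec) -> list[tuple[str, str]]:
    schema = []
    for f in dc_fields(rec):
        v = getattr(rec, f.name)
        if isinstance(v, (bool, np.bool_)):
            t = "bool"
        elif isinstance(v, (int, np.integer)):
            t = "int"
        elif isinstance(v, (float, np.floating)) or v is None:
            t = "float" if isinstance(v, (float, np.floating)) else "str"
        elif isinstance(v, (list, tuple)):
            t = "list"
        else:
            t = "str"
        schema.append((f.name, t))
    return schema


def write_results_table(records: Sequence, path, columns: list[str] | None = None) -> None:
    """Write a record collection (dataclasses or a DataFrame) as TSV.

    Column order is deterministic (dataclass field order, or the given
    ``columns``); a ``# schema:`` comment line records column types so the
    file can be read back losslessly.
    """
    if isinstance(records, pd.DataFrame):
        recs_df = records if columns is None else records[columns]
        schema = []
        for c in recs_df.columns:
            kind = recs_df[c].dtype.kind
            t = {"f": "float", "i": "int", "b": "bool"}.get(kind, "str")
            schema.append((c, t))
        rows = recs_df.itertuples(index=False)
    else:
        records = list(records)
        if records and not is_dataclass(records[0]):
            raise TypeError("records must be dataclass instances or a DataFrame")
        if records:
            schema = _record_schema(records[0])
        elif columns is not None:
            schema = [(c, "str") for c in columns]
        else:
            schema = []
        rows = (tuple(getattr(r, name) for name, _ in schema) for r in records)
    with open(path, "w") as fh:
        fh.write("# schema: " + " ".join(f"{n}:{t}" for n, t in schema) + "\n")
        fh.write("\t".join(n for n, _ in schema) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt_value(v) for v in row) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_results_table`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# schema:"):
            raise TableFormatError(f"{path} lacks a schema header")
        schema = [tuple(tok.rsplit(":", 1)) for tok in header[len("# schema:"):].split()]
        names = fh.readline().rstrip("\n").split("\t") if schema else []
        rows = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            rows.append([_parse_typed(c, t) for c, (_, t) in zip(cells, schema)])
    df = pd.DataFrame(rows, columns=[n for n, _ in schema] if schema else None)
    if df.empty and schema:
        df = pd.DataFrame({n: pd.Series(dtype=float if t == "float" else object)
                           for n, t in schema})
    return df


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _resource_bytes(name: str) -> bytes:
    return importlib_resources.files("methmediate.resources").joinpath(name).read_bytes()


def load_candidate_fixture() -> CandidateTable:
    """Load the packaged nine-row candidate CpG table (the published worked
    example: promoter CpGs mapped to IL-1β / gouty-inflammation genes)."""
    raw = _resource_bytes("table1_candidates.tsv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CANDIDATE_FIXTURE_SHA256:
        raise TableFormatError(
            f"candidate fixture checksum mismatch ({digest}); resource corrupted"
        )
    df = pd.read_csv(io.BytesIO(raw), sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df["delta_beta_percent"] = df["delta_beta_percent"].astype(float)
    df["p"] = df["p"].astype(float)
    df["position"] = df["position"].astype(int)
    return CandidateTable(df)


def load_curated_gene_config() -> dict:
    """Curated IL-1β / gouty-inflammation gene list plus the shared-variant
    replay map used by the fixture-mode pipeline."""
    import yaml

    return yaml.safe_load(_resource_bytes("candidate_genes.yaml"))
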