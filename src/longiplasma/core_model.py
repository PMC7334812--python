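"""Domain containers, validation and plain-text IO.

The central object is :class:`ProteinDataset`: a samples x antibodies
intensity matrix (raw MFI, log, or normalized scale) carried together with
per-sample metadata (individual, visit, collection date, plate, assay
batch, technical-replicate link).  Genotypes travel as
:class:`GenotypeMatrix` (individuals x SNPs additive dosage, oriented to
the minor allele, with per-SNP coordinates and gene windows), clinical
traits as a ``(individual_id, visit)``-indexed DataFrame.

All files are plain text: TSV for matrices and metadata, VCF or dosage TSV
for genotypes, BED4 for gene windows.  Genomic coordinates are held
1-based inclusive internally (the VCF convention); BED input is converted
at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "sample_id",
    "individual_id",
    "visit",
    "collection_date",
    "plate_id",
    "assay_batch",
    "replicate_of",
]

SCALE_TAGS = ("raw", "log", "normalized")


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class ProteinDataset:
    """Sample x antibody intensity matrix with aligned sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by ``sample_id`` with one column per antibody.
        Positive reals on the ``raw`` scale, finite reals on ``log`` /
        ``normalized`` scales (missing cells allowed only after
        normalization, where upstream QC may have removed them).
    meta
        DataFrame indexed by ``sample_id`` with columns ``individual_id``,
        ``visit`` (1..V), ``collection_date``, ``plate_id``,
        ``assay_batch`` and ``replicate_of`` (the sample this row is a
        duplicate technical assay of, or NA).
    scale_tag
        One of ``raw``, ``log``, ``normalized``.
    target_map
        Optional antibody id -> gene symbol mapping.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    scale_tag: str = "raw"
    target_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.intensities.columns.duplicated().any():
            dups = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValidationError(f"duplicated antibody ids: {list(dups)}")
        if self.intensities.index.duplicated().any():
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValidationError(f"duplicated sample_id: {list(dups)}")
        if len(self.intensities) != len(self.meta):
            raise ValidationError(
                f"{len(self.intensities)} intensity rows vs {len(self.meta)} meta rows"
            )
        if not self.intensities.index.equals(self.meta.index):
            raise ValidationError("intensity rows and metadata rows are not aligned")
        visits = self.meta["visit"]
        bad = visits[(visits < 1) | ~np.isfinite(visits)]
        if len(bad):
            raise ValidationError(f"visit outside 1..V for sample(s) {list(bad.index[:5])}")
        vals = self.intensities.to_numpy(dtype=float)
        if self.scale_tag == "raw":
            if np.isnan(vals).any():
                raise ValidationError("missing cells are not allowed in raw data")
            if (vals <= 0).any():
                i, j = np.argwhere(vals <= 0)[0]
                raise ValidationError(
                    "non-positive raw MFI at sample "
                    f"{self.intensities.index[i]!r}, antibody {self.intensities.columns[j]!r}"
                )
        else:
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite values on {self.scale_tag} scale")
        # collection_date non-decreasing in visit within an individual
        m = self.meta.copy()
        m["collection_date"] = pd.to_datetime(m["collection_date"])
        for ind, grp in m.groupby("individual_id", sort=False):
            grp = grp.sort_values("visit")
            if grp["collection_date"].is_monotonic_increasing is False:
                raise ValidationError(
                    f"collection_date decreases across visits for individual {ind!r}"
                )
        key = m.loc[m["replicate_of"].isna(), ["individual_id", "visit", "assay_batch"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"(individual, visit, assay_batch) not unique: {tuple(dup)}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def days_since_first_visit(self) -> pd.Series:
        """Per-sample time covariate: days since the individual's first visit."""
        dates = pd.to_datetime(self.meta["collection_date"])
        first = dates.groupby(self.meta["individual_id"]).transform("min")
        return (dates - first).dt.days.astype(float)

    def with_values(self, values: pd.DataFrame, scale_tag: str) -> "ProteinDataset":
        """New dataset sharing this metadata but with replaced values."""
        return ProteinDataset(
            intensities=values,
            meta=self.meta.copy(),
            scale_tag=scale_tag,
            target_map=dict(self.target_map),
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with SNP coordinates.

    ``dosages`` is indexed by individual id; entries are in ``[0, 2]``
    counting the minor allele.  ``snp_info`` is indexed by SNP id with
    columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and ``maf``.
    ``gene_windows`` maps gene symbol -> ``(chrom, start, end)``, 1-based
    inclusive.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame
    gene_windows: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snp_info.index):
            raise ValidationError("dosage columns and snp_info rows are not aligned")
        maf = self.snp_info["maf"].to_numpy(dtype=float)
        if ((maf < 0) | (maf > 0.5 + 1e-12)).any():
            raise ValidationError("MAF outside [0, 0.5]; orient dosages to the minor allele")
        if (self.snp_info["pos"] <= 0).any():
            raise ValidationError("SNP positions must be positive (1-based)")
        for gene, (chrom, start, end) in self.gene_windows.items():
            if start <= 0 or end < start:
                raise ValidationError(f"bad window for {gene}: {chrom}:{start}-{end}")

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def orient_to_minor_allele(dosages: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Flip dosage columns so the counted allele is the minor one.

    Returns the oriented matrix and the per-SNP MAF computed from data.
    """
    freq = dosages.mean(axis=0).to_numpy() / 2.0
    flip = freq > 0.5
    out = dosages.copy()
    if flip.any():
        out.loc[:, flip] = 2.0 - out.loc[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)
    return out, maf


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_protein_dataset(intensity_path: str | Path, meta_path: str | Path) -> ProteinDataset:
    """Read a raw intensity TSV plus a sample-metadata TSV.

    The intensity table's first column must be ``sample_id``; remaining
    columns are antibody ids.  Samples present in the metadata but absent
    from the intensity table are dropped with a logged warning; the
    converse is an error.  Row order of the intensity table is preserved.
    """
    inten = pd.read_csv(intensity_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in inten.columns:
        raise ValidationError("intensity table must have a sample_id column")
    if inten["sample_id"].duplicated().any():
        dups = inten.loc[inten["sample_id"].duplicated(), "sample_id"]
        raise ValidationError(f"duplicate sample_id in intensity table: {list(dups)}")
    inten = inten.set_index("sample_id")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    meta["visit"] = meta["visit"].astype(int)
    meta["replicate_of"] = meta["replicate_of"].replace({"": None, "NA": None})

    unknown = inten.index.difference(meta.index)
    if len(unknown):
        raise ValidationError(f"samples without metadata: {list(unknown[:5])}")
    extra = meta.index.difference(inten.index)
    if len(extra):
        logger.warning("dropping %d metadata rows without intensities: %s",
                       len(extra), list(extra[:5]))
    meta = meta.loc[inten.index]
    return ProteinDataset(intensities=inten.astype(float), meta=meta, scale_tag="raw")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a clinical-trait TSV keyed by (individual_id, visit).

    Non-key columns are coerced to numeric where possible; columns that
    resist coercion (e.g. sex category) are kept as strings.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    for col in ("individual_id", "visit"):
        if col not in df.columns:
            raise ValidationError(f"trait table must have a {col} column")
    df["visit"] = df["visit"].astype(int)
    df = df.set_index(["individual_id", "visit"])
    if df.index.duplicated().any():
        raise ValidationError("duplicate (individual_id, visit) in trait table")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.notna().sum() >= df[col].notna().sum():
                df[col] = coerced
    return df


def read_bed_windows(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read BED4 gene windows, converting 0-based half-open to 1-based inclusive."""
    windows: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"BED4 line with <4 fields: {line!r}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            windows[name] = (chrom, start + 1, end)
    return windows


def read_genotypes(
    path: str | Path,
    gene_window_path: str | Path | None = None,
    individuals: list[str] | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    Multi-allelic VCF records are skipped (count logged).  Dosages are
    oriented so the counted allele is the minor allele and MAF is computed
    from the data.  If ``individuals`` is given, an empty intersection
    with the file's samples is an error.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or str(path).endswith((".vcf.gz", ".vcf")):
        dosages, info = _read_vcf(path)
    else:
        dosages, info = _read_dosage_tsv(path)

    if individuals is not None:
        keep = [i for i in dosages.index if i in set(individuals)]
        if not keep:
            raise ValidationError("no overlap between genotype samples and dataset individuals")
        dosages = dosages.loc[keep]

    dosages, maf = orient_to_minor_allele(dosages)
    info = info.copy()
    info["maf"] = maf
    windows = read_bed_windows(gene_window_path) if gene_window_path else {}
    return GenotypeMatrix(dosages=dosages, snp_info=info, gene_windows=windows)


def _read_vcf(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    rows = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds_field = var.format("DS")
        except KeyError:
            ds_field = None
        if ds_field is not None:
            ds = np.asarray(ds_field, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 3 hom-alt
            ds = np.where(gts == 3, 2.0, gts)
            ds[gts == 2] = np.nan  # unknown
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        cols.append(ds)
    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise ValidationError(f"no biallelic records in {path}")
    ids = [r[0] for r in rows]
    dosages = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    info = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    ).set_index("snp_id")
    return dosages, info


def _read_dosage_tsv(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage TSV: columns individual_id then SNP ids; a sidecar ``.snps.tsv``
    file (columns snp_id, chrom, pos, ref, alt) provides coordinates."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}).set_index("individual_id")
    sidecar = path.with_suffix("").with_suffix(".snps.tsv") if path.suffix else None
    info_path = Path(str(path).rsplit(".", 1)[0] + ".snps.tsv")
    if info_path.exists():
        info = pd.read_csv(info_path, sep="\t", dtype={"snp_id": str}).set_index("snp_id")
        info = info.loc[df.columns]
    else:
        info = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, df.shape[1] + 1), "ref": "A", "alt": "B"},
            index=pd.Index(df.columns, name="snp_id"),
        )
    return df.astype(float), info


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "1.0"
_FLOAT_FMT = "%.10g"  # 10 significant digits


def write_dataset(ds: ProteinDataset, intensity_path: str | Path, meta_path: str | Path) -> None:
    """Write a dataset back to the intensity + metadata TSV pair."""
    out = ds.intensities.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(intensity_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = ds.meta.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(meta_path, sep="\t", index=False)


def write_report(report: pd.DataFrame | Mapping, path: str | Path) -> None:
    """Serialize a result table to TSV, or any mapping/table to JSON.

    Column order is preserved deterministically; floats use 10 significant
    digits.  The JSON variant carries a ``schema_version`` field.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = {"schema_version": SCHEMA_VERSION}
        if isinstance(report, pd.DataFrame):
            payload["columns"] = list(report.columns)
            payload["records"] = json.loads(
                report.to_json(orient="records", double_precision=10)
            )
        else:
            payload.update({k: _jsonable(v) for k, v in dict(report).items()})
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
    else:
        if not isinstance(report, pd.DataFrame):
            report = pd.DataFrame(report)
        report.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, pd.DataFrame):
        return json.loads(v.to_json(orient="records", double_precision=10))
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
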