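"""Data model and file I/O shared by every analysis stage.

The universal container is :class:`ExpressionStudy`: a genes x samples
nonnegative matrix plus per-sample design metadata (line, donor, culture
condition, day, replicate).  All on-disk formats are plain tab-separated
text; numeric output is written at 6 significant digits, UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("SR", "NSB", "BMP4", "other")

FLOAT_FMT = "%.6g"


class StudyError(ValueError):
    """Raised on malformed expression data or metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one RNA-seq (or external) sample."""

    sample_id: str
    line_id: str
    donor_id: str
    condition: str
    day: int
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise StudyError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.day < 0:
            raise StudyError(f"day must be nonnegative, got {self.day}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Optional per-gene annotations: evolutionary era and dosage sensitivity."""

    gene_id: str
    era: int | None = None
    phaplo: float | None = None
    set_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.era is not None and not 1 <= self.era <= 5:
            raise StudyError(f"era must be in 1..5, got {self.era}")
        if self.phaplo is not None and not 0.0 <= self.phaplo <= 1.0:
            raise StudyError(f"phaplo must be in [0,1], got {self.phaplo}")


@dataclass
class ExpressionStudy:
    """Genes x samples expression matrix with aligned sample metadata.

    Parameters
    ----------
    values
        Nonnegative (genes, samples) array; counts or normalized units.
    gene_ids
        Unique gene identifiers, one per row.
    samples
        One :class:`SampleMeta` per column, in column order.
    scale
        One of ``counts``, ``rpkm``, ``log2rpkm`` (or ``other`` for
        external signal matrices such as promoter-level ChIP signal).
    """

    values: np.ndarray
    gene_ids: list[str]
    samples: list[SampleMeta]
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise StudyError("values must be 2-D (genes x samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise StudyError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.samples):
            raise StudyError(
                f"{self.values.shape[1]} columns but {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise StudyError(f"duplicate gene ids: {dupes[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise StudyError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise StudyError("non-finite expression values")
        if self.scale != "other" and np.any(self.values < 0):
            raise StudyError("negative expression values")
        if self.scale == "counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise StudyError("scale='counts' requires integral values")
        donor_of: dict[str, str] = {}
        for s in self.samples:
            if donor_of.setdefault(s.line_id, s.donor_id) != s.donor_id:
                raise StudyError(
                    f"line {s.line_id} mapped to multiple donors"
                )

    # -- convenience ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "line_id": [s.line_id for s in self.samples],
                "donor_id": [s.donor_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "day": [s.day for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "ExpressionStudy":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionStudy(
            values=self.values[:, keep],
            gene_ids=list(self.gene_ids),
            samples=[self.samples[i] for i in keep],
            scale=self.scale,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _meta_from_frame(meta: pd.DataFrame) -> dict[str, SampleMeta]:
    required = {"sample_id", "line_id", "donor_id", "condition", "day"}
    missing = required - set(meta.columns)
    if missing:
        raise StudyError(f"metadata missing columns: {sorted(missing)}")
    out = {}
    for row in meta.itertuples(index=False):
        sm = SampleMeta(
            sample_id=str(row.sample_id),
            line_id=str(row.line_id),
            donor_id=str(row.donor_id),
            condition=str(row.condition),
            day=int(row.day),
            replicate=str(getattr(row, "replicate", "r1")),
        )
        if sm.sample_id in out:
            raise StudyError(f"duplicate sample id in metadata: {sm.sample_id}")
        out[sm.sample_id] = sm
    return out


def read_expression(path: str | Path, metadata_path: str | Path,
                    scale: str = "rpkm") -> ExpressionStudy:
    """Read an expression TSV (gene-id column + sample columns) and its metadata.

    Samples present in the matrix but absent from the metadata raise an
    error naming the sample; extra metadata rows are ignored.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        raise StudyError(
            f"duplicate gene ids in {path}: "
            f"{sorted(mat.index[mat.index.duplicated()].unique())[:5]}"
        )
    bad = [c for c in mat.columns if not pd.api.types.is_numeric_dtype(mat[c])]
    if bad:
        raise StudyError(f"non-numeric cells in columns {bad[:5]} of {path}")
    meta = _meta_from_frame(pd.read_csv(metadata_path, sep="\t", dtype=str))
    samples = []
    for sid in mat.columns:
        if sid not in meta:
            raise StudyError(f"sample {sid!r} missing from metadata")
        samples.append(meta[sid])
    return ExpressionStudy(
        values=mat.to_numpy(dtype=float),
        gene_ids=[str(g) for g in mat.index],
        samples=samples,
        scale=scale,
    )


def write_expression(study: ExpressionStudy, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    study.to_frame().rename_axis("gene_id").to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )
    if metadata_path is not None:
        study.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> description <tab> gene...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise StudyError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read per-gene annotation TSV with columns gene_id[, era][, phaplo]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        era = getattr(row, "era", None)
        era = None if era is None or pd.isna(era) else int(era)
        ph = getattr(row, "phaplo", None)
        ph = None if ph is None or pd.isna(ph) else float(ph)
        out.append(GeneAnnotation(gene_id=str(row.gene_id), era=era, phaplo=ph))
    return out


def write_annotations(annotations: Sequence[GeneAnnotation],
                      path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "era": [a.era for a in annotations],
            "phaplo": [a.phaplo for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_kinship(path: str | Path) -> pd.DataFrame:
    k = pd.read_csv(path, sep="\t", index_col=0)
    if list(k.index) != list(k.columns):
        raise StudyError("kinship matrix must be square with matching labels")
    arr = k.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise StudyError("kinship matrix must be symmetric")
    return k


def write_kinship(kinship: pd.DataFrame, path: str | Path) -> None:
    kinship.rename_axis("id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_phenotypes(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.line_id): float(r.phenotype) for r in df.itertuples(index=False)}


def write_phenotypes(pheno: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"line_id": list(pheno), "phenotype": list(pheno.values())}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# normalization / gene matching
# ---------------------------------------------------------------------------


def rpkm_normalize(study: ExpressionStudy,
                   gene_lengths: Mapping[str, float]) -> ExpressionStudy:
    """Reads-per-kilobase-per-million normalization of a count matrix.

    ``rpkm[g, s] = counts[g, s] / (length_kb[g] * mapped_millions[s])`` with
    the library size taken as the column sum of the supplied count matrix.
    """
    if study.scale != "counts":
        raise StudyError(f"rpkm_normalize requires counts, got {study.scale!r}")
    missing = [g for g in study.gene_ids if g not in gene_lengths]
    if missing:
        raise StudyError(f"missing gene lengths, e.g. {missing[:5]}")
    lengths = np.array([gene_lengths[g] for g in study.gene_ids], dtype=float)
    if np.any(lengths <= 0):
        raise StudyError("gene lengths must be positive")
    colsum = study.values.sum(axis=0)
    if np.any(colsum <= 0):
        zero = [study.sample_ids[i] for i in np.flatnonzero(colsum <= 0)]
        raise StudyError(f"zero column sum for samples {zero}")
    rpkm = study.values / (lengths[:, None] / 1e3) / (colsum[None, :] / 1e6)
    return ExpressionStudy(rpkm, study.gene_ids, study.samples, scale="rpkm")


def log_transform(study: ExpressionStudy, pseudocount: float = 1.0) -> ExpressionStudy:
    """Monotone log2(value + pseudocount) transform."""
    if np.any(study.values < 0):
        raise StudyError("log_transform requires nonnegative values")
    return ExpressionStudy(
        np.log2(study.values + pseudocount),
        study.gene_ids,
        study.samples,
        scale="log2rpkm",
    )


def match_genes(a: ExpressionStudy, b: ExpressionStudy
                ) -> tuple[ExpressionStudy, ExpressionStudy]:
    """Restrict two studies to their gene-id intersection, identical order.

    Matching is by exact, case-sensitive identifier; order follows the
    first study. Raises on an empty intersection.
    """
    in_b = set(b.gene_ids)
    shared = [g for g in a.gene_ids if g in in_b]
    if not shared:
        raise StudyError("no shared gene identifiers")
    a_idx = {g: i for i, g in enumerate(a.gene_ids)}
    b_idx = {g: i for i, g in enumerate(b.gene_ids)}
    ai = [a_idx[g] for g in shared]
    bi = [b_idx[g] for g in shared]
    a2 = ExpressionStudy(a.values[ai], shared, a.samples, a.scale)
    b2 = ExpressionStudy(b.values[bi], list(shared), b.samples, b.scale)
    return a2, b2


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
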