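"""Readers, writers and validated containers for the tables the pipeline touches.

Counts are genes x samples (TSV or MatrixMarket triplet), sample metadata and
gene annotation are TSV, annotation may also come from a GFF3 subset.
Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted on read and restored on write.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

SEXES = ("female", "male")
HETEROGAMETY = ("XY", "ZW", "unknown")

#: chromosome-name patterns used to flag mitochondrial / unplaced genes when
#: the annotation does not carry explicit flags
MITO_CHROM_PATTERNS = (r"^MT$", r"^chrM(T)?$", r"^mito", r"^mtDNA$")
UNPLACED_CHROM_PATTERNS = (r"scaffold", r"^unplaced", r"^chrUn", r"_random$", r"^contig")


class FormatError(ValueError):
    """A file violated the contract of its format (bad value, duplicate id, ...)."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: pd.Index
    sample_ids: pd.Index
    counts: np.ndarray  # int64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.sample_ids = pd.Index(self.sample_ids, name="sample_id")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.sample_ids.has_duplicates:
            dups = self.sample_ids[self.sample_ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = ~np.isclose(counts, rounded, atol=1e-9)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer count {counts[g, s]!r} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count {counts[g, s]} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.index, df.columns, df.to_numpy())

    def subset_genes(self, keep: Sequence) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.gene_ids.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5].tolist()
                raise KeyError(f"genes not in matrix: {missing}")
        return CountMatrix(self.gene_ids[idx], self.sample_ids, self.counts[idx])

    def subset_samples(self, keep: Sequence) -> "CountMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0][:5].tolist()
            raise KeyError(f"samples not in matrix: {missing}")
        return CountMatrix(self.gene_ids, self.sample_ids[idx], self.counts[:, idx])


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: first column gene ids, header row sample ids. ``mtx``: a
    MatrixMarket triplet file with sibling ``<stem>.rows`` / ``<stem>.cols``
    id files (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return CountMatrix(df.index, df.columns.astype(str), df.to_numpy())
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        gene_ids = Path(f"{stem}.rows").read_text().split()
        sample_ids = Path(f"{stem}.cols").read_text().split()
        return CountMatrix(pd.Index(gene_ids), pd.Index(sample_ids), np.asarray(mat))
    raise ValueError(f"unknown counts format {format!r} (expected 'tsv' or 'mtx')")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.rows").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
        Path(f"{stem}.cols").write_text("\n".join(map(str, cm.sample_ids)) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# sample metadata


def validate_samples(samples: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    required = {"sample_id", "species", "sex", "tissue", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    samples = samples.copy()
    samples["sample_id"] = samples["sample_id"].astype(str)
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample table")
    bad_sex = set(samples["sex"]) - set(SEXES)
    if bad_sex:
        raise FormatError(f"sex values outside {SEXES}: {sorted(bad_sex)}")
    if counts is not None:
        unknown = set(samples["sample_id"]) - set(counts.sample_ids)
        if unknown:
            raise FormatError(f"sample ids absent from count matrix: {sorted(unknown)[:5]}")
    return samples


def read_samples(path: str | Path, counts: CountMatrix | None = None) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t", dtype={"sample_id": str}), counts)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "species", "sex", "tissue", "replicate"]
    extra = [c for c in samples.columns if c not in cols]
    samples[cols + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation


def _matches_any(name: str, patterns: Iterable[str]) -> bool:
    return any(re.search(p, name, flags=re.IGNORECASE) for p in patterns)


def validate_annotation(
    ann: pd.DataFrame,
    counts: CountMatrix | None = None,
    mito_patterns: Sequence[str] = MITO_CHROM_PATTERNS,
    unplaced_patterns: Sequence[str] = UNPLACED_CHROM_PATTERNS,
) -> pd.DataFrame:
    """Normalise an annotation frame: fill length and the mito/unplaced flags.

    Explicit ``is_mitochondrial`` / ``is_placed`` columns win; otherwise flags
    fall back to chromosome-name pattern matching (configurable).
    """
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    ann = ann.copy()
    ann["gene_id"] = ann["gene_id"].astype(str)
    if ann["gene_id"].duplicated().any():
        raise FormatError("duplicate gene_id in annotation")
    if "length" not in ann.columns:
        ann["length"] = ann["end"] - ann["start"]
    bad = ann["length"] <= 0
    if bad.any():
        raise FormatError(f"genes with length <= 0: {ann.loc[bad, 'gene_id'].tolist()[:5]}")
    chrom = ann["chromosome"].astype(str)
    if "is_mitochondrial" not in ann.columns:
        ann["is_mitochondrial"] = chrom.map(lambda c: _matches_any(c, mito_patterns))
    else:
        ann["is_mitochondrial"] = ann["is_mitochondrial"].astype(bool)
    if "is_placed" not in ann.columns:
        ann["is_placed"] = ~chrom.map(lambda c: _matches_any(c, unplaced_patterns))
    else:
        ann["is_placed"] = ann["is_placed"].astype(bool)
    if counts is not None:
        missing_genes = set(map(str, counts.gene_ids)) - set(ann["gene_id"])
        if missing_genes:
            raise FormatError(
                f"annotation missing {len(missing_genes)} counted genes, e.g. "
                f"{sorted(missing_genes)[:5]}"
            )
    return ann.reset_index(drop=True)


def read_annotation(
    path: str | Path,
    dialect: str = "tsv",
    counts: CountMatrix | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Read gene annotation from a BED-like TSV or a GFF3 subset.

    TSV columns: gene_id, chromosome, start, end[, length, is_mitochondrial,
    is_placed]; coordinates already 0-based half-open. GFF3 ``gene`` features
    are converted from 1-based inclusive to 0-based half-open; the gene id is
    taken from the ``ID`` attribute.
    """
    path = Path(path)
    if dialect == "tsv":
        ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        return validate_annotation(ann, counts, **kwargs)
    if dialect == "gff3":
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].rstrip(";").split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"gene feature without ID attribute: {line!r}")
            rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": parts[0],
                    # GFF3 1-based inclusive -> 0-based half-open
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                }
            )
        return validate_annotation(pd.DataFrame(rows), counts, **kwargs)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotation(ann: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        cols = ["gene_id", "chromosome", "start", "end", "length", "is_mitochondrial", "is_placed"]
        ann[cols].to_csv(path, sep="\t", index=False)
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in ann.itertuples():
                # restore 1-based inclusive coordinates
                fh.write(
                    f"{row.chromosome}\t.\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                    f"ID={row.gene_id}\n"
                )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sex systems


def validate_sex_systems(table: pd.DataFrame) -> pd.DataFrame:
    required = {"species", "heterogamety", "sex_linked_chromosomes"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"sex-system table missing columns: {sorted(missing)}")
    table = table.copy()
    bad = set(table["heterogamety"]) - set(HETEROGAMETY)
    if bad:
        raise FormatError(f"heterogamety outside {HETEROGAMETY}: {sorted(bad)}")

    def _to_list(v):
        if isinstance(v, (list, tuple)):
            return list(v)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "-"):
            return []
        return [c.strip() for c in str(v).split(",") if c.strip()]

    table["sex_linked_chromosomes"] = table["sex_linked_chromosomes"].map(_to_list)
    unknown_with_chroms = table[
        (table["heterogamety"] == "unknown")
        & table["sex_linked_chromosomes"].map(len).astype(bool)
    ]
    if len(unknown_with_chroms):
        raise FormatError(
            "species with unknown heterogamety must not declare sex-linked "
            f"chromosomes: {unknown_with_chroms['species'].tolist()}"
        )
    return table.reset_index(drop=True)


def read_sex_systems(path: str | Path) -> pd.DataFrame:
    return validate_sex_systems(pd.read_csv(path, sep="\t"))


def write_sex_systems(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["sex_linked_chromosomes"] = out["sex_linked_chromosomes"].map(
        lambda v: ",".join(v) if isinstance(v, (list, tuple)) else v
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write result tables as TSV plus a JSON run summary.

    Column order is whatever the table carries (the pipeline constructs them
    deterministically), floats are written with full precision, and the
    summary records seed/thresholds so a run can be audited.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    if metadata is not None:
        p = out_dir / "run_summary.json"
        with open(p, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=_json_default)
        written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
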