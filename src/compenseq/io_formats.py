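"""Reading and writing the pipeline's external representations.

All tables are genes-in-rows, samples-in-columns. Gene and sample
identifiers are opaque strings; no symbol/accession mapping is attempted.
Canonical on-disk formats: TSV count matrices (first column = gene id,
header row = sample ids), MatrixMarket with plain-text id sidecars, GMT
gene-set collections and TSV result tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

#: The three strain roles of the study design: progenitor (W), the derived
#: seizure-prone strain (KM) and the strain back-selected from their hybrids
#: for absence of the phenotype (ZERO, written "0" in sample sheets).
ROLES = ("W", "KM", "ZERO")

_ROLE_ALIASES = {"W": "W", "KM": "KM", "ZERO": "ZERO", "0": "ZERO"}


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class CountTable:
    """Integer gene x sample count matrix.

    Invariants: unique gene and sample ids, non-negative integer counts,
    matrix dimensions matching the id lists.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = ~np.isclose(self.counts, rounded, atol=1e-9) | ~np.isfinite(
                self.counts
            )
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {self.counts[g, s]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, mask_or_ids) -> "CountTable":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids], dtype=int)
        return CountTable(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )


@dataclass
class SampleSheet:
    """Assignment of every sample to one of the three strain roles."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for sample, role in self.assignments.items():
            key = str(role).strip().upper()
            if key not in _ROLE_ALIASES:
                raise ValidationError(
                    f"sample {sample!r}: unknown group {role!r} "
                    f"(expected one of W, KM, ZERO/0)"
                )
            clean[str(sample)] = _ROLE_ALIASES[key]
        self.assignments = clean

    def samples_for(self, role: str) -> list[str]:
        role = _ROLE_ALIASES[str(role).strip().upper()]
        return [s for s, r in self.assignments.items() if r == role]

    def group_sizes(self) -> dict[str, int]:
        return {role: len(self.samples_for(role)) for role in ROLES}

    def validate_against(self, counts: CountTable, min_per_role: int = 2) -> None:
        missing = [s for s in counts.sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        for role, n in self.group_sizes().items():
            if n < min_per_role:
                raise ValidationError(
                    f"group {role} has {n} sample(s); >= {min_per_role} required"
                )

    def indices(self, counts: CountTable, role: str) -> np.ndarray:
        wanted = set(self.samples_for(role))
        return np.array(
            [i for i, s in enumerate(counts.sample_ids) if s in wanted], dtype=int
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, ordered member list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_counts(path: str, dialect: str = "tsv") -> CountTable:
    """Read a count matrix.

    ``tsv``: header row of sample ids, first column of gene ids.
    ``mtx``: MatrixMarket file accompanied by ``<path>.genes.txt`` and
    ``<path>.samples.txt`` sidecars (one id per line).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in header")
        numeric = df.apply(pd.to_numeric, errors="coerce")
        values = numeric.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-numeric count at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}: {df.iat[g, s]!r}"
            )
        frac = values != np.rint(values)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}: {df.iat[g, s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}: {df.iat[g, s]!r}"
            )
        return CountTable(
            list(df.index), list(df.columns), values.astype(np.int64)
        )
    if dialect == "mtx":
        genes_path, samples_path = path + ".genes.txt", path + ".samples.txt"
        for side in (genes_path, samples_path):
            if not os.path.exists(side):
                raise FileNotFoundError(f"missing MTX sidecar: {side}")
        raw = mmread(path)
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        gene_ids = _read_id_lines(genes_path)
        sample_ids = _read_id_lines(samples_path)
        return CountTable(gene_ids, sample_ids, mat)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_id_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_counts(table: CountTable, path: str, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        df = table.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
    elif dialect == "mtx":
        from scipy.sparse import coo_matrix

        mmwrite(path, coo_matrix(table.counts))
        # mmwrite appends .mtx when absent; mirror that for the sidecars
        target = path if path.endswith(".mtx") else path + ".mtx"
        with open(target + ".genes.txt", "w") as fh:
            fh.write("\n".join(table.gene_ids) + "\n")
        with open(target + ".samples.txt", "w") as fh:
            fh.write("\n".join(table.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sample_sheet(path: str) -> SampleSheet:
    """Two-column TSV: sample_id <tab> group (W / KM / ZERO or 0)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "group" in cols:
        sample_col = df.columns[cols.index("sample_id")]
        group_col = df.columns[cols.index("group")]
    elif df.shape[1] >= 2:
        sample_col, group_col = df.columns[0], df.columns[1]
    else:
        raise ValidationError("sample sheet needs sample_id and group columns")
    return SampleSheet(dict(zip(df[sample_col], df[group_col])))


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    pd.DataFrame(
        {"sample_id": list(sheet.assignments), "group": list(sheet.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB members...

    Duplicate members within a set are dropped, first occurrence kept.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    f"need name, description and at least one member"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_results(table: pd.DataFrame, path: str, float_digits: int = 12) -> None:
    """Write a result table as TSV with full float precision.

    The index is written as the first column when it is named (e.g. gene id).
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    index = table.index.name is not None
    table.to_csv(path, sep="\t", index=index, float_format=f"%.{float_digits}g")


def read_results(path: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
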