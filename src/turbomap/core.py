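"""Core domain containers and tabular I/O.

The pipeline works on log2-scale protein abundance matrices with an explicit
missingness mask, paired with per-sample design metadata (group, batch,
covariates, global-internal-standard flag), clinical trait tables, and flat
gene-set collections (GMT). All identifiers live in a single canonical
namespace: the upper-cased first whitespace-delimited token of the raw
identifier. Set-overlap arithmetic downstream depends on that normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("turbomap")

MISSING_TOKENS = {"", "NA", "NAN", "N/A", "NULL"}


def normalize_id(identifier: str) -> str:
    """Canonical identifier: upper-cased first whitespace token.

    Idempotent; gene symbols and accessions share one namespace so that
    overlap counting is well defined.
    """
    return str(identifier).strip().split()[0].upper()


def normalize_ids(identifiers: Iterable[str]) -> list[str]:
    """Normalize and de-duplicate, preserving first-seen order."""
    seen: dict[str, None] = {}
    for x in identifiers:
        key = normalize_id(x)
        if key:
            seen.setdefault(key)
    return list(seen)


@dataclass
class IntensityMatrix:
    """Proteins x samples log2 abundances with an observedness mask.

    values at masked-out cells are carried (often 0 or NaN) but must never be
    read by downstream code; the mask is the single source of truth for
    observedness.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_proteins, n_samples), float64
    mask: np.ndarray    # same shape, bool, True = observed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_p, n_s = self.values.shape
        if len(self.protein_ids) != n_p or len(self.sample_ids) != n_s:
            raise ValueError("identifier list lengths do not match matrix shape")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if len(set(self.protein_ids)) != n_p:
            raise ValueError("duplicate protein identifiers")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed values must be finite")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            list(self.protein_ids), list(self.sample_ids),
            self.values.copy(), self.mask.copy(),
        )

    def subset_proteins(self, keep: np.ndarray | Sequence[int]) -> "IntensityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return IntensityMatrix(
            [self.protein_ids[i] for i in keep], list(self.sample_ids),
            self.values[keep], self.mask[keep],
        )

    def subset_samples(self, keep: np.ndarray | Sequence[int]) -> "IntensityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return IntensityMatrix(
            list(self.protein_ids), [self.sample_ids[i] for i in keep],
            self.values[:, keep], self.mask[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame with NaN at unobserved cells."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.protein_ids, columns=self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def protein_index(self, protein_id: str) -> int:
        return self.protein_ids.index(protein_id)


@dataclass
class SampleDesign:
    """Per-sample metadata: group, batch, covariates, GIS flag."""

    table: pd.DataFrame  # indexed by sample_id; columns: group, batch, is_gis, covariates...

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample_id in design")
        if "group" not in t.columns:
            raise ValueError("design requires a 'group' column")
        if "batch" not in t.columns:
            self.table = t = t.assign(batch="b1")
        if "is_gis" not in t.columns:
            self.table = t = t.assign(is_gis=False)
        self.table["is_gis"] = self.table["is_gis"].astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> list[str]:
        return list(pd.unique(self.table.loc[~self.table["is_gis"], "group"]))

    def samples_in_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.index[(t["group"] == group) & ~t["is_gis"]])

    def aligned_to(self, m: IntensityMatrix) -> "SampleDesign":
        """Reindex to the matrix's samples; every matrix sample must be present."""
        missing = set(m.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"design missing samples: {sorted(missing)}")
        return SampleDesign(self.table.loc[m.sample_ids].copy())

    def validate_against(self, m: IntensityMatrix) -> None:
        self.aligned_to(m)
        for g in self.groups():
            if not self.samples_in_group(g):
                raise ValueError(f"group {g!r} has no non-GIS samples")


@dataclass
class TraitTable:
    """Sample-level clinical traits (Braak, CERAD, MFTau, diagnosis dummies)."""

    table: pd.DataFrame  # indexed by sample_id, numeric columns

    ORDINAL_RANGES = {"braak": (0, 6)}

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample_id in trait table")
        for col, (lo, hi) in self.ORDINAL_RANGES.items():
            if col in self.table.columns:
                v = self.table[col].dropna()
                if ((v < lo) | (v > hi)).any():
                    raise ValueError(f"trait {col!r} outside [{lo}, {hi}]")

    @property
    def trait_names(self) -> list[str]:
        return list(self.table.columns)

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        return self.table.reindex(sample_ids)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sets:
            if not s.members:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_intensity_table(
    path: str | Path,
    id_column: str | None = None,
    zero_is_missing: bool = True,
) -> IntensityMatrix:
    """Read a delimited protein x sample intensity table.

    First column (or ``id_column``) holds protein identifiers, the header row
    sample names. Blank cells, NA/NaN tokens and (by default) exact zeros
    become unobserved in the mask. Duplicate protein rows collapse to the row
    with the highest total observed intensity, with a warning.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    raw_cols = header.rstrip("\n").split(sep)
    if len(set(raw_cols)) != len(raw_cols):
        raise ValueError(f"duplicate sample names in header of {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     comment="#")
    if id_column is None:
        id_column = df.columns[0]
    sample_ids = [c for c in df.columns if c != id_column]

    raw = df[sample_ids].to_numpy(dtype=object)
    n_rows, n_cols = raw.shape
    values = np.zeros((n_rows, n_cols))
    mask = np.ones((n_rows, n_cols), dtype=bool)
    for j in range(n_cols):
        for i in range(n_rows):
            tok = str(raw[i, j]).strip()
            if tok.upper() in MISSING_TOKENS:
                mask[i, j] = False
                continue
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {tok!r} at row {df[id_column].iloc[i]!r}, "
                    f"column {sample_ids[j]!r} in {path}"
                ) from None
            if zero_is_missing and v == 0.0:
                mask[i, j] = False
            else:
                values[i, j] = v

    ids = [normalize_id(x) for x in df[id_column]]
    if len(set(ids)) != len(ids):
        order = np.argsort(-np.where(mask, values, 0.0).sum(axis=1), kind="stable")
        keep_idx: dict[str, int] = {}
        for i in order:
            keep_idx.setdefault(ids[i], i)
        dropped = n_rows - len(keep_idx)
        logger.warning("collapsed %d duplicate protein rows by max intensity", dropped)
        sel = sorted(keep_idx.values())
        ids = [ids[i] for i in sel]
        values, mask = values[sel], mask[sel]

    return IntensityMatrix(ids, sample_ids, values, mask)


def write_intensity_table(m: IntensityMatrix, path: str | Path,
                          header_meta: str | None = None) -> None:
    """Write TSV/CSV; unobserved cells as 'NA'; values to 12 significant digits."""
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        fh.write(sep.join(["protein"] + m.sample_ids) + "\n")
        for i, pid in enumerate(m.protein_ids):
            cells = [
                f"{m.values[i, j]:.12g}" if m.mask[i, j] else "NA"
                for j in range(m.n_samples)
            ]
            fh.write(sep.join([pid] + cells) + "\n")


def read_design_table(path: str | Path) -> SampleDesign:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return SampleDesign(df)


def write_design_table(d: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    d.table.to_csv(path, sep=_sniff_sep(path), index_label="sample_id")


def read_trait_table(path: str | Path) -> TraitTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return TraitTable(df.apply(pd.to_numeric))


def write_trait_table(t: TraitTable, path: str | Path) -> None:
    path = Path(path)
    t.table.to_csv(path, sep=_sniff_sep(path), index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file: name, description, then members, tab-separated.

    Members are upper-cased and de-duplicated; set order follows the file.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members = normalize_ids(fields[2:])
            sets.append(GeneSet(name, desc, members))
    if not sets:
        logger.warning("GMT file %s is empty", path)
    return GeneSetCollection(sets)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in c:
            fh.write("\t".join([s.name, s.description] + s.members) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; '#' comment lines skipped; normalized, deduped."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line)
    out = normalize_ids(out)
    if not out:
        raise ValueError(f"gene list {path} is empty after filtering")
    return out


def write_gene_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")
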