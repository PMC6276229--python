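"""Readers/writers for the tabular formats used across the pipeline.

Matrices are TSV with features in rows (first column = feature id, header row =
sample ids).  Clinical tables are CSV keyed on ``sample_id``.  Gene sets use the
standard GMT layout.  Annotation lists are plain text, one id per line.  No
science lives here: every function either parses, validates, or serializes.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("proteoconcord")

VALUE_KINDS = ("counts", "transformed", "log_intensity")
TISSUES = ("tumor", "normal")
SUBTYPES = ("luminalA", "HER2", "TN_basal", "other")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with id bookkeeping.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique row ids.
    sample_ids : sequence of str
        Unique column ids.
    values : ndarray, shape (n_features, n_samples)
        ``counts`` matrices must be non-negative integers with no missing
        values (absence of detection is 0).  ``log_intensity`` matrices may
        contain NaN (written as "NA").
    value_kind : {"counts", "transformed", "log_intensity"}
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if self.value_kind == "counts":
            if np.isnan(self.values).any():
                raise ValueError("counts matrix may not contain missing values")
            if (self.values < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.array_equal(self.values, np.floor(self.values)):
                raise ValueError("counts must be integers")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        return np.array([lookup[i] for i in ids], dtype=int)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def select_features(self, ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.feature_index(ids)
        return OmicsMatrix(list(ids), list(self.sample_ids),
                           self.values[idx, :], self.value_kind)

    def select_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.sample_index(ids)
        return OmicsMatrix(list(self.feature_ids), list(ids),
                           self.values[:, idx], self.value_kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)


CLINICAL_COLUMNS = ("sample_id", "tissue", "pair_id", "subtype", "grade",
                    "er_status", "race", "surv_time", "surv_event")


@dataclass
class SampleTable:
    """Typed clinical table, one row per sample.

    Backed by a DataFrame indexed on ``sample_id``; unknown columns are kept
    as opaque covariates.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise FormatError("clinical table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError("duplicated sample_id in clinical table")
        if "tissue" in df.columns:
            bad = set(df["tissue"].dropna()) - set(TISSUES)
            if bad:
                raise FormatError(f"unknown tissue values {sorted(bad)}")
        if "subtype" in df.columns:
            bad = set(df["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise FormatError(f"unknown subtype values {sorted(bad)}")
        if "surv_time" in df.columns:
            has_time = df["surv_time"].notna()
            if "surv_event" not in df.columns:
                if has_time.any():
                    raise FormatError("surv_time present without surv_event")
            else:
                missing = has_time & df["surv_event"].isna()
                if missing.any():
                    raise FormatError(
                        "surv_event missing for samples with surv_time: "
                        + ", ".join(df.index[missing][:5])
                    )
            if (df.loc[has_time, "surv_time"] <= 0).any():
                raise FormatError("surv_time must be positive")
        # each pair_id at most once per tissue value
        if "pair_id" in df.columns and "tissue" in df.columns:
            sub = df.dropna(subset=["pair_id"])
            dup = sub.groupby(["pair_id", "tissue"]).size()
            if (dup > 1).any():
                raise FormatError("a pair_id occurs more than once per tissue")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def samples_with_tissue(self, tissue: str) -> list[str]:
        return list(self.df.index[self.df["tissue"] == tissue])

    def complete_pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) for every pair_id present in both."""
        df = self.df.dropna(subset=["pair_id"])
        tum = df[df["tissue"] == "tumor"].reset_index().set_index("pair_id")["sample_id"]
        nor = df[df["tissue"] == "normal"].reset_index().set_index("pair_id")["sample_id"]
        shared = [p for p in tum.index if p in nor.index]
        return [(tum[p], nor[p]) for p in shared]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = [str(m) for m in members]
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PairMap:
    """protein_id -> gene_id mapping; each protein maps to at most one gene."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(p), str(g)) for p, g in self.pairs]
        prot = [p for p, _ in self.pairs]
        if len(set(prot)) != len(prot):
            raise FormatError("a protein_id maps to more than one gene_id")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairedCohort:
    """Matched protein + mRNA matrices with clinical metadata and pairing."""

    protein: OmicsMatrix
    mrna: OmicsMatrix
    samples: SampleTable
    pairmap: PairMap


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _check_rectangular(path: Path, delimiter: str) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        widths = {len(row) for row in reader if row}
    if len(widths) > 1:
        raise FormatError(f"{path}: ragged rows (field counts {sorted(widths)})")


def read_matrix(path: str | Path, value_kind: str) -> OmicsMatrix:
    """Parse a features x samples TSV into an :class:`OmicsMatrix`.

    The first column holds feature ids and the header row holds sample ids.
    "NA" encodes missing values (allowed only for non-count matrices).
    """
    path = Path(path)
    _check_rectangular(path, "\t")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry ({exc})") from exc
    try:
        return OmicsMatrix(list(df.index), [str(c) for c in df.columns],
                           values, value_kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    if matrix.value_kind == "counts":
        df = df.astype(int)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then >=1 member per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and >=1 member"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: duplicated set name {name!r} "
                                  f"at line {lineno}")
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(path: str | Path) -> SampleTable:
    """Parse the clinical CSV; see :class:`SampleTable` for the contract."""
    path = Path(path)
    _check_rectangular(path, ",")
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column sample_id")
    for col in ("grade", "surv_event"):
        if col in df.columns:
            df[col] = df[col].astype("Float64").astype(float)
    return SampleTable(df)


def write_clinical(table: SampleTable, path: str | Path) -> None:
    df = table.df.reset_index()
    df.to_csv(path, index=False, na_rep="NA")


def read_pair_map(path: str | Path) -> PairMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: pair map needs two columns")
    return PairMap(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_pair_map(pairmap: PairMap, path: str | Path) -> None:
    pd.DataFrame(pairmap.pairs, columns=["protein_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_id_list(path: str | Path) -> list[str]:
    with open(Path(path)) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise FormatError(f"{path}: config must be a mapping")
    return dict(cfg)


def write_resolved_config(cfg: Mapping, out_dir: str | Path) -> Path:
    """Persist the resolved configuration (incl. seed) next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = out_dir / "resolved_config.yaml"
    with open(target, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=True)
    logger.info("resolved config written to %s (seed=%s)",
                target, cfg.get("seed"))
    return target


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
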