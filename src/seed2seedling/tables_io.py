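"""Data model, readers/writers and run configuration for the pipeline.

The single carrier of observed data is :class:`FeatureTable`: an integer
ASV count matrix (samples x ASVs) with aligned per-sample metadata and an
optional per-ASV taxonomy. All files are plain TSV (UTF-8, tab-separated,
``.`` decimal, ``#`` comment lines); phylogenies are newick.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("seed2seedling")

COMPARTMENTS = ("seed", "soil", "root", "stem")
#: metadata columns with a controlled vocabulary (missing values allowed)
FACTOR_LEVELS = {
    "compartment": set(COMPARTMENTS),
    "soil": {"S1", "S2"},
    "genotype": {"Boston", "Major"},
    "year": {"Y1", "Y2"},
    "stage": {"d07", "d14"},
    "replicate": {"A", "B", "C"},
}

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class FeatureTable:
    """Integer ASV count matrix with aligned sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples as rows, ASVs as columns, non-negative integer entries.
    metadata : pandas.DataFrame
        One row per sample (index = sample id). Factor columns are checked
        against the study vocabulary; values may be missing (e.g. ``stage``
        for source samples).
    taxonomy : pandas.DataFrame, optional
        One row per ASV (index = ASV id) with rank columns
        (kingdom ... genus, species).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.counts.index, "sample ids")
        _check_unique(self.counts.columns, "ASV ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"count at sample {self.counts.index[i]!r}, ASV "
                f"{self.counts.columns[j]!r} is {arr[i, j]!r}: counts must be "
                "non-negative integers"
            )
        self.counts = self.counts.astype(np.int64)

        missing = [s for s in self.counts.index if s not in self.metadata.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.metadata.index if s not in self.counts.index]
        if extra:
            # metadata rows for dropped samples are common; tolerate, warn
            logger.warning("metadata rows for unobserved samples: %s", extra)
        self.metadata = self.metadata.loc[self.counts.index]
        for col, levels in FACTOR_LEVELS.items():
            if col not in self.metadata.columns:
                continue
            vals = self.metadata[col].dropna()
            unknown = sorted(set(vals) - levels)
            if unknown:
                raise ValidationError(f"unknown {col} level(s): {unknown}")

        if self.taxonomy is not None:
            _check_unique(self.taxonomy.index, "taxonomy ASV ids")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def select(self, **factors) -> "FeatureTable":
        """Sub-table of samples matching all ``column=value`` (or list) filters."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in factors.items():
            if col not in self.metadata.columns:
                raise KeyError(f"metadata has no column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.metadata[col].isin(list(val))
            else:
                mask &= self.metadata[col] == val
        ids = self.metadata.index[mask]
        if len(ids) == 0:
            raise ValidationError(f"no samples match filter {factors!r}")
        return FeatureTable(
            self.counts.loc[ids].copy(), self.metadata.loc[ids].copy(), self.taxonomy
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (derived view, never stored back)."""
        totals = self.counts.sum(axis=1)
        zero = totals[totals == 0].index.tolist()
        if zero:
            warnings.warn(f"samples with zero total excluded: {zero}")
        keep = totals[totals > 0].index
        return self.counts.loc[keep].div(totals.loc[keep], axis=0)


@dataclass
class PipelineConfig:
    """Tunable parameters of a full pipeline run.

    Rarefaction depths follow the study design: 30,000 reads for soil
    bacterial profiles, 25,000 for soil fungal profiles and 1,000 for plant
    (root/stem) samples. Abundance-class thresholds are relative-abundance
    fractions: rare < 1e-4, abundant > 1e-2, intermediate in between
    (boundaries inclusive to intermediate).
    """

    depth_soil_bacteria: int = 30_000
    depth_soil_fungi: int = 25_000
    depth_plant: int = 1_000
    detect_min_count: int = 1
    detect_min_reps: int = 1
    class_low: float = 1e-4
    class_high: float = 1e-2
    n_permutations: int = 999
    rng_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for d in (self.depth_soil_bacteria, self.depth_soil_fungi, self.depth_plant):
            if d <= 0:
                raise ValidationError("rarefaction depths must be > 0")
        if not (0.0 < self.class_low < self.class_high < 1.0):
            raise ValidationError("class thresholds must be strictly increasing in (0,1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Independent reproducible stream for one named operation.

    Derived as ``SeedSequence([seed, crc32(name)])`` so each stage of the
    pipeline is reproducible in isolation from the single run seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype={0: str})


def read_feature_table(
    path,
    metadata: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    orientation: str = "samples_as_rows",
) -> FeatureTable:
    """Read a count table from TSV, normalising orientation to samples x ASVs.

    ``orientation`` declares what the file's rows are: ``samples_as_rows``
    or ``asvs_as_rows`` (the BIOM-style dense export).
    """
    if orientation not in ("samples_as_rows", "asvs_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "asvs_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if metadata is None:
        metadata = pd.DataFrame(index=df.index)
    return FeatureTable(df, metadata, taxonomy)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (one row per sample, factor columns)."""
    md = _read_tsv(path)
    md.index = md.index.astype(str)
    _check_unique(md.index, "metadata sample ids")
    for col, levels in FACTOR_LEVELS.items():
        if col in md.columns:
            unknown = sorted(set(md[col].dropna()) - levels)
            if unknown:
                raise ValidationError(f"unknown {col} level(s): {unknown}")
    return md


def read_taxonomy(path) -> pd.DataFrame:
    tax = _read_tsv(path)
    tax.index = tax.index.astype(str)
    _check_unique(tax.index, "taxonomy ASV ids")
    return tax


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick phylogeny.

    Tips absent from the count table are allowed — consumers prune lazily.
    Negative branch lengths are rejected.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific parse errors
        raise ValidationError(f"cannot parse newick file {path}: {exc}") from exc
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at node {node.name!r}"
            )
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip labels")
    return tree


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    *,
    config: dict | None = None,
    seed: int | None = None,
    inputs: dict[str, str] | None = None,
    warnings_log: list[str] | None = None,
    overwrite: bool = False,
) -> dict:
    """Write one TSV per result table plus a JSON run manifest.

    Returns the manifest dict. Existing files are a hard error unless
    ``overwrite`` is set, so two runs cannot silently interleave.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config or {},
        "seed": seed,
        "inputs": {k: _digest(v) for k, v in (inputs or {}).items()},
        "tables": {},
        "warnings": list(warnings_log or []),
    }
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
        df.to_csv(path, sep="\t", float_format="%.10g")
        manifest["tables"][name] = {"rows": int(df.shape[0]), "columns": int(df.shape[1])}
    mpath = out / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True to replace")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
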