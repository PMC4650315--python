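"""Evidence-dataset registry and the tables the pipeline exchanges.

The pipeline integrates three classes of gene-level evidence for membership in
the mammalian circadian clock network: ChIP-seq binding of clock transcription
factors near a gene, circadian oscillation of the gene's protein product, and
protein-protein interaction with core clock proteins.  Each evidence source is
one :class:`DatasetRecord`; the presence/absence of every master-list gene in
every source is a binary :class:`HitMatrix`.

Gene identifiers are opaque strings; any ID mapping (ENTREZ, symbols, probes)
is upstream curation and outside this package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DATA_CLASSES",
    "TF_GROUPS",
    "DatasetRecord",
    "Registry",
    "HitMatrix",
    "RegistryError",
    "HitTableError",
    "load_registry",
    "write_registry",
    "paper_registry",
    "load_hit_matrix",
    "write_hit_matrix",
    "write_score_table",
    "load_score_table",
]

DATA_CLASSES = ("chipseq", "proteomics", "ppi")
TF_GROUPS = ("ebox", "dbox", "rre", "none")

REGISTRY_SCHEMA_VERSION = 1


class RegistryError(ValueError):
    """A registry file or record violates the dataset schema."""


class HitTableError(ValueError):
    """A hit table does not match the registry or is malformed."""


@dataclass(frozen=True)
class DatasetRecord:
    """One evidence source.

    Parameters
    ----------
    dataset_id : str
        Short unique identifier used as the hit-table column name.
    source_label : str
        Free-text provenance, e.g. study plus characterized factor.
    data_class : {"chipseq", "proteomics", "ppi"}
    weight : int
        Positive integer weight of the dataset in the total score.
    tf_group : {"ebox", "dbox", "rre", "none"}
        Transcription-factor group of a ChIP-seq dataset: E-box activators
        (CLOCK/BMAL1/NPAS2), the D-box repressor (E4BP4), or RRE regulators
        (REV-ERBs and RORalpha).  PER/CRY sets and non-ChIP-seq data carry
        ``"none"``.
    expected_hits : int
        Number of master-list genes present in the source.
    """

    dataset_id: str
    source_label: str
    data_class: str
    weight: int
    tf_group: str
    expected_hits: int

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise RegistryError("dataset_id must be a non-empty string")
        if self.data_class not in DATA_CLASSES:
            raise RegistryError(
                f"dataset {self.dataset_id!r}: data_class {self.data_class!r} "
                f"not one of {DATA_CLASSES}"
            )
        if self.tf_group not in TF_GROUPS:
            raise RegistryError(
                f"dataset {self.dataset_id!r}: tf_group {self.tf_group!r} "
                f"not one of {TF_GROUPS}"
            )
        if not isinstance(self.weight, (int, np.integer)) or self.weight < 1:
            raise RegistryError(
                f"dataset {self.dataset_id!r}: weight must be a positive integer"
            )
        if not isinstance(self.expected_hits, (int, np.integer)) or self.expected_hits < 0:
            raise RegistryError(
                f"dataset {self.dataset_id!r}: expected_hits must be a "
                "non-negative integer"
            )


@dataclass(frozen=True)
class Registry:
    """An ordered collection of evidence datasets plus the master-list size."""

    records: tuple[DatasetRecord, ...]
    n_genes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.n_genes < 1:
            raise RegistryError("n_genes must be positive")
        ids = [r.dataset_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RegistryError(f"duplicate dataset_id(s): {sorted(dupes)}")
        for r in self.records:
            if r.expected_hits > self.n_genes:
                raise RegistryError(
                    f"dataset {r.dataset_id!r}: expected_hits {r.expected_hits} "
                    f"exceeds master-list size {self.n_genes}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dataset_ids(self) -> tuple[str, ...]:
        return tuple(r.dataset_id for r in self.records)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.records], dtype=np.int64)

    @property
    def expected_hits(self) -> np.ndarray:
        return np.array([r.expected_hits for r in self.records], dtype=np.int64)

    @property
    def max_total_score(self) -> int:
        """Score of a gene present in every dataset (21 for the built-in registry)."""
        return int(self.weights.sum())

    def class_mask(self, data_class: str) -> np.ndarray:
        if data_class not in DATA_CLASSES:
            raise RegistryError(f"unknown data_class {data_class!r}")
        return np.array([r.data_class == data_class for r in self.records])

    def group_mask(self, tf_group: str) -> np.ndarray:
        """Boolean mask of ChIP-seq datasets belonging to a TF group."""
        if tf_group not in TF_GROUPS:
            raise RegistryError(f"unknown tf_group {tf_group!r}")
        return np.array(
            [r.data_class == "chipseq" and r.tf_group == tf_group for r in self.records]
        )

    def class_max_score(self, data_class: str) -> int:
        """Largest within-class weighted score a single gene can attain."""
        return int(self.weights[self.class_mask(data_class)].sum())


# ---------------------------------------------------------------------------
# Built-in registry of the 19 published sources
# ---------------------------------------------------------------------------

# (dataset_id, source_label, data_class, weight, tf_group, hits in master list)
_PAPER_DATASETS = (
    ("koike_bmal1", "Koike et al. BMAL1", "chipseq", 1, "ebox", 359),
    ("koike_per1", "Koike et al. PER1", "chipseq", 1, "none", 15),
    ("koike_per2", "Koike et al. PER2", "chipseq", 1, "none", 384),
    ("koike_cry1", "Koike et al. CRY1", "chipseq", 1, "none", 356),
    ("koike_cry2", "Koike et al. CRY2", "chipseq", 1, "none", 318),
    ("koike_clock", "Koike et al. CLOCK", "chipseq", 1, "ebox", 170),
    ("koike_npas", "Koike et al. NPAS2", "chipseq", 1, "ebox", 121),
    ("rey_bmal1", "Rey et al. BMAL1", "chipseq", 3, "ebox", 228),
    ("cho_reverba", "Cho et al. REV-ERBa", "chipseq", 1, "rre", 412),
    ("cho_reverbb", "Cho et al. REV-ERBb", "chipseq", 1, "rre", 412),
    ("bugge_reverba", "Bugge et al. REV-ERBa", "chipseq", 1, "rre", 636),
    ("feng_reverbb", "Feng et al. REV-ERBb", "chipseq", 1, "rre", 635),
    ("fang_rora", "Fang et al. RORa", "chipseq", 1, "rre", 529),
    ("fang_e4bp4", "Fang et al. E4BP4", "chipseq", 1, "dbox", 437),
    ("robles", "Robles et al. liver proteome", "proteomics", 1, "none", 34),
    ("mauvoisin", "Mauvoisin et al. liver proteome", "proteomics", 1, "none", 35),
    ("chiang", "Chiang et al. SCN proteome", "proteomics", 1, "none", 6),
    ("wallach", "Wallach et al. clock interactome", "ppi", 1, "none", 25),
    ("pina", "PINA mouse clock interactions", "ppi", 1, "none", 33),
)


def paper_registry(n_genes: int = 1000) -> Registry:
    """The published 19-dataset configuration over the 1000-gene master list.

    14 ChIP-seq sources (the detailed Rey et al. BMAL1 set weighted 3, all
    others 1), 3 circadian proteomes, and 2 clock-protein interactomes, with
    per-dataset master-list hit counts as published.
    """
    records = tuple(DatasetRecord(*row) for row in _PAPER_DATASETS)
    return Registry(records=records, n_genes=n_genes)


# ---------------------------------------------------------------------------
# Registry file IO (YAML)
# ---------------------------------------------------------------------------

_RECORD_FIELDS = ("dataset_id", "source_label", "data_class", "weight", "tf_group", "expected_hits")


def load_registry(path: str | Path) -> Registry:
    """Read a registry from a YAML config file.

    The file carries ``schema_version``, ``n_genes`` and a ``datasets`` list;
    each entry has the six :class:`DatasetRecord` fields.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise RegistryError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise RegistryError(f"{path}: expected a mapping at top level")
    if "n_genes" not in raw:
        raise RegistryError(f"{path}: missing top-level n_genes")
    if "datasets" not in raw or not isinstance(raw["datasets"], list):
        raise RegistryError(f"{path}: missing datasets list")
    records = []
    for i, entry in enumerate(raw["datasets"]):
        missing = [f for f in _RECORD_FIELDS if f not in entry]
        if missing:
            rid = entry.get("dataset_id", f"#{i}")
            raise RegistryError(f"{path}: record {rid}: missing field(s) {missing}")
        records.append(DatasetRecord(**{f: entry[f] for f in _RECORD_FIELDS}))
    return Registry(records=tuple(records), n_genes=int(raw["n_genes"]))


def write_registry(registry: Registry, path: str | Path) -> None:
    doc = {
        "schema_version": REGISTRY_SCHEMA_VERSION,
        "n_genes": int(registry.n_genes),
        "datasets": [dataclasses.asdict(r) for r in registry.records],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Hit matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitMatrix:
    """Genes x datasets binary indicator of evidence presence.

    ``values[g, d]`` is 1 when gene ``g`` is a hit in dataset ``d``; column
    order follows the registry record order.
    """

    gene_ids: tuple[str, ...]
    dataset_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "dataset_ids", tuple(self.dataset_ids))
        vals = np.asarray(self.values, dtype=np.int8)
        if vals.ndim != 2 or vals.shape != (len(self.gene_ids), len(self.dataset_ids)):
            raise HitTableError(
                f"indicator shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.dataset_ids)} datasets"
            )
        if not np.isin(vals, (0, 1)).all():
            raise HitTableError("hit matrix entries must be 0 or 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise HitTableError("duplicated gene IDs in hit matrix")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.dataset_ids),
        )


def load_hit_matrix(path: str | Path, registry: Registry) -> HitMatrix:
    """Read a TSV hit table and align its columns to the registry order.

    The file has a header row, a leading ``gene_id`` column and one 0/1
    column per registered dataset.  Columns may appear in any order; they are
    reordered to the registry's.  Unknown or missing columns, non-binary
    cells and duplicated gene IDs raise :class:`HitTableError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise HitTableError(f"{path}: missing gene_id column")
    file_cols = [c for c in df.columns if c != "gene_id"]
    want = set(registry.dataset_ids)
    unknown = [c for c in file_cols if c not in want]
    if unknown:
        raise HitTableError(f"{path}: unknown dataset column(s) {unknown}")
    missing = [c for c in registry.dataset_ids if c not in file_cols]
    if missing:
        raise HitTableError(f"{path}: missing dataset column(s) {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise HitTableError(
            f"{path}: duplicated gene ID {dup.iloc[0]!r} at row {dup.index[0] + 2}"
        )
    vals = df[list(registry.dataset_ids)].to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        g, d = np.argwhere(bad)[0]
        raise HitTableError(
            f"{path}: non-binary cell {vals[g, d]!r} at row {g + 2}, "
            f"column {registry.dataset_ids[d]!r}"
        )
    return HitMatrix(
        gene_ids=tuple(df["gene_id"]),
        dataset_ids=registry.dataset_ids,
        values=vals.astype(np.int8),
    )


def write_hit_matrix(hits: HitMatrix, path: str | Path) -> None:
    hits.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Score table IO (the ScoreTable type itself lives in clockminer.scoring)
# ---------------------------------------------------------------------------


def write_score_table(scores, path: str | Path) -> None:
    """Write a score table as TSV: gene_id, per-dataset hits, total_score,
    p_value, significant, robust.  Boolean flags are stored as 0/1 so the
    file round-trips losslessly through :func:`load_score_table`."""
    df = scores.table.copy()
    df["significant"] = df["significant"].astype(int)
    df["robust"] = df["robust"].astype(int)
    df.to_csv(path, sep="\t", index=True, float_format="%.17g")


def load_score_table(path: str | Path, registry: Registry):
    from .scoring import ScoreTable  # deferred: scoring imports this module

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, index_col="gene_id")
    needed = list(registry.dataset_ids) + ["total_score", "p_value", "significant", "robust"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise HitTableError(f"{path}: missing score-table column(s) {missing}")
    df = df[needed]
    df["significant"] = df["significant"].astype(bool)
    df["robust"] = df["robust"].astype(bool)
    return ScoreTable(table=df, dataset_ids=registry.dataset_ids)
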