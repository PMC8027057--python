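"""OTU-table data model, abundance filtering and clade labeling.

The substrate of the co-occurrence pipeline is a sample x OTU matrix of 16S
amplicon read counts with a SILVA-style semicolon-delimited lineage string per
OTU. Two cleaning steps precede correlation inference: removal of reagent
contaminants identified from negative controls, and removal of rare OTUs that
never reach 10 reads in any single library. OTUs are then labeled with the
ANME / seep-SRB clade vocabulary used for partnership calls.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Controlled vocabulary of partnership-relevant clades.
ANME_CLADES = ("ANME-1", "ANME-2a", "ANME-2b", "ANME-2c", "ANME-2d", "ANME-3")
SRB_CLADES = ("SEEP-SRB1a", "SEEP-SRB1g", "SEEP-SRB2")
OTHER_CLADE = "other"
CLADE_VOCABULARY = ANME_CLADES + SRB_CLADES + (OTHER_CLADE,)


@dataclass(frozen=True)
class OtuTable:
    """Sample x OTU read-count matrix with per-OTU lineage and clade labels.

    counts is an (n_samples, n_otus) nonnegative integer array; ``lineage`` and
    ``clade`` run parallel to ``otu_ids``. Every OTU carries a clade label, with
    ``"other"`` for anything outside the ANME/SRB vocabulary.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    lineage: tuple[str, ...]
    clade: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D sample x OTU matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.floor(counts)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            s, o = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[s]!r}, OTU {self.otu_ids[o]!r}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "lineage", tuple(self.lineage))
        object.__setattr__(self, "clade", tuple(self.clade))
        n_s, n_o = counts.shape
        if len(self.sample_ids) != n_s:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n_s} rows")
        if len(self.otu_ids) != n_o:
            raise FormatError(f"{len(self.otu_ids)} OTU ids for {n_o} columns")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != n_o:
            raise FormatError("duplicate OTU ids")
        if len(self.lineage) != n_o or len(self.clade) != n_o:
            raise FormatError("lineage/clade must have one entry per OTU")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def genus(self) -> tuple[str, ...]:
        """Genus-level label per OTU: second-to-last non-empty lineage rank."""
        return tuple(genus_label(lin) for lin in self.lineage)

    def select_otus(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            counts=self.counts[:, keep],
            sample_ids=self.sample_ids,
            otu_ids=tuple(self.otu_ids[i] for i in keep),
            lineage=tuple(self.lineage[i] for i in keep),
            clade=tuple(self.clade[i] for i in keep),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Classic layout: OTUs as rows, samples as columns, trailing taxonomy."""
        df = pd.DataFrame(self.counts.T, index=list(self.otu_ids), columns=list(self.sample_ids))
        df.index.name = "#OTU ID"
        df["taxonomy"] = list(self.lineage)
        return df

    def equals(self, other: "OtuTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and self.lineage == other.lineage
            and self.clade == other.clade
            and np.array_equal(self.counts, other.counts)
        )


def genus_label(lineage: str) -> str:
    """Second-to-last non-empty semicolon-delimited rank (SILVA convention)."""
    ranks = [r.strip() for r in lineage.split(";") if r.strip()]
    if len(ranks) >= 2:
        return ranks[-2]
    if ranks:
        return ranks[-1]
    return ""


# ---------------------------------------------------------------------------
# Clade rules


@dataclass(frozen=True)
class CladeRuleSet:
    """Ordered first-match-wins mapping of lineage substrings to clade labels.

    The shipped defaults include the alias rule mapping "Desulfococcus"-labeled
    lineages into SEEP-SRB1g, reflecting the reassignment of those OTUs to a
    distinct seep-associated clade.
    """

    rules: tuple[tuple[str, str], ...]

    def assign(self, lineage: str) -> str:
        for pattern, label in self.rules:
            if pattern in lineage:
                return label
        return OTHER_CLADE

    @classmethod
    def default(cls) -> "CladeRuleSet":
        text = resources.files("syntronet").joinpath("data/clade_rules.txt").read_text()
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "CladeRuleSet":
        rules = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t+", line)
            if len(parts) != 2:
                raise FormatError(f"clade rule line {lineno}: expected 'pattern<TAB>label'")
            rules.append((parts[0], parts[1]))
        return cls(rules=tuple(rules))

    @classmethod
    def from_file(cls, path: str | Path) -> "CladeRuleSet":
        return cls.from_text(Path(path).read_text())


def assign_clades(table: OtuTable, rules: CladeRuleSet | None = None) -> OtuTable:
    """Label every OTU with the first matching clade rule (unmatched -> other)."""
    rules = rules or CladeRuleSet.default()
    clade = tuple(rules.assign(lin) for lin in table.lineage)
    return replace(table, clade=clade)


# ---------------------------------------------------------------------------
# Filters


def remove_contaminants(table: OtuTable, blacklist: Iterable[str]) -> OtuTable:
    """Drop OTUs whose id matches, or whose lineage contains, a blacklist entry.

    Mirrors removal of known PCR-reagent contaminants flagged by negative
    controls. Unknown blacklist entries are logged, never fatal.
    """
    blacklist = list(blacklist)
    if not blacklist:
        return table
    hit = np.zeros(table.n_otus, dtype=bool)
    matched_entries = set()
    for j, (oid, lin) in enumerate(zip(table.otu_ids, table.lineage)):
        for entry in blacklist:
            if oid == entry or entry in lin:
                hit[j] = True
                matched_entries.add(entry)
    for entry in blacklist:
        if entry not in matched_entries:
            logger.info("contaminant blacklist entry %r matched no OTU", entry)
    keep = np.flatnonzero(~hit)
    logger.info("remove_contaminants: dropped %d of %d OTUs", int(hit.sum()), table.n_otus)
    return table.select_otus(keep)


def filter_rare_otus(table: OtuTable, min_reads: int = 10, mode: str = "drop") -> OtuTable:
    """Remove OTUs that never reach ``min_reads`` in any single library.

    ``mode="drop"`` (default) keeps an OTU iff its maximum count over samples is
    >= min_reads. ``mode="mask"`` instead zeroes individual cells below
    min_reads, keeping every OTU column (alternative reading of a per-library
    rarity rule).
    """
    if min_reads < 0:
        raise ParameterError("min_reads must be >= 0")
    if min_reads == 0:
        return table
    if mode == "drop":
        keep = np.flatnonzero(table.counts.max(axis=0) >= min_reads)
        logger.info(
            "filter_rare_otus: kept %d of %d OTUs (min_reads=%d)",
            keep.size, table.n_otus, min_reads,
        )
        return table.select_otus(keep)
    if mode == "mask":
        counts = table.counts.copy()
        counts[counts < min_reads] = 0
        return replace(table, counts=counts)
    raise ParameterError(f"unknown mode {mode!r}; expected 'drop' or 'mask'")


# ---------------------------------------------------------------------------
# Readers / writers


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    """Write classic tab-separated layout or BIOM-style (1.0, dense) JSON."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
            for j, oid in enumerate(table.otu_ids):
                row = "\t".join(str(int(c)) for c in table.counts[:, j])
                fh.write(f"{oid}\t{row}\t{table.lineage[j]}\n")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "syntronet",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [
                {"id": oid, "metadata": {"taxonomy": lin.split(";")}}
                for oid, lin in zip(table.otu_ids, table.lineage)
            ],
            "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        path.write_text(json.dumps(doc))
    else:
        raise ParameterError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def read_otu_table(
    path: str | Path, format: str = "auto", rules: CladeRuleSet | None = None
) -> OtuTable:
    """Parse a classic OTU TSV or BIOM-style JSON file into an :class:`OtuTable`.

    Clades are assigned from lineage via ``rules`` (shipped defaults if None).
    A missing taxonomy column loads with empty lineages, all clades "other",
    and a logged warning.
    """
    path = Path(path)
    if format == "auto":
        head = path.read_text()[:1].strip()
        format = "biom" if head == "{" else "tsv"
    if format == "biom":
        table = _read_biom_json(path)
    elif format == "tsv":
        table = _read_classic_tsv(path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    return assign_clades(table, rules)


def _read_classic_tsv(path: Path) -> OtuTable:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if not header[0].lstrip("#").strip().lower().startswith("otu"):
        raise FormatError(f"{path}: header must start with '#OTU ID'")
    has_tax = header[-1].strip().lower() == "taxonomy"
    if not has_tax:
        logger.warning("%s: no taxonomy column; all clades set to 'other'", path)
    sample_ids = header[1: len(header) - 1] if has_tax else header[1:]
    n_cols = len(header)
    otu_ids, lineages, rows = [], [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise FormatError(f"{path}: row {i} has {len(parts)} fields, expected {n_cols}")
        otu_ids.append(parts[0])
        lineages.append(parts[-1] if has_tax else "")
        values = parts[1: n_cols - 1] if has_tax else parts[1:]
        row = []
        for j, v in enumerate(values):
            try:
                fv = float(v)
            except ValueError:
                raise FormatError(f"{path}: non-numeric count at row {i}, column {j + 2}")
            if fv != int(fv):
                raise FormatError(f"{path}: non-integer count at row {i}, column {j + 2}")
            row.append(int(fv))
        rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).T if rows else np.zeros((len(sample_ids), 0), int)
    return OtuTable(
        counts=counts,
        sample_ids=tuple(sample_ids),
        otu_ids=tuple(otu_ids),
        lineage=tuple(lineages),
        clade=tuple(OTHER_CLADE for _ in otu_ids),
    )


def _read_biom_json(path: Path) -> OtuTable:
    doc = json.loads(path.read_text())
    n_obs, n_samp = doc["shape"]
    otu_ids = tuple(r["id"] for r in doc["rows"])
    sample_ids = tuple(c["id"] for c in doc["columns"])
    lineages = []
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        lineages.append(";".join(tax) if isinstance(tax, list) else str(tax))
    mat = np.zeros((n_obs, n_samp), dtype=np.int64)
    if doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return OtuTable(
        counts=np.asarray(mat).T,
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        lineage=tuple(lineages),
        clade=tuple(OTHER_CLADE for _ in otu_ids),
    )
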