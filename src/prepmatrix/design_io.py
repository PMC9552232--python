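"""Tabular interfaces of the pipeline.

Readers and writers for the sample-design table, MaxQuant-dialect
``proteinGroups.txt`` and ``peptides.txt``, PTM-Shepherd-dialect
``global.modsummary.tsv`` and protein feature-annotation tables.

All tables are plain TSV/CSV; MaxQuant boolean flags use the literal
``"+"`` convention, zero / empty LFQ cells mean "not quantified in this
run".  Writers emit tab-separated UTF-8 with a fixed column order,
``"."`` decimal separator and floats at six significant digits, so that
``read(write(x)) == x`` holds field-by-field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# identification-type vocabulary (MaxQuant: "By MS/MS", "By matching", "")
ID_BY_MSMS = "by_msms"
ID_BY_MATCHING = "by_matching"
ID_ABSENT = "absent"

_MQ_ID_TYPE = {"By MS/MS": ID_BY_MSMS, "By matching": ID_BY_MATCHING, "": ID_ABSENT}
_MQ_ID_TYPE_INV = {v: k for k, v in _MQ_ID_TYPE.items()}

#: default per-sample column prefixes of the MaxQuant dialect
DEFAULT_PREFIXES = {
    "lfq": "LFQ intensity",
    "id_type": "Identification type",
    "msms": "MS/MS count",
}

ISD = "ISD"
CLEANUP = "cleanup"

_DESIGN_COLUMNS = [
    "sample_id",
    "method",
    "replicate",
    "batch",
    "protocol_class",
    "buffer",
    "precipitation",
]


class DesignError(ValueError):
    """Raised when a table violates a structural invariant."""


def _fmt(x: float) -> str:
    """Format a float at 6 significant digits, integers without decimals."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# SampleDesign
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Maps each MS run to method, replicate, batch and protocol covariates.

    ``table`` has one row per run with columns ``sample_id``, ``method``,
    ``replicate``, ``batch``, ``protocol_class`` ("ISD" or "cleanup"),
    ``buffer`` and ``precipitation`` (empty string for cleanup protocols,
    which do not enter the linear model).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table lacks columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise DesignError(f"duplicate sample_id values: {dups}")
        pairs = t[["method", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DesignError("duplicate (method, replicate) pairs in design")
        isd = t[t["protocol_class"] == ISD]
        bad = isd[(isd["buffer"] == "") | (isd["precipitation"] == "")]
        if len(bad):
            raise DesignError(
                "ISD rows must carry buffer and precipitation: "
                f"{sorted(bad['sample_id'])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def methods(self) -> list[str]:
        return list(dict.fromkeys(self.table["method"]))

    def samples_of(self, method: str) -> list[str]:
        t = self.table
        return list(t.loc[t["method"] == method, "sample_id"])

    def method_of(self, sample_id: str) -> str:
        t = self.table.set_index("sample_id")
        return str(t.loc[sample_id, "method"])

    @property
    def isd_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["protocol_class"] == ISD, "sample_id"])


def read_design(path: str | Path, sep: str | None = None) -> SampleDesign:
    """Read a sample-design table (TSV or CSV, auto-detected).

    Unknown methods are allowed (they are just labels); duplicated
    ``sample_id`` or an ISD row lacking buffer/precipitation is a hard
    error.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df = df.fillna("")
    for col in ("replicate", "batch"):
        df[col] = df[col].astype(int)
    for col in ("sample_id", "method", "protocol_class", "buffer", "precipitation"):
        df[col] = df[col].astype(str)
    return SampleDesign(df.reset_index(drop=True))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table[_DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ProteinGroupTable
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroupTable:
    """Protein-group rows with decoy flags and per-sample quantification.

    ``meta`` is indexed by ``group_id`` and carries ``protein_ids``
    (";"-joined accessions), ``razor_unique_peptides`` and the three decoy
    flags.  ``lfq`` (linear intensities, 0 = absent), ``id_type`` and
    ``msms_count`` share that index, one column per sample.  ``masked``
    is an optional per-cell invalidation mask set by downstream masking
    steps; original values stay in place for audit.
    """

    meta: pd.DataFrame
    lfq: pd.DataFrame
    id_type: pd.DataFrame
    msms_count: pd.DataFrame
    masked: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.lfq.to_numpy() < 0).any():
            raise DesignError("negative LFQ intensity")
        absent = self.id_type == ID_ABSENT
        if (self.msms_count.to_numpy()[absent.to_numpy()] != 0).any():
            raise DesignError("absent identification with nonzero MS/MS count")

    @property
    def group_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def samples(self) -> list[str]:
        return list(self.lfq.columns)

    def subset(self, keep: pd.Index) -> "ProteinGroupTable":
        return ProteinGroupTable(
            meta=self.meta.loc[keep].copy(),
            lfq=self.lfq.loc[keep].copy(),
            id_type=self.id_type.loc[keep].copy(),
            msms_count=self.msms_count.loc[keep].copy(),
            masked=None if self.masked is None else self.masked.loc[keep].copy(),
            provenance=list(self.provenance),
        )

    def equals(self, other: "ProteinGroupTable") -> bool:
        return (
            self.meta.equals(other.meta)
            and self.lfq.equals(other.lfq)
            and self.id_type.equals(other.id_type)
            and self.msms_count.equals(other.msms_count)
        )


def _parse_flag(series: pd.Series, column: str) -> pd.Series:
    vals = series.fillna("").astype(str).str.strip()
    odd = vals[(vals != "") & (vals != "+")]
    if len(odd):
        logger.warning(
            "column %r: %d non-'+' tokens treated as false (e.g. %r)",
            column, len(odd), odd.iloc[0],
        )
    return vals == "+"


def _sample_columns(
    header: Iterable[str], design: SampleDesign, prefix: str
) -> dict[str, str]:
    """Resolve '<prefix> <sample_id>' columns for every design sample."""
    cols = set(header)
    out, missing = {}, []
    for s in design.samples:
        name = f"{prefix} {s}"
        if name in cols:
            out[s] = name
        else:
            missing.append(s)
    if missing:
        raise DesignError(f"no '{prefix}' column for samples: {missing}")
    return out


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    prefixes: Mapping[str, str] = DEFAULT_PREFIXES,
) -> ProteinGroupTable:
    """Read a MaxQuant-dialect ``proteinGroups.txt``.

    Empty LFQ cells become 0 (absent); flag columns follow the literal
    ``"+"`` convention.  Every design sample must resolve to an LFQ,
    identification-type and MS/MS-count column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    n = len(df)
    meta = pd.DataFrame(index=pd.RangeIndex(n))
    meta["protein_ids"] = df["Protein IDs"]
    meta["razor_unique_peptides"] = pd.to_numeric(
        df["Razor + unique peptides"]
    ).astype(int)
    meta["reverse"] = _parse_flag(df["Reverse"], "Reverse")
    meta["contaminant"] = _parse_flag(
        df["Potential contaminant"], "Potential contaminant"
    )
    meta["only_by_site"] = _parse_flag(
        df["Only identified by site"], "Only identified by site"
    )
    if "id" in df.columns:
        meta.index = pd.Index(df["id"], name="group_id")
    else:
        meta.index = pd.Index([str(i) for i in range(n)], name="group_id")

    lfq_cols = _sample_columns(df.columns, design, prefixes["lfq"])
    idt_cols = _sample_columns(df.columns, design, prefixes["id_type"])
    msms_cols = _sample_columns(df.columns, design, prefixes["msms"])

    lfq = pd.DataFrame(index=meta.index)
    idt = pd.DataFrame(index=meta.index)
    msms = pd.DataFrame(index=meta.index)
    for s in design.samples:
        lfq[s] = pd.to_numeric(df[lfq_cols[s]].replace("", "0")).to_numpy()
        raw = df[idt_cols[s]].str.strip()
        unknown = set(raw) - set(_MQ_ID_TYPE)
        if unknown:
            raise DesignError(f"unknown identification type tokens: {sorted(unknown)}")
        idt[s] = raw.map(_MQ_ID_TYPE).to_numpy()
        msms[s] = pd.to_numeric(df[msms_cols[s]].replace("", "0")).astype(int).to_numpy()
    return ProteinGroupTable(meta=meta, lfq=lfq, id_type=idt, msms_count=msms)


def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    prefixes: Mapping[str, str] = DEFAULT_PREFIXES,
) -> None:
    cols: dict[str, object] = {
        "id": table.meta.index,
        "Protein IDs": table.meta["protein_ids"],
        "Razor + unique peptides": table.meta["razor_unique_peptides"],
        "Reverse": np.where(table.meta["reverse"], "+", ""),
        "Potential contaminant": np.where(table.meta["contaminant"], "+", ""),
        "Only identified by site": np.where(table.meta["only_by_site"], "+", ""),
    }
    for s in table.samples:
        cols[f"{prefixes['lfq']} {s}"] = [_fmt(x) for x in table.lfq[s]]
        cols[f"{prefixes['id_type']} {s}"] = table.id_type[s].map(_MQ_ID_TYPE_INV)
        cols[f"{prefixes['msms']} {s}"] = table.msms_count[s]
    pd.DataFrame(cols, index=table.meta.index).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PeptideTable
# ---------------------------------------------------------------------------


@dataclass
class PeptideTable:
    """Peptide rows: sequence, missed-cleavage count, per-sample identification."""

    meta: pd.DataFrame  # index: sequence; column: missed_cleavages
    identified: pd.DataFrame  # bool, one column per sample

    @property
    def samples(self) -> list[str]:
        return list(self.identified.columns)

    def equals(self, other: "PeptideTable") -> bool:
        return self.meta.equals(other.meta) and self.identified.equals(other.identified)


def read_peptides(
    path: str | Path,
    design: SampleDesign,
    prefixes: Mapping[str, str] = DEFAULT_PREFIXES,
) -> PeptideTable:
    """Read a MaxQuant-dialect ``peptides.txt``.

    Missed-cleavage values outside the 0–2 search limit are retained with
    a warning (tolerant parse).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta = pd.DataFrame(index=pd.Index(df["Sequence"], name="sequence"))
    mc = pd.to_numeric(df["Missed cleavages"]).astype(int)
    if ((mc < 0) | (mc > 2)).any():
        logger.warning(
            "%d peptides with missed-cleavage count outside 0..2 retained",
            int(((mc < 0) | (mc > 2)).sum()),
        )
    meta["missed_cleavages"] = mc.to_numpy()
    idt_cols = _sample_columns(df.columns, design, prefixes["id_type"])
    ident = pd.DataFrame(index=meta.index)
    for s in design.samples:
        ident[s] = (df[idt_cols[s]].str.strip() != "").to_numpy()
    return PeptideTable(meta=meta, identified=ident)


def write_peptides(
    table: PeptideTable,
    path: str | Path,
    prefixes: Mapping[str, str] = DEFAULT_PREFIXES,
) -> None:
    cols: dict[str, object] = {
        "Sequence": table.meta.index,
        "Missed cleavages": table.meta["missed_cleavages"].to_numpy(),
    }
    for s in table.samples:
        cols[f"{prefixes['id_type']} {s}"] = np.where(
            table.identified[s], "By MS/MS", ""
        )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ModificationSummary
# ---------------------------------------------------------------------------


@dataclass
class ModificationSummary:
    """Open-search modification summary: PSM counts per (modification, sample)."""

    meta: pd.DataFrame  # index: mod_label; column: mass_shift (Da)
    counts: pd.DataFrame  # int PSM counts, one column per sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DesignError("negative PSM count")
        key = list(zip(self.meta.index, self.meta["mass_shift"]))
        if len(set(key)) != len(key):
            raise DesignError("duplicate (mod_label, mass_shift) rows")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def equals(self, other: "ModificationSummary") -> bool:
        return self.meta.equals(other.meta) and self.counts.equals(other.counts)


def read_mod_summary(path: str | Path, design: SampleDesign) -> ModificationSummary:
    """Read a PTM-Shepherd-dialect ``global.modsummary.tsv``.

    Per-experiment count columns are named by sample_id; a non-numeric
    count is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        logger.warning("empty modification summary: %s", path)
    meta = pd.DataFrame(index=pd.Index(df.get("Modification", pd.Series(dtype=str)),
                                       name="mod_label"))
    meta["mass_shift"] = pd.to_numeric(
        df.get("Mass Shift", pd.Series(dtype=str))
    ).to_numpy() if len(df) else np.empty(0)
    counts = pd.DataFrame(index=meta.index)
    for s in design.samples:
        if s not in df.columns:
            raise DesignError(f"modification summary lacks count column {s!r}")
        try:
            col = pd.to_numeric(df[s]).astype(int) if len(df) else pd.Series(dtype=int)
        except (ValueError, TypeError) as exc:
            raise DesignError(f"non-numeric PSM count in column {s!r}") from exc
        counts[s] = col.to_numpy()
    return ModificationSummary(meta=meta, counts=counts)


def write_mod_summary(summary: ModificationSummary, path: str | Path) -> None:
    out = pd.DataFrame()
    out["Modification"] = summary.meta.index
    # mass shifts keep full precision (they are identifiers, not measurements)
    out["Mass Shift"] = [f"{x:.10g}" for x in summary.meta["mass_shift"]]
    for s in summary.samples:
        out[s] = summary.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FeatureAnnotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureAnnotation:
    """Protein accession → set of binary feature labels.

    ``vocabulary`` maps each feature label to a free-text source tag
    (e.g. the database the feature came from).
    """

    memberships: Mapping[str, frozenset[str]]
    vocabulary: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise DesignError("empty feature vocabulary")
        stray = set().union(*self.memberships.values(), set()) - set(self.vocabulary)
        if stray:
            raise DesignError(f"features outside vocabulary: {sorted(stray)}")

    @property
    def features(self) -> list[str]:
        return sorted(self.vocabulary)

    def has(self, accession: str, feature: str) -> bool:
        return feature in self.memberships.get(accession, frozenset())

    def carriers(self, feature: str) -> set[str]:
        return {a for a, fs in self.memberships.items() if feature in fs}


def read_annotations(path: str | Path, sep: str = "\t") -> FeatureAnnotation:
    """Read a feature-annotation table, long or wide format (auto-detected).

    Long format: columns ``accession``, ``feature`` and optional
    ``source``.  Wide format: ``accession`` plus one 0/1 column per
    feature.  Duplicate (accession, feature) pairs collapse to a single
    membership.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    memberships: dict[str, set[str]] = {}
    vocab: dict[str, str] = {}
    if "feature" in cols:  # long
        for _, row in df.iterrows():
            memberships.setdefault(row["accession"], set()).add(row["feature"])
            vocab.setdefault(row["feature"], row.get("source", "") or "")
    else:  # wide binary matrix
        feats = [c for c in cols if c != "accession"]
        for f in feats:
            vocab[f] = ""
        for _, row in df.iterrows():
            memberships[row["accession"]] = {
                f for f in feats if row[f] not in ("", "0")
            }
    return FeatureAnnotation(
        memberships={a: frozenset(s) for a, s in memberships.items()},
        vocabulary=vocab,
    )


def write_annotations(annotation: FeatureAnnotation, path: str | Path) -> None:
    """Write long-format (accession, feature, source) TSV."""
    rows = [
        (acc, f, annotation.vocabulary.get(f, ""))
        for acc in sorted(annotation.memberships)
        for f in sorted(annotation.memberships[acc])
    ]
    pd.DataFrame(rows, columns=["accession", "feature", "source"]).to_csv(
        path, sep="\t", index=False
    )
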