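"""Filtering, transformation, imputation and overlap analysis.

The preprocessing path mirrors standard label-free quantification
practice: decoy/contaminant removal and a razor+unique peptide cutoff,
restriction to MS/MS-based identifications, log2 transformation, a
valid-value cutoff of three replicates in at least one method group,
and imputation of the remaining missing values by a single constant —
the floor of the minimum observed log2 intensity (the low-abundance
regime that intensity-dependent dropout censors).

A second, independent clearing path (no peptide-count cutoff, no
valid-value filter) feeds the protein-ID overlap analysis, where a
protein counts for a method when it was identified by MS/MS in at
least two of three replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_io import ID_BY_MSMS, ProteinGroupTable, SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_IRT_PATTERNS = ("iRT", "Biognosys")


class PreprocessError(ValueError):
    pass


@dataclass
class LogIntensityMatrix:
    """Proteins x samples matrix of log2 LFQ intensities.

    ``values`` holds log2 intensities (NaN = missing before imputation);
    ``valid`` marks cells observed by MS/MS with positive intensity.
    After :func:`impute_constant`, every formerly missing cell equals
    ``imputation_constant`` and ``valid`` still identifies them.
    """

    values: pd.DataFrame
    valid: pd.DataFrame
    imputation_constant: int | None = None
    provenance: list = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "LogIntensityMatrix":
        return LogIntensityMatrix(
            self.values.copy(), self.valid.copy(), self.imputation_constant,
            list(self.provenance),
        )


@dataclass(frozen=True)
class OverlapReport:
    """Per-method protein-ID sets with intersection statistics.

    ``collections`` reports, for each named method collection,
    ``|intersection|``, ``|union|`` and the percentage overlap
    ``|intersection| / |union| * 100``.  ``upset`` is the full
    exact-membership pattern table (UpSet-style): one row per observed
    membership pattern with its protein count.
    """

    sets: Mapping[str, frozenset[str]]
    collections: pd.DataFrame
    upset: pd.DataFrame


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _irt_mask(meta: pd.DataFrame, patterns: Sequence[str]) -> pd.Series:
    pat = meta["protein_ids"].astype(str)
    mask = pd.Series(False, index=meta.index)
    for p in patterns:
        mask |= pat.str.contains(p, case=False, regex=False)
    return mask


def filter_protein_groups(
    table: ProteinGroupTable,
    design: SampleDesign | None = None,
    min_razor_unique: int = 2,
    irt_patterns: Sequence[str] = DEFAULT_IRT_PATTERNS,
) -> ProteinGroupTable:
    """Remove decoy/contaminant rows, low-evidence groups and iRT standards.

    A row is dropped when it is a reverse hit, a potential contaminant,
    identified only by a modified peptide ("only by site"), has fewer
    than ``min_razor_unique`` razor+unique peptides, or any of its
    accessions matches an iRT pattern.  Per-rule removal counts are
    appended to the returned table's provenance (a row may count toward
    several rules).
    """
    meta = table.meta
    rules = {
        "reverse": meta["reverse"].astype(bool),
        "contaminant": meta["contaminant"].astype(bool),
        "only_by_site": meta["only_by_site"].astype(bool),
        "min_razor_unique": meta["razor_unique_peptides"] < min_razor_unique,
        "irt": _irt_mask(meta, irt_patterns),
    }
    remove = pd.Series(False, index=meta.index)
    counts = {}
    for name, mask in rules.items():
        counts[name] = int(mask.sum())
        remove |= mask
    keep = meta.index[~remove]
    if len(keep) == 0:
        raise PreprocessError("all rows filtered")
    out = table.subset(keep)
    record = {
        "op": "filter_protein_groups",
        "removed": counts,
        "removed_total": int(remove.sum()),
        "n_in": len(meta),
        "n_out": len(keep),
    }
    out.provenance.append(record)
    logger.info("filter_protein_groups: %s", record)
    return out


def clear_for_overlap(
    table: ProteinGroupTable,
    irt_patterns: Sequence[str] = DEFAULT_IRT_PATTERNS,
) -> ProteinGroupTable:
    """Clearing path of the overlap (Venn/UpSet) analysis.

    Contaminants, reverse hits, only-by-site identifications and iRT
    standards are removed; unlike the quantitative path there is no
    razor+unique cutoff and no valid-value filter.
    """
    return filter_protein_groups(
        table, min_razor_unique=0, irt_patterns=irt_patterns
    )


def mask_non_msms(table: ProteinGroupTable) -> ProteinGroupTable:
    """Invalidate per-sample entries not identified by fragmentation.

    Cells whose identification type is not "by MS/MS" (match-between-runs
    transfers and absences) are marked in ``table.masked``; intensity
    values are preserved for audit.
    """
    masked = table.id_type != ID_BY_MSMS
    out = table.subset(table.group_ids)
    out.masked = masked
    frac = float(masked.to_numpy().mean()) if masked.size else 0.0
    out.provenance.append({"op": "mask_non_msms", "masked_fraction": frac})
    return out


def log2_transform(table: ProteinGroupTable) -> LogIntensityMatrix:
    """Log2-transform LFQ intensities; invalid or zero cells become missing."""
    lfq = table.lfq.to_numpy(float)
    if (lfq < 0).any():
        raise PreprocessError("negative intensity")
    invalid = lfq <= 0
    if table.masked is not None:
        invalid |= table.masked.to_numpy()
    with np.errstate(divide="ignore"):
        vals = np.where(invalid, np.nan, np.log2(np.where(lfq > 0, lfq, 1.0)))
    values = pd.DataFrame(vals, index=table.group_ids, columns=table.samples)
    valid = pd.DataFrame(~invalid, index=table.group_ids, columns=table.samples)
    return LogIntensityMatrix(
        values=values, valid=valid,
        provenance=list(table.provenance) + [{"op": "log2_transform"}],
    )


def valid_value_filter(
    matrix: LogIntensityMatrix, design: SampleDesign, min_valid: int = 3
) -> LogIntensityMatrix:
    """Keep proteins with >= ``min_valid`` valid values in at least one method."""
    keep = pd.Series(False, index=matrix.values.index)
    for method in design.methods:
        cols = design.samples_of(method)
        if len(cols) < min_valid:
            logger.warning(
                "method %s has %d replicates; min_valid=%d unreachable",
                method, len(cols), min_valid,
            )
            continue
        keep |= matrix.valid[cols].sum(axis=1) >= min_valid
    out = LogIntensityMatrix(
        values=matrix.values.loc[keep].copy(),
        valid=matrix.valid.loc[keep].copy(),
        imputation_constant=matrix.imputation_constant,
        provenance=list(matrix.provenance),
    )
    out.provenance.append(
        {"op": "valid_value_filter", "min_valid": min_valid,
         "n_in": len(keep), "n_out": int(keep.sum())}
    )
    return out


def impute_constant(matrix: LogIntensityMatrix) -> LogIntensityMatrix:
    """Replace missing cells by floor(min over valid log2 cells).

    The constant approximates the detection limit; in the study's own
    data it came out at 21.  Valid cells are never altered, and the
    validity mask is retained so imputed cells stay identifiable.
    """
    vals = matrix.values.to_numpy(float)
    valid = matrix.valid.to_numpy(bool)
    if not valid.any():
        raise PreprocessError("no valid cells to derive the imputation constant")
    constant = int(math.floor(np.nanmin(vals[valid])))
    filled = np.where(valid, vals, float(constant))
    out = LogIntensityMatrix(
        values=pd.DataFrame(filled, index=matrix.values.index,
                            columns=matrix.values.columns),
        valid=matrix.valid.copy(),
        imputation_constant=constant,
        provenance=list(matrix.provenance),
    )
    out.provenance.append({"op": "impute_constant", "constant": constant})
    return out


# ---------------------------------------------------------------------------
# QC and overlaps
# ---------------------------------------------------------------------------


def summed_intensity_qc(
    table: ProteinGroupTable,
    design: SampleDesign,
    tolerance_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-sample summed linear intensities with equal-loading flags.

    Samples whose total deviates more than ``tolerance_fold``-fold from
    the median total are flagged — the sanity check behind the equal
    sample-loading assumption of the unnormalized comparison.
    """
    sums = table.lfq[design.samples].sum(axis=0)
    median = float(sums.median())
    with np.errstate(divide="ignore"):
        ratio = sums / median if median > 0 else sums * np.nan
    flagged = (ratio > tolerance_fold) | (ratio < 1.0 / tolerance_fold)
    return pd.DataFrame(
        {"summed_intensity": sums, "ratio_to_median": ratio, "flagged": flagged}
    ).rename_axis("sample_id")


def overlap_sets(
    table: ProteinGroupTable,
    design: SampleDesign,
    min_reps: int = 2,
    method_collections: Mapping[str, Sequence[str]] | None = None,
) -> OverlapReport:
    """Per-method ID sets, named-collection overlaps and the UpSet table.

    The input table should already be cleared via
    :func:`clear_for_overlap`.  A protein belongs to a method's set when
    at least ``min_reps`` of its replicates identified it by MS/MS.
    """
    msms = table.id_type == ID_BY_MSMS
    sets: dict[str, frozenset[str]] = {}
    for method in design.methods:
        cols = design.samples_of(method)
        hit = msms[cols].sum(axis=1) >= min_reps
        sets[method] = frozenset(table.group_ids[hit])

    method_collections = method_collections or {"all": list(design.methods)}
    rows = []
    for name, methods in method_collections.items():
        unknown = [m for m in methods if m not in sets]
        if unknown:
            raise PreprocessError(f"collection {name!r}: unknown methods {unknown}")
        members = [sets[m] for m in methods]
        inter = frozenset.intersection(*members)
        union = frozenset().union(*members)
        pct = 100.0 * len(inter) / len(union) if union else float("nan")
        rows.append(
            {"collection": name, "n_methods": len(methods),
             "n_intersection": len(inter), "n_union": len(union),
             "percent_overlap": pct}
        )
    collections = pd.DataFrame(rows)

    # exact-membership pattern counts (UpSet-style)
    methods = list(design.methods)
    all_ids = sorted(frozenset().union(*sets.values()) if sets else frozenset())
    patterns: dict[tuple[bool, ...], int] = {}
    membership = {m: sets[m] for m in methods}
    for gid in all_ids:
        pat = tuple(gid in membership[m] for m in methods)
        patterns[pat] = patterns.get(pat, 0) + 1
    upset = pd.DataFrame(
        [
            {"pattern": "&".join(m for m, b in zip(methods, pat) if b),
             "degree": sum(pat), "count": cnt}
            for pat, cnt in sorted(patterns.items(), key=lambda kv: -kv[1])
        ],
        columns=["pattern", "degree", "count"],
    )
    return OverlapReport(sets=sets, collections=collections, upset=upset)
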