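"""Feature-enrichment guide matrix.

For every (protein feature, cluster) pair the module tabulates a 2x2
contingency table over the clustered universe, computes the enrichment
factor

    EF = observed / expected,   expected = cluster_size * global_count / N,

and a one-sided (enrichment-direction) Fisher exact p-value — the
upper-tail hypergeometric probability P(X >= observed).  The resulting
guide matrix (features as rows, clusters as columns) summarizes which
protein classes each preparation method's favored clusters are made of.

Proteins absent from the annotation table count as feature-negative by
default, so expected counts refer to the full clustered universe; no
multiple-testing correction is applied by default (cells are flagged on
the raw p < alpha), with Benjamini-Hochberg available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .design_io import FeatureAnnotation

Alpha = float


class EnrichmentError(ValueError):
    pass


def _first_accession(group_id: str) -> str:
    """Map a protein-group identifier to its first (majority) accession."""
    return str(group_id).split(";")[0]


def tabulate_feature(
    assignments: pd.Series,
    annotation: FeatureAnnotation,
    feature: str,
    cluster: int,
) -> tuple[int, int, int, int]:
    """2x2 table (in-cluster w/ feature, in w/o, out w/, out w/o)."""
    if feature not in annotation.vocabulary:
        raise EnrichmentError(f"feature {feature!r} not in vocabulary")
    carriers = annotation.carriers(feature)
    has = np.array(
        [_first_accession(g) in carriers for g in assignments.index], dtype=bool
    )
    inside = (assignments == cluster).to_numpy()
    a = int((inside & has).sum())
    b = int((inside & ~has).sum())
    c = int((~inside & has).sum())
    d = int((~inside & ~has).sum())
    return a, b, c, d


def enrichment_factor(
    observed: int, cluster_size: int, global_count: int, total_n: int
) -> float:
    """observed / (cluster_size * global_count / total_n); NaN when undefined."""
    if total_n <= 0:
        raise EnrichmentError("total_n must be positive")
    if global_count == 0:
        return float("nan")
    expected = cluster_size * global_count / total_n
    return observed / expected


def fisher_one_sided(table: tuple[int, int, int, int]) -> float:
    """Upper-tail Fisher exact p-value for enrichment of a 2x2 table."""
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise EnrichmentError("negative entries in contingency table")
    return float(
        scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    )


@dataclass
class GuideMatrix:
    """Feature x cluster enrichment with significance and strength flags.

    ``long`` has one row per (feature, cluster) with observed/expected
    counts, enrichment factor, p-value and the ``significant`` (p <
    alpha) and ``strong`` (EF >= strong_threshold) flags; ``ef_matrix``
    is the wide layout with clusters as columns and features as rows.
    """

    long: pd.DataFrame
    ef_matrix: pd.DataFrame
    alpha: float
    strong_threshold: float
    total_n: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.long[self.long["significant"]]


def build_guide_matrix(
    assignments: pd.Series,
    annotation: FeatureAnnotation,
    alpha: Alpha = 0.05,
    strong_threshold: float = 2.0,
    bh_correction: bool = False,
    drop_unannotated: bool = False,
) -> GuideMatrix:
    """One enrichment cell per (feature, cluster) over the clustered universe.

    With ``drop_unannotated`` the universe is restricted to proteins
    present in the annotation table; otherwise unannotated proteins are
    feature-negative members of the universe.
    """
    if drop_unannotated:
        keep = [
            g for g in assignments.index
            if _first_accession(g) in annotation.memberships
        ]
        assignments = assignments.loc[keep]
    total_n = int(len(assignments))
    clusters = sorted(assignments.unique())
    cluster_sizes = assignments.value_counts()

    rows = []
    for feature in annotation.features:
        carriers = annotation.carriers(feature)
        has = pd.Series(
            [_first_accession(g) in carriers for g in assignments.index],
            index=assignments.index,
        )
        global_count = int(has.sum())
        for cl in clusters:
            inside = assignments == cl
            a = int((inside & has).sum())
            size = int(cluster_sizes[cl])
            tab = (a, size - a, global_count - a,
                   total_n - size - (global_count - a))
            ef = enrichment_factor(a, size, global_count, total_n)
            p = fisher_one_sided(tab)
            rows.append(
                {"feature": feature, "cluster": cl, "observed": a,
                 "expected": size * global_count / total_n,
                 "cluster_size": size, "global_count": global_count,
                 "enrichment_factor": ef, "p_value": p}
            )
    long = pd.DataFrame(rows)
    if bh_correction and len(long):
        from statsmodels.stats.multitest import multipletests

        long["p_adjusted"] = multipletests(long["p_value"], method="fdr_bh")[1]
        long["significant"] = long["p_adjusted"] < alpha
    else:
        long["significant"] = long["p_value"] < alpha
    long["strong"] = long["enrichment_factor"] >= strong_threshold
    ef_matrix = long.pivot(index="feature", columns="cluster",
                           values="enrichment_factor")
    return GuideMatrix(
        long=long, ef_matrix=ef_matrix, alpha=alpha,
        strong_threshold=strong_threshold, total_n=total_n,
    )
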