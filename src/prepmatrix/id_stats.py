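"""Identification statistics: counts, bridging, and the linear ID model.

Three analyses of per-run identification numbers live here:

* per-sample counts of MS/MS-identified protein groups, peptides and
  fully cleaved (zero missed-cleavage) peptides, joined with the design
  covariates;
* a median-based bridging correction that puts the two measurement
  blocks (in-solution-digest batches vs cleanup batches) on one scale
  using re-measured bridge samples of one method from each block;
* an ordinary least squares model ``IDs ~ batch + precipitation +
  buffer`` over the in-solution-digest runs, with sequential F/ANOVA
  per term, t-based 95% confidence intervals on per-level predicted
  means, and component-plus-residual (partial) residuals for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .design_io import ID_BY_MSMS, ISD, PeptideTable, ProteinGroupTable, SampleDesign

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("n_proteins", "n_peptides", "n_peptides_zero_mc")


class IdStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count_ids(
    protein_table: ProteinGroupTable,
    peptide_table: PeptideTable | None,
    design: SampleDesign,
) -> pd.DataFrame:
    """Per-sample identification counts joined with design covariates.

    ``n_proteins`` counts protein groups identified by MS/MS in the
    sample; ``n_peptides`` counts identified peptides and
    ``n_peptides_zero_mc`` those without missed cleavage.
    """
    msms = protein_table.id_type == ID_BY_MSMS
    out = design.table.copy()
    out["n_proteins"] = [int(msms[s].sum()) for s in out["sample_id"]]
    if peptide_table is not None:
        ident = peptide_table.identified
        zero_mc = peptide_table.meta["missed_cleavages"] == 0
        out["n_peptides"] = [int(ident[s].sum()) for s in out["sample_id"]]
        out["n_peptides_zero_mc"] = [
            int((ident[s] & zero_mc).sum()) for s in out["sample_id"]
        ]
    else:
        out["n_peptides"] = 0
        out["n_peptides_zero_mc"] = 0
    return out


def missed_cleavage_profile(
    peptide_table: PeptideTable, design: SampleDesign
) -> pd.DataFrame:
    """Per-sample fractions of identified peptides with 0/1/2 missed cleavages.

    Fractions sum to 1 over each sample's identified peptides; a sample
    without identifications reports NaN.
    """
    mc = peptide_table.meta["missed_cleavages"]
    rows = []
    for s in design.samples:
        ident = peptide_table.identified[s]
        total = int(ident.sum())
        row = {"sample_id": s, "n_identified": total}
        for k in (0, 1, 2):
            row[f"frac_mc{k}"] = (
                float((ident & (mc == k)).sum()) / total if total else np.nan
            )
        extra = int((ident & ~mc.isin([0, 1, 2])).sum())
        row["frac_mc_other"] = float(extra) / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bridging of batches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BridgeResult:
    """Corrected counts plus the applied change factors.

    ``change_factor`` maps each count column to the relative median
    change factor f of the bridge samples; ``scale`` to the uniform
    rescaling applied to the corrected block.
    """

    counts: pd.DataFrame
    change_factor: Mapping[str, float]
    scale: Mapping[str, float]


def bridge_batches(
    counts: pd.DataFrame,
    bridge_counts: pd.DataFrame,
    group_a: str = "SDC-A",
    group_b: str = "EasyPep",
    columns: Sequence[str] = COUNT_COLUMNS,
) -> BridgeResult:
    """Readjust one measurement block's counts via bridge re-measurements.

    The relative median change factor between the bridge groups is

        f = (median(bridge_a) - median(bridge_b)) / median(bridge_b)

    and the corrected median of ``group_a`` is ``median(b original
    samples) * (1 + f)``.  Every method group in ``group_a``'s block is
    rescaled so its median m_g maps to m* * (m_g / m_a), i.e. samples
    are scaled by the ratio of their group's corrected to original
    median.  With equal bridge medians the correction is the identity.
    """
    if "method" not in counts.columns:
        raise IdStatsError("counts must carry a 'method' column")
    block_mask = _block_of(counts, group_a)
    out = counts.copy()
    present = [c for c in columns if c in counts.columns]
    out[present] = out[present].astype(float)
    change, scale_used = {}, {}
    for col in present:
        ba = bridge_counts.loc[bridge_counts["method"] == group_a, col]
        bb = bridge_counts.loc[bridge_counts["method"] == group_b, col]
        if len(ba) == 0 or len(bb) == 0:
            raise IdStatsError(
                f"bridge counts must contain both {group_a!r} and {group_b!r}"
            )
        if float(bb.median()) == 0:
            raise IdStatsError(f"median bridge count of {group_b!r} is zero ({col})")
        f = (float(ba.median()) - float(bb.median())) / float(bb.median())
        m_b = float(counts.loc[counts["method"] == group_b, col].median())
        m_star = m_b * (1.0 + f)
        m_a = float(counts.loc[counts["method"] == group_a, col].median())
        if m_a == 0:
            raise IdStatsError(f"original median of {group_a!r} is zero ({col})")
        for method in counts.loc[block_mask, "method"].unique():
            g = block_mask & (counts["method"] == method)
            m_g = float(counts.loc[g, col].median())
            target = m_star * (m_g / m_a)
            group_scale = target / m_g if m_g else 1.0
            out.loc[g, col] = counts.loc[g, col] * group_scale
        change[col] = f
        scale_used[col] = m_star / m_a
    return BridgeResult(counts=out, change_factor=change, scale=scale_used)


def _block_of(counts: pd.DataFrame, group: str) -> pd.Series:
    """Samples sharing the measurement block of ``group``.

    The block is identified by protocol class when present (ISD batches
    vs cleanup batches), otherwise by the set of batches the group was
    measured in.
    """
    if "protocol_class" in counts.columns:
        pclass = counts.loc[counts["method"] == group, "protocol_class"]
        if len(pclass) == 0:
            raise IdStatsError(f"method {group!r} not present in counts")
        return counts["protocol_class"] == pclass.iloc[0]
    if "batch" in counts.columns:
        batches = set(counts.loc[counts["method"] == group, "batch"])
        return counts["batch"].isin(batches)
    raise IdStatsError("counts need a 'protocol_class' or 'batch' column")


# ---------------------------------------------------------------------------
# linear model of ID counts
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """OLS fit of an ID count on categorical design factors.

    Carries the coefficient estimates with standard errors, the
    sequential (or Type II) ANOVA table, per-level predicted means with
    95% t-based confidence intervals, and per-term partial residuals.
    """

    response: str
    factors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    anova: pd.DataFrame
    level_predictions: pd.DataFrame
    partial_residuals: Mapping[str, pd.DataFrame]
    df_resid: int
    fitted: pd.Series
    residuals: pd.Series
    ssr: float
    sst: float

    def summary(self) -> str:
        lines = [
            f"OLS model: {self.response} ~ {' + '.join(self.factors)}",
            f"n = {len(self.fitted)}, residual df = {self.df_resid}",
            "",
            "Coefficients:",
            pd.DataFrame({"estimate": self.params, "std_err": self.bse}).to_string(),
            "",
            "ANOVA:",
            self.anova.to_string(index=False),
            "",
            "Predicted level means (95% CI):",
            self.level_predictions.to_string(index=False),
        ]
        return "\n".join(lines)


def _design_matrix(
    data: pd.DataFrame, factors: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design matrix with intercept; levels sorted, first = reference."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    term_cols: dict[str, list[str]] = {}
    for f in factors:
        levels = sorted(data[f].astype(str).unique())
        if len(levels) < 2:
            raise IdStatsError(f"factor {f!r} has fewer than 2 levels")
        term_cols[f] = []
        for lev in levels[1:]:
            name = f"{f}[{lev}]"
            cols.append((data[f].astype(str) == lev).to_numpy(float))
            names.append(name)
            term_cols[f].append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise IdStatsError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names, term_cols


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) < np.linalg.matrix_rank(X[:, :j]) + 1:
            aliased.append(names[j])
    return aliased


def fit_id_model(
    counts: pd.DataFrame,
    response: str = "n_proteins",
    factors: Sequence[str] = ("batch", "precipitation", "buffer"),
    anova_type: str = "I",
    conf_level: float = 0.95,
) -> ModelFit:
    """Fit ``response ~ batch + precipitation + buffer`` over ISD samples.

    Factors are treatment-coded with the alphabetically first level as
    reference.  The ANOVA is sequential (Type I) in formula order by
    default, or Type II for the unbalanced design; per-level predicted
    means average the fitted model over the observed covariate
    distribution and carry t-based confidence intervals on the residual
    degrees of freedom.
    """
    data = counts
    if "protocol_class" in data.columns:
        data = data[data["protocol_class"] == ISD]
    data = data.reset_index(drop=True)
    if response not in data.columns:
        raise IdStatsError(f"unknown response {response!r}")
    y = data[response].to_numpy(float)

    X, names, term_cols = _design_matrix(data, factors)
    ols = sm.OLS(y, X).fit()
    params = pd.Series(ols.params, index=names)
    bse = pd.Series(ols.bse, index=names)
    df_resid = int(ols.df_resid)
    mse = ols.ssr / df_resid
    sst = float(((y - y.mean()) ** 2).sum())

    anova = _anova(y, data, list(factors), term_cols, names, ols.ssr, df_resid, mse,
                   anova_type)

    tq = scipy.stats.t.ppf(0.5 + conf_level / 2.0, df_resid)
    cov = np.asarray(ols.cov_params())
    pred_rows = []
    for f in factors:
        for lev in sorted(data[f].astype(str).unique()):
            Xl = X.copy()
            # set factor f to level `lev` for every observation
            for name in term_cols[f]:
                Xl[:, names.index(name)] = 1.0 if name == f"{f}[{lev}]" else 0.0
            c = Xl.mean(axis=0)
            mean = float(c @ ols.params)
            se = float(np.sqrt(c @ cov @ c))
            pred_rows.append(
                {"factor": f, "level": lev, "predicted": mean,
                 "se": se, "ci_low": mean - tq * se, "ci_high": mean + tq * se}
            )
    level_predictions = pd.DataFrame(pred_rows)

    resid = y - ols.fittedvalues
    partials = {}
    for f in factors:
        idx = [names.index(n) for n in term_cols[f]]
        contrib = X[:, idx] @ ols.params[idx]
        partials[f] = pd.DataFrame(
            {"level": data[f].astype(str), "partial_residual": resid + contrib}
        )

    return ModelFit(
        response=response,
        factors=tuple(factors),
        params=params,
        bse=bse,
        anova=anova,
        level_predictions=level_predictions,
        partial_residuals=partials,
        df_resid=df_resid,
        fitted=pd.Series(ols.fittedvalues),
        residuals=pd.Series(resid),
        ssr=float(ols.ssr),
        sst=sst,
    )


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _anova(
    y: np.ndarray,
    data: pd.DataFrame,
    factors: list[str],
    term_cols: dict[str, list[str]],
    names: list[str],
    ssr_full: float,
    df_resid: int,
    mse: float,
    anova_type: str,
) -> pd.DataFrame:
    X_full, _, _ = _design_matrix(data, factors)
    rows = []
    if anova_type == "I":
        included: list[str] = []
        prev_rss = _rss(y, np.ones((len(y), 1)))
        for f in factors:
            included.append(f)
            Xs, _, _ = _design_matrix(data, included)
            rss = _rss(y, Xs)
            df = len(term_cols[f])
            ss = prev_rss - rss
            rows.append({"term": f, "df": df, "sum_sq": ss,
                         "F": (ss / df) / mse,
                         "p": float(scipy.stats.f.sf((ss / df) / mse, df, df_resid))})
            prev_rss = rss
    elif anova_type == "II":
        for f in factors:
            others = [g for g in factors if g != f]
            Xo, _, _ = _design_matrix(data, others) if others else (
                np.ones((len(y), 1)), None, None)
            ss = _rss(y, Xo) - ssr_full
            df = len(term_cols[f])
            rows.append({"term": f, "df": df, "sum_sq": ss,
                         "F": (ss / df) / mse,
                         "p": float(scipy.stats.f.sf((ss / df) / mse, df, df_resid))})
    else:
        raise IdStatsError(f"unknown ANOVA type {anova_type!r}")
    rows.append({"term": "Residuals", "df": df_resid, "sum_sq": ssr_full,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
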