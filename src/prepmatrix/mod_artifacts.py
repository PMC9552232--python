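"""Open-search modification abundance and method-specific artifact flags.

PSM counts from an open-search modification summary are summed over
each method's replicates and expressed as percentages of that method's
total PSMs (the unmodified row included, so percentages sum to 100 per
method).  A modification is flagged method-specific when one method's
percentage both clears an absolute floor and exceeds a fold multiple of
the median percentage across methods — an operationalization of the
qualitative observation that such artifacts are rare and low-abundance.

A built-in annotation list maps known preparation artifacts to their
mass shifts: the acetone adduct (+40.0313 Da, propionaldehyde), the
EasyPep-associated acetaldehyde shift (+26.0157 Da), the FASP-associated
formaldehyde adduct (+12.00 Da), the DTT adduct on cysteine (+151.9966
Da), off-target carbamidomethylation (+/-57.0215 Da) and urea-derived
carbamylation (+43.0058 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_io import ModificationSummary, SampleDesign

KNOWN_ARTIFACT_MASSES: dict[float, str] = {
    40.0313: "acetone adduct (propionaldehyde)",
    26.0157: "acetaldehyde Schiff base",
    12.00: "formaldehyde adduct",
    151.9966: "DTT adduct on cysteine",
    57.0215: "off-target carbamidomethylation",
    -57.0215: "missing carbamidomethylation",
    43.0058: "carbamylation (urea)",
}

MASS_TOLERANCE_DA = 0.01


class ModArtifactError(ValueError):
    pass


@dataclass
class ModProfile:
    """Per-(modification, method) PSM sums and percentages.

    ``percent`` is a modifications x methods matrix of percentages of
    each method's total PSMs; columns sum to 100 where the method has
    any PSMs.
    """

    psm_sum: pd.DataFrame
    percent: pd.DataFrame
    meta: pd.DataFrame  # mod_label index, mass_shift column

    @property
    def methods(self) -> list[str]:
        return list(self.percent.columns)


def summarize_mods(summary: ModificationSummary, design: SampleDesign) -> ModProfile:
    """Sum replicate PSM counts per method and convert to percentages."""
    psm = pd.DataFrame(index=summary.meta.index)
    for method in design.methods:
        cols = [s for s in design.samples_of(method) if s in summary.counts.columns]
        psm[method] = summary.counts[cols].sum(axis=1) if cols else 0
    totals = psm.sum(axis=0)
    percent = pd.DataFrame(index=psm.index)
    for method in psm.columns:
        if totals[method] == 0:
            import warnings

            warnings.warn(f"method {method!r} has zero total PSMs", stacklevel=2)
            percent[method] = np.nan
        else:
            percent[method] = 100.0 * psm[method] / totals[method]
    return ModProfile(psm_sum=psm, percent=percent, meta=summary.meta.copy())


def annotate_known_artifact(mass_shift: float) -> str:
    """Name of a known preparation artifact within the mass tolerance, or ''."""
    for mass, label in KNOWN_ARTIFACT_MASSES.items():
        if abs(mass_shift - mass) <= MASS_TOLERANCE_DA:
            return label
    return ""


def flag_method_specific(
    profile: ModProfile, min_percent: float = 0.05, fold: float = 2.0
) -> pd.DataFrame:
    """Flag modifications concentrated in a single method.

    A modification is method-specific when its maximum per-method
    percentage is at least ``min_percent`` and at least ``fold`` times
    the median percentage across methods.  The top method and any known
    artifact annotation are reported alongside.
    """
    if profile.percent.shape[1] < 2:
        raise ModArtifactError("need at least 2 methods to flag specificity")
    pct = profile.percent
    max_pct = pct.max(axis=1)
    med_pct = pct.median(axis=1)
    top = pct.idxmax(axis=1)
    flagged = (max_pct >= min_percent) & (max_pct >= fold * med_pct) & (max_pct > 0)
    return pd.DataFrame(
        {
            "mass_shift": profile.meta["mass_shift"],
            "max_percent": max_pct,
            "median_percent": med_pct,
            "top_method": top,
            "method_specific": flagged,
            "known_artifact": [
                annotate_known_artifact(m) for m in profile.meta["mass_shift"]
            ],
        }
    )
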