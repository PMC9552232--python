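"""Ground-truthed synthetic inputs for the comparison pipeline.

The generator emulates the study layout the analysis assumes: 16 sample
preparation methods (nine classical in-solution digests combining three
buffers with precipitation variants, SPEED, and six device/kit cleanup
protocols) measured in three technical replicates across six batches —
in-solution digests in batches 1–3, cleanup methods in batches 4–6.

Protein-group log2 LFQ intensities follow an additive model

    log2 x[i, m, r] = baseline_i + effect[cluster_i, m] + eps[i, m, r]

with protein baselines drawn from a Gaussian, planted method-dependent
cluster effects, and i.i.d. replicate noise.  Cells drop out through an
intensity-dependent logistic mechanism (missing-not-at-random) plus a
small completely-random component; decoy rows (contaminants, reversed
sequences, only-by-site identifications, retention-time standards) are
appended so that every filtering rule is exercised.  Feature
annotations, per-sample identification counts (with a between-block
drift and bridge re-measurements) and open-search modification
summaries are generated from the same configuration, each from its own
seeded RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special

from .design_io import (
    CLEANUP,
    ID_ABSENT,
    ID_BY_MATCHING,
    ID_BY_MSMS,
    ISD,
    FeatureAnnotation,
    ModificationSummary,
    PeptideTable,
    ProteinGroupTable,
    SampleDesign,
)

# (method, protocol_class, buffer, precipitation); ISD block = batches 1-3
_METHODS: list[tuple[str, str, str, str]] = [
    ("U", ISD, "urea", "none"),
    ("U-A", ISD, "urea", "acetone"),
    ("U-CM", ISD, "urea", "chloroform_methanol"),
    ("G", ISD, "GnHCl", "none"),
    ("G-E", ISD, "GnHCl", "ethanol"),
    ("G-CM", ISD, "GnHCl", "chloroform_methanol"),
    ("SDC", ISD, "SDC", "none"),
    ("SDC-A", ISD, "SDC", "acetone"),
    ("SDC-CM", ISD, "SDC", "chloroform_methanol"),
    ("SPEED", ISD, "TFA", "none"),
    ("FASP", CLEANUP, "", ""),
    ("iST", CLEANUP, "", ""),
    ("EasyPep", CLEANUP, "", ""),
    ("S-Trap", CLEANUP, "", ""),
    ("SP3", CLEANUP, "", ""),
    ("SP3-SDC", CLEANUP, "", ""),
]


def default_design(n_replicates: int = 3) -> SampleDesign:
    """The study layout: 16 methods x replicates, ISD batches 1-3, cleanup 4-6."""
    rows = []
    for method, pclass, buffer, precip in _METHODS:
        for rep in range(1, n_replicates + 1):
            batch = rep if pclass == ISD else rep + n_replicates
            rows.append(
                {
                    "sample_id": f"{method}_{rep}",
                    "method": method,
                    "replicate": rep,
                    "batch": batch,
                    "protocol_class": pclass,
                    "buffer": buffer,
                    "precipitation": precip,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


@dataclass(frozen=True)
class FeatureSpec:
    """One planted binary protein feature.

    Prevalence is ``p1`` inside the enriched cluster and ``p0``
    elsewhere; ``p1 == p0`` yields a null feature.
    """

    name: str
    cluster: int  # 1-based planted cluster
    p0: float = 0.1
    p1: float = 0.5
    source: str = "synthetic"


# default per-method mean protein-ID counts (study range 3500-4500;
# SDC-based preparations highest, GnHCl buffers lowest)
_DEFAULT_ID_MEANS = {
    "U": 4000, "U-A": 4100, "U-CM": 4050, "G": 3550, "G-E": 3600,
    "G-CM": 3650, "SDC": 4350, "SDC-A": 4400, "SDC-CM": 4300,
    "SPEED": 4150, "FASP": 4000, "iST": 4200, "EasyPep": 4150,
    "S-Trap": 4100, "SP3": 4050, "SP3-SDC": 4250,
}

# default open-search modification menu: (label, mass shift Da, base
# proportion of PSMs, {method-substring: excess fold})
_DEFAULT_MODS: list[tuple[str, float, float, dict[str, float]]] = [
    ("Unmodified", 0.0, 0.78, {}),
    ("Oxidation", 15.9949, 0.08, {}),
    ("Acetylation", 42.0106, 0.04, {}),
    ("Deamidation", 0.9840, 0.05, {}),
    ("Carbamylation", 43.0058, 0.008, {"U": 3.0}),
    ("Propionaldehyde (+40)", 40.0313, 0.004, {"U-A": 5.0, "SDC-A": 5.0}),
    ("Acetaldehyde (+26)", 26.0157, 0.004, {"EasyPep": 5.0}),
    ("Formaldehyde (+12)", 12.0, 0.004, {"FASP": 5.0}),
    ("DTT adduct", 151.9966, 0.004, {"SDC": 3.0, "S-Trap": 2.5}),
    ("Carbamidomethyl (off-target)", 57.0215, 0.01, {"iST": 1.5, "EasyPep": 1.5}),
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_proteins: int = 2000
    n_replicates: int = 3
    n_clusters: int = 5
    cluster_weights: tuple[float, ...] = (0.35, 0.25, 0.175, 0.15, 0.075)
    effect_scale: float = 1.5  # log2 units
    effect_sparsity: float = 0.5  # fraction of (cluster, method) cells left at 0
    baseline_mean: float = 30.0
    baseline_sd: float = 3.0
    noise_sd: float = 0.3
    mnar_midpoint: float | None = None  # default: baseline_mean - 2*baseline_sd
    mnar_slope: float = 1.5  # per log2 unit
    mcar_rate: float = 0.005
    matching_offset: float = 1.5  # MBR midpoint sits this far above the MNAR midpoint
    contaminant_rate: float = 0.05
    reverse_rate: float = 0.05
    only_by_site_rate: float = 0.02
    n_irt: int = 1
    razor1_fraction: float = 0.05
    by_matching_rate: float = 0.02  # intensity-independent MBR component
    features: tuple[FeatureSpec, ...] = (
        FeatureSpec("nuclear", cluster=1),
        FeatureSpec("cytosolic", cluster=2),
        FeatureSpec("mitochondrial", cluster=3),
        FeatureSpec("membrane", cluster=4),
        FeatureSpec("iron_transport", cluster=5),
    )
    id_means: tuple[tuple[str, float], ...] = tuple(_DEFAULT_ID_MEANS.items())
    batch_offsets: tuple[float, ...] = (0.0, -30.0, 25.0, 10.0, -20.0, 15.0)
    id_noise_sd: float = 40.0
    peptides_per_protein: float = 8.5
    zero_mc_fraction: float = 0.7
    bridge_shift: float = -0.01  # relative drift of the ISD block (~1% observed)
    n_bridge_reps: int = 3
    bridge_group_a: str = "SDC-A"
    bridge_group_b: str = "EasyPep"
    n_peptides: int = 4000
    psm_total: int = 50000
    mods: tuple[tuple[str, float, float, tuple[tuple[str, float], ...]], ...] = tuple(
        (label, mass, prop, tuple(excess.items()))
        for label, mass, prop, excess in _DEFAULT_MODS
    )
    seed: int = 0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent integer-keyed RNG stream (full determinism per seed)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    @property
    def mnar_mid(self) -> float:
        if self.mnar_midpoint is not None:
            return self.mnar_midpoint
        return self.baseline_mean - 2.0 * self.baseline_sd

    def validate(self) -> None:
        probs = [self.mcar_rate, self.contaminant_rate, self.reverse_rate,
                 self.only_by_site_rate, self.razor1_fraction, self.by_matching_rate]
        probs += [f.p0 for f in self.features] + [f.p1 for f in self.features]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates and prevalences must lie in [0, 1]")
        if len(self.cluster_weights) != self.n_clusters:
            raise ValueError("cluster_weights length must equal n_clusters")


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters the pipeline is expected to recover."""

    cluster_labels: pd.Series  # protein -> 1..k (real rows only)
    effect_matrix: pd.DataFrame  # clusters x methods, log2 shifts
    features: tuple[FeatureSpec, ...]
    id_means: dict[str, float]
    batch_offsets: tuple[float, ...]
    bridge_shift: float


# default planted shift pattern (units of effect_scale) for the 5-cluster,
# 16-method layout; rows emulate protein classes with distinct method
# preferences: 1 = extracted equally by all methods, 2 = sensitive to
# chloroform/methanol precipitation, 3 = favored by SDC-based buffers and
# depleted in GnHCl, 4 = favored by device/bead protocols, 5 = favored by
# GnHCl and depleted in commercial kits
_DEFAULT_EFFECT_PATTERN: dict[int, dict[str, float]] = {
    2: {"U-CM": -1, "G-CM": -1, "SDC-CM": -1, "U": 1, "G": 1, "SDC": 1, "SPEED": 1},
    3: {"SDC": 1, "SDC-A": 1, "SDC-CM": 1, "SP3-SDC": 1, "S-Trap": 1,
        "G": -1, "G-E": -1, "G-CM": -1, "U": -1, "U-A": -1},
    4: {"FASP": 1, "SP3": 1, "SP3-SDC": 1, "S-Trap": 1, "iST": 1, "EasyPep": 1,
        "U": -1, "U-A": -1, "U-CM": -1, "G": -1, "G-E": -1, "G-CM": -1},
    5: {"U": 1, "U-A": 1, "U-CM": 1, "G": 1, "G-E": 1, "G-CM": 1, "SDC": 1,
        "SPEED": 1, "iST": -1, "EasyPep": -1, "FASP": -1, "SP3": -1,
        "SP3-SDC": -1, "S-Trap": -1, "SDC-A": -1, "SDC-CM": -1},
}


def _draw_effects(config: SimulationConfig, rng: np.random.Generator,
                  methods: Sequence[str]) -> pd.DataFrame:
    """Cluster x method shift matrix in log2 units.

    For the default 5-cluster, 16-method layout a fixed structured
    pattern (scaled by ``effect_scale``) is planted: cluster 1 is the
    large "every method works" class and the others carry distinct
    method-class signatures, so clusters are genuinely separable.  For
    other layouts each non-reference cluster draws a sparse random
    pattern of +/-effect_scale shifts.
    """
    k, m = config.n_clusters, len(methods)
    eff = np.zeros((k, m))
    pattern_ok = k == len(_DEFAULT_EFFECT_PATTERN) + 1 and all(
        set(row) <= set(methods) for row in _DEFAULT_EFFECT_PATTERN.values()
    )
    if pattern_ok:
        col = {name: j for j, name in enumerate(methods)}
        for cl, row in _DEFAULT_EFFECT_PATTERN.items():
            for name, sign in row.items():
                eff[cl - 1, col[name]] = config.effect_scale * sign
    else:
        for j in range(1, k):
            signs = rng.choice(
                [-1.0, 0.0, 1.0],
                size=m,
                p=[(1 - config.effect_sparsity) / 2, config.effect_sparsity,
                   (1 - config.effect_sparsity) / 2],
            )
            eff[j] = config.effect_scale * signs
    return pd.DataFrame(eff, index=pd.RangeIndex(1, k + 1, name="cluster"),
                        columns=list(methods))


def simulate_protein_groups(
    config: SimulationConfig,
) -> tuple[ProteinGroupTable, SampleDesign, GroundTruth]:
    """Generate a MaxQuant-style protein-group table with planted structure."""
    config.validate()
    rng = config.rng(0)
    design = default_design(config.n_replicates)
    methods = design.methods
    samples = design.samples
    sample_method = {s: design.method_of(s) for s in samples}

    n = config.n_proteins
    weights = np.asarray(config.cluster_weights, float)
    weights = weights / weights.sum()
    # exact allocation: cluster sizes are part of the planted ground truth
    sizes = np.floor(weights * n).astype(int)
    sizes[0] += n - sizes.sum()
    labels = np.repeat(np.arange(1, config.n_clusters + 1), sizes)
    eff = _draw_effects(config, rng, methods)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    accs = np.array([f"P{i:05d}" for i in range(n)])

    log2 = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        m = sample_method[s]
        log2[:, j] = (
            baseline
            + eff.loc[labels, m].to_numpy()
            + rng.normal(0.0, config.noise_sd, size=n)
        )

    # missingness: logistic MNAR on log2 intensity, then MCAR
    p_mnar = scipy.special.expit(config.mnar_slope * (config.mnar_mid - log2))
    drop = rng.random(log2.shape) < p_mnar
    drop |= rng.random(log2.shape) < config.mcar_rate

    lfq = np.where(drop, 0.0, np.exp2(log2))
    observed = ~drop
    # match-between-runs transfers concentrate at low intensity (cells just
    # above the dropout regime), plus a small intensity-independent rate
    p_match = scipy.special.expit(
        config.mnar_slope * (config.mnar_mid + config.matching_offset - log2)
    )
    matching = observed & (
        (rng.random(log2.shape) < p_match)
        | (rng.random(log2.shape) < config.by_matching_rate)
    )
    id_type = np.full(log2.shape, ID_ABSENT, dtype=object)
    id_type[observed] = ID_BY_MSMS
    id_type[matching] = ID_BY_MATCHING
    msms = np.where(id_type == ID_BY_MSMS, rng.poisson(5, size=log2.shape) + 1, 0)

    razor = rng.poisson(8, size=n) + 2
    razor[rng.random(n) < config.razor1_fraction] = 1

    meta = pd.DataFrame(
        {
            "protein_ids": accs,
            "razor_unique_peptides": razor,
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        },
        index=pd.Index(accs, name="group_id"),
    )

    # decoy rows: contaminants, reverse hits, only-by-site, iRT standards
    def _decoy_rows(count: int, prefix: str, flag: str | None):
        nonlocal meta, lfq, id_type, msms
        if count <= 0:
            return
        d_accs = [f"{prefix}{i:04d}" for i in range(count)]
        d_meta = pd.DataFrame(
            {
                "protein_ids": d_accs,
                "razor_unique_peptides": rng.poisson(4, size=count) + 2,
                "reverse": flag == "reverse",
                "contaminant": flag == "contaminant",
                "only_by_site": flag == "only_by_site",
            },
            index=pd.Index(d_accs, name="group_id"),
        )
        d_log2 = rng.normal(config.baseline_mean - 2, 1.0, size=(count, len(samples)))
        d_drop = rng.random(d_log2.shape) < 0.3
        d_lfq = np.where(d_drop, 0.0, np.exp2(d_log2))
        d_idt = np.where(d_drop, ID_ABSENT, ID_BY_MSMS).astype(object)
        d_msms = np.where(d_drop, 0, rng.poisson(3, size=d_log2.shape) + 1)
        meta = pd.concat([meta, d_meta])
        lfq = np.vstack([lfq, d_lfq])
        id_type = np.vstack([id_type, d_idt])
        msms = np.vstack([msms, d_msms])

    _decoy_rows(int(round(config.contaminant_rate * n)), "CON_Q", "contaminant")
    _decoy_rows(int(round(config.reverse_rate * n)), "REV_P", "reverse")
    _decoy_rows(int(round(config.only_by_site_rate * n)), "OBS_P", "only_by_site")
    _decoy_rows(config.n_irt, "iRT_Biognosys_", None)

    table = ProteinGroupTable(
        meta=meta,
        lfq=pd.DataFrame(lfq, index=meta.index, columns=samples),
        id_type=pd.DataFrame(id_type, index=meta.index, columns=samples),
        msms_count=pd.DataFrame(msms.astype(int), index=meta.index, columns=samples),
    )
    truth = GroundTruth(
        cluster_labels=pd.Series(labels, index=pd.Index(accs, name="group_id"),
                                 name="cluster"),
        effect_matrix=eff,
        features=config.features,
        id_means=dict(config.id_means),
        batch_offsets=config.batch_offsets,
        bridge_shift=config.bridge_shift,
    )
    return table, design, truth


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> FeatureAnnotation:
    """Bernoulli feature memberships: p1 inside the enriched cluster, p0 outside."""
    rng = config.rng(1)
    labels = truth.cluster_labels
    memberships: dict[str, set[str]] = {a: set() for a in labels.index}
    for spec in config.features:
        if spec.p1 < spec.p0:
            import warnings

            warnings.warn(
                f"feature {spec.name!r}: p1 < p0 (depletion scenario)", stacklevel=2
            )
        inside = (labels == spec.cluster).to_numpy()
        p = np.where(inside, spec.p1, spec.p0)
        hit = rng.random(len(labels)) < p
        for acc in labels.index[hit]:
            memberships[acc].add(spec.name)
    return FeatureAnnotation(
        memberships={a: frozenset(s) for a, s in memberships.items() if s},
        vocabulary={f.name: f.source for f in config.features},
    )


def simulate_id_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample identification counts plus bridge re-measurements.

    Counts follow ``method mean + batch offset + Gaussian noise`` (rounded,
    floored at 0).  The ISD block (batches 1-3) is additionally scaled by
    ``1 + bridge_shift``, emulating a machine-performance drift between
    the two batch sequences; the bridge samples of both bridge groups are
    re-measured drift-free in a single sequence.
    """
    config.validate()
    rng = config.rng(2)
    design = default_design(config.n_replicates)
    id_means = dict(config.id_means)
    rows = []
    for _, r in design.table.iterrows():
        mu = id_means[r["method"]] + config.batch_offsets[r["batch"] - 1]
        drift = 1.0 + config.bridge_shift if r["protocol_class"] == ISD else 1.0
        n_prot = max(0.0, round((mu + rng.normal(0, config.id_noise_sd)) * drift))
        n_pep = max(
            0.0,
            round(
                (mu * config.peptides_per_protein + rng.normal(0, config.id_noise_sd * 8))
                * drift
            ),
        )
        n_zero = round(n_pep * config.zero_mc_fraction)
        rows.append(
            dict(r) | {
                "n_proteins": n_prot,
                "n_peptides": n_pep,
                "n_peptides_zero_mc": n_zero,
            }
        )
    counts = pd.DataFrame(rows)

    bridge_rows = []
    for group in (config.bridge_group_a, config.bridge_group_b):
        for rep in range(1, config.n_bridge_reps + 1):
            mu = id_means[group]
            n_prot = max(0.0, round(mu + rng.normal(0, config.id_noise_sd)))
            n_pep = max(0.0, round(mu * config.peptides_per_protein
                                   + rng.normal(0, config.id_noise_sd * 8)))
            bridge_rows.append(
                {
                    "sample_id": f"bridge_{group}_{rep}",
                    "method": group,
                    "replicate": rep,
                    "n_proteins": n_prot,
                    "n_peptides": n_pep,
                    "n_peptides_zero_mc": round(n_pep * config.zero_mc_fraction),
                }
            )
    return counts, pd.DataFrame(bridge_rows)


def simulate_peptides(config: SimulationConfig) -> PeptideTable:
    """Peptide table with method-dependent missed-cleavage profiles."""
    rng = config.rng(4)
    design = default_design(config.n_replicates)
    n = config.n_peptides
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seqs = ["".join(rng.choice(alphabet, size=12)) + f"K{i}" for i in range(n)]
    mc = rng.choice([0, 1, 2], size=n, p=[0.7, 0.25, 0.05])
    meta = pd.DataFrame(
        {"missed_cleavages": mc}, index=pd.Index(seqs, name="sequence")
    )
    ident = pd.DataFrame(index=meta.index)
    for s in design.samples:
        # kit protocols digest more completely: fewer missed-cleavage IDs
        kit = design.method_of(s) in ("iST", "EasyPep")
        p = np.where(mc == 0, 0.85, 0.25 if kit else 0.55)
        ident[s] = rng.random(n) < p
    return PeptideTable(meta=meta, identified=ident)


def simulate_mod_summary(config: SimulationConfig) -> ModificationSummary:
    """Multinomial PSM counts per sample over the configured modification menu."""
    config.validate()
    rng = config.rng(3)
    design = default_design(config.n_replicates)
    labels = [m[0] for m in config.mods]
    masses = np.array([m[1] for m in config.mods])
    base = np.array([m[2] for m in config.mods], float)
    excess = [dict(m[3]) for m in config.mods]

    meta = pd.DataFrame(
        {"mass_shift": masses}, index=pd.Index(labels, name="mod_label")
    )
    counts = pd.DataFrame(index=meta.index)
    for s in design.samples:
        method = design.method_of(s)
        p = base.copy()
        for i, ex in enumerate(excess):
            if method in ex:
                p[i] *= ex[method]
        # absorb the adjustment into the unmodified fraction, then normalize
        p[0] = max(p[0] - (p[1:].sum() - base[1:].sum()), 0.01)
        p = p / p.sum()
        counts[s] = rng.multinomial(config.psm_total, p)
    return ModificationSummary(meta=meta, counts=counts)
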