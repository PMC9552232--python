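import numpy as np
import pandas as pd
import pytest

from prepmatrix import design_io, synthetic_data


@pytest.fixture(scope="session")
def design():
    return synthetic_data.default_design()


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation (fast enough for unit tests)."""
    return synthetic_data.SimulationConfig(n_proteins=500, seed=42)


@pytest.fixture(scope="session")
def small_tables(small_config):
    table, design, truth = synthetic_data.simulate_protein_groups(small_config)
    return table, design, truth


def make_design(rows):
    return design_io.SampleDesign(pd.DataFrame(rows))


@pytest.fixture()
def tiny_design():
    """Two methods x three replicates; method A is ISD, B is a kit."""
    rows = []
    for m, pclass, buf, prec in [("A", "ISD", "urea", "none"), ("B", "cleanup", "", "")]:
        for r in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"{m}{r}",
                    "method": m,
                    "replicate": r,
                    "batch": r if pclass == "ISD" else r + 3,
                    "protocol_class": pclass,
                    "buffer": buf,
                    "precipitation": prec,
                }
            )
    return make_design(rows)


def make_pg_table(design, lfq, id_type=None, msms=None, meta=None):
    """Assemble a ProteinGroupTable from plain arrays for fixture building."""
    lfq = pd.DataFrame(lfq, columns=design.samples)
    n = len(lfq)
    idx = pd.Index([f"P{i}" for i in range(n)], name="group_id")
    lfq.index = idx
    if id_type is None:
        id_type = pd.DataFrame(
            np.where(lfq.to_numpy() > 0, design_io.ID_BY_MSMS, design_io.ID_ABSENT),
            index=idx, columns=design.samples,
        )
    else:
        id_type = pd.DataFrame(id_type, index=idx, columns=design.samples)
    if msms is None:
        msms = pd.DataFrame(
            np.where(id_type == design_io.ID_BY_MSMS, 2, 0),
            index=idx, columns=design.samples,
        )
    else:
        msms = pd.DataFrame(msms, index=idx, columns=design.samples)
    base_meta = pd.DataFrame(
        {
            "protein_ids": idx,
            "razor_unique_peptides": 5,
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        },
        index=idx,
    )
    if meta:
        for col, vals in meta.items():
            base_meta[col] = vals
    return design_io.ProteinGroupTable(
        meta=base_meta, lfq=lfq, id_type=id_type, msms_count=msms
    )
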