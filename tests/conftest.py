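import numpy as np
import pandas as pd
import pytest

import oxbspipe as ox


def make_sheet(genotypes, chips=None, positions=None, passages=None):
    """Sample sheet from a genotype list with optional batch columns."""
    n = len(genotypes)
    return ox.SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "genotype": list(genotypes),
        "chip": chips if chips is not None else ["c1"] * n,
        "position": positions if positions is not None else ["p1"] * n,
        "passage": passages if passages is not None else [1] * n,
    }))


def make_matrix(values, arm="mC", probe_prefix="cg", sample_ids=None):
    values = np.asarray(values, float)
    probes = [f"{probe_prefix}{i:04d}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return ox.BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), arm)


def make_manifest(probe_ids, chroms, positions, blacklist=None, transcripts=None):
    n = len(probe_ids)
    probes = pd.DataFrame({
        "chromosome": chroms,
        "position": positions,
        "cpg_relation": ["OpenSea"] * n,
        "blacklist": blacklist if blacklist is not None else [False] * n,
    }, index=pd.Index(probe_ids, name="probe_id"))
    tx = transcripts if transcripts is not None else pd.DataFrame(
        columns=["probe_id", "gene", "transcript_id", "transcript_length",
                 "genomic_context"])
    return ox.ProbeManifest(probes, tx)


@pytest.fixture(scope="session")
def paired_sim():
    """One moderate paired dataset shared by read-only tests."""
    cfg = ox.SimConfig(n_probes=4000, seed=11)
    return cfg, ox.simulate_paired_dataset(cfg)
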