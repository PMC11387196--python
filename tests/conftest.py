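"""Shared fixtures: one default synthetic cohort run end-to-end per session.

The default generator configuration (n = 20,000) defines the study
conditions for the recovery tests; building it once and correcting /
combining the measurements once keeps the suite fast while letting every
downstream stage be tested against the same planted truth.
"""

import numpy as np
import pandas as pd
import pytest

from telojoint import coverage, metrics, simulate
from telojoint.utils import build_covariates


@pytest.fixture(scope="session")
def sim():
    return simulate.simulate_cohort()


@pytest.fixture(scope="session")
def adjusted(sim):
    res, scores = coverage.batch_pca_residualize(
        sim.coverage,
        sim.measurements["telseq_raw"].to_numpy(),
        return_scores=True,
    )
    return res, scores


@pytest.fixture(scope="session")
def joint(sim, adjusted):
    res, _ = adjusted
    return metrics.build_joint_metric(
        sim.measurements["qpcr_raw"].to_numpy(),
        res["telseq_adjusted"].to_numpy(),
        sample_id=sim.cohort["sample_id"].to_numpy(),
    )


@pytest.fixture(scope="session")
def covars(sim):
    return build_covariates(sim.cohort)


@pytest.fixture(scope="session")
def phenotypes(joint):
    t = joint.table
    return pd.DataFrame(
        {
            "pc1": t["pc1"].to_numpy(),
            "pc2": t["pc2"].to_numpy(),
            "qpcr": t["qpcr_int"].to_numpy(),
            "telseq": t["telseq_int"].to_numpy(),
        }
    )


@pytest.fixture(scope="session")
def rare_scan(sim, phenotypes, covars):
    """ExWAS over the rare stratum of the default cohort, all four phenotypes."""
    from telojoint import rarevar

    ann = sim.annotations
    rare_ids = ann.index[ann["maf"] < 0.01]
    return rarevar.exwas(
        phenotypes, sim.genotypes[list(rare_ids)], ann.loc[rare_ids], covars
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate.simulate_cohort(simulate.small_config())
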