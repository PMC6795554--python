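"""Shared fixtures: shipped parameter sets, the noiseless reference cell,
reference-cell protocol runs per genotype, and modest seeded cohorts reused
across the measurement-recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from navclamp import (build_protocol, extract_cell, load_genotype,
                      run_protocol, simulate_hek_cohort, simulate_oocyte_cohort)
from navclamp.calibrate import reference_cell

GENOTYPES = ("WT", "R1882Q", "R853Q")

COHORT_SEED = 3
COHORT_N = 8


@pytest.fixture(scope="session")
def params():
    return {g: load_genotype(g) for g in GENOTYPES}


@pytest.fixture(scope="session")
def ref_cell():
    return reference_cell()


@pytest.fixture(scope="session")
def ref_runs(params, ref_cell):
    """Noiseless reference-cell traces for each genotype and HEK protocol."""
    prots = {name: build_protocol(name) for name in
             ("activation_iv", "inactivation", "resurgent")}
    out = {}
    for g in GENOTYPES:
        out[g] = {name: run_protocol(ref_cell, params[g], prot, seed=None)
                  for name, prot in prots.items()}
    return out


@pytest.fixture(scope="session")
def ref_reports(ref_runs, ref_cell):
    """Full extraction reports for the noiseless reference cells."""
    return {
        g: extract_cell(runs["activation_iv"], inact=runs["inactivation"],
                        res=runs["resurgent"], Cm=ref_cell.Cm, cell_id=g)
        for g, runs in ref_runs.items()
    }


@pytest.fixture(scope="session")
def hek_cohort_features():
    """Seeded noisy HEK cohorts (n=8 per genotype) through the full
    simulate -> extract pipeline; DataFrame of per-cell features each."""
    return {g: simulate_hek_cohort(g, seed=COHORT_SEED, n=COHORT_N)[1]
            for g in GENOTYPES}


@pytest.fixture(scope="session")
def oocyte_cohorts():
    """Seeded oocyte cohorts: Qmax-recovery cohorts for WT (n=5) and R853Q
    (n=6), plus the wide-spread R853Q correlation cohort (n=11)."""
    _, wt = simulate_oocyte_cohort("WT", seed=101)
    _, rq = simulate_oocyte_cohort("R853Q", seed=102)
    _, corr = simulate_oocyte_cohort("R853Q", seed=103, correlation=True)
    return {"WT": wt, "R853Q": rq, "correlation": corr}
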