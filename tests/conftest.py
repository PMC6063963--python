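"""Shared fixtures: toy barcode layouts, a small library design, and one
error-free simulated screen reused across quantification tests."""

import numpy as np
import pandas as pd
import pytest

from pairscreen import design as D
from pairscreen import hamming as hm
from pairscreen import quantify as Q
from pairscreen import simulate as S


@pytest.fixture(scope="session")
def toy_spec():
    """Tiny layout: 2 data bases, checks at 1/2/4, parity at 6 (4^2 = 16 codewords)."""
    return hm.BarcodeSpec(n_data=2)


@pytest.fixture(scope="session")
def toy_codebook(toy_spec):
    words = [(a, b) for a in range(4) for b in range(4)]
    return {hm.encode(w, toy_spec).sequence: w for w in words}


@pytest.fixture(scope="session")
def barcode_pool():
    """The full default filtered barcode pool (shared: enumeration is the
    expensive step)."""
    return hm.generate_all()


@pytest.fixture(scope="session")
def small_design(barcode_pool):
    """One spacer group, matched + all single mismatches at every length
    (393 members)."""
    groups = D.generate_spacer_groups(1, seed=42)
    plan = D.uniform_plan(groups, ["matched", "single_mismatch"])
    lib = D.assemble_library(groups, plan, barcode_pool[:1000], seed=42)
    return D.library_to_frame(lib)


@pytest.fixture(scope="session")
def design_index(small_design):
    return Q.DesignIndex(small_design)


@pytest.fixture(scope="session")
def clean_sim(small_design, design_index, tmp_path_factory):
    """Error-free screen over ``small_design``: truth, truth log, Day-3
    observations (parsed), plus the sim config."""
    out = tmp_path_factory.mktemp("clean_sim")
    cfg = S.SimConfig(
        seed=5,
        synthesis_error_rate=0.0,
        synthesis_indel_rate=0.0,
        sequencing_error_rate=0.0,
        integrations_per_member=25,
        reads_per_rbc=3,
    )
    truth = S.simulate_truth(small_design, cfg)
    log = S.simulate_integrations(small_design, cfg)
    r1, r2 = out / "d3_R1.fastq.gz", out / "d3_R2.fastq.gz"
    S.simulate_reads(log, truth, small_design, 3, cfg, r1, r2)
    obs, accounting = Q.parse_fastq_pair(r1, r2, design_index)
    return {
        "config": cfg,
        "truth": truth,
        "log": log,
        "obs": obs,
        "accounting": accounting,
    }
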