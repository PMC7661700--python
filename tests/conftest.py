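"""Shared fixtures: packaged reference and seeded simulated repertoires.

All repertoires are generated at test time; session scope keeps the
alignment-heavy annotation runs to one per configuration.
"""

from __future__ import annotations

import pytest

from vdjrep import load_builtin_reference
from vdjrep.annotator import annotate_many
from vdjrep.simulator import make_config, simulate_repertoire


@pytest.fixture(scope="session")
def reference():
    return load_builtin_reference()


@pytest.fixture(scope="session")
def clean_rep(reference):
    """Study-scale repertoire with SHM off and everything productive."""
    cfg = make_config(
        "ptec-like", seed=101,
        shm_rate_dist=((1.0, 0.0, 0.0),), p_nonfunctional=0.0,
    )
    return simulate_repertoire(reference, cfg)


@pytest.fixture(scope="session")
def clean_annotations(clean_rep, reference):
    anns, failures = annotate_many(clean_rep.records, reference)
    assert not failures
    return anns


@pytest.fixture(scope="session")
def shm10_rep(reference):
    """Repertoire with per-sequence SHM uniform in 0-10%."""
    cfg = make_config(
        "ptec-like", seed=102,
        shm_rate_dist=((1.0, 0.0, 0.10),), p_nonfunctional=0.0,
    )
    return simulate_repertoire(reference, cfg)


@pytest.fixture(scope="session")
def shm10_annotations(shm10_rep, reference):
    anns, failures = annotate_many(shm10_rep.records, reference)
    assert not failures
    return anns


@pytest.fixture(scope="session")
def ptec_rep(reference):
    """Full "ptec-like" preset at its default study scale."""
    return simulate_repertoire(reference, make_config("ptec-like", seed=103))


@pytest.fixture(scope="session")
def ptec_annotations(ptec_rep, reference):
    anns, _ = annotate_many(ptec_rep.records, reference)
    return anns


@pytest.fixture(scope="session")
def bcell_rep(reference):
    return simulate_repertoire(reference, make_config("bcell-like", seed=104))


@pytest.fixture(scope="session")
def bcell_annotations(bcell_rep, reference):
    anns, _ = annotate_many(bcell_rep.records, reference)
    return anns
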