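"""Shared fixtures: toy subunits and planted ring maps, generated at test time."""

from __future__ import annotations

import pytest

from msring.model import select
from msring.synthetic import (
    ToySubunitSpec,
    make_planted_ring_map,
    make_toy_subunit,
)


@pytest.fixture(scope="session")
def subunit():
    """Default toy two-domain subunit (CA/CB, D1 + linker + D2)."""
    return make_toy_subunit(ToySubunitSpec(seed=4))


@pytest.fixture(scope="session")
def small_subunit():
    """Reduced subunit for fast fitting and sweep tests."""
    return make_toy_subunit(ToySubunitSpec(seed=11, n_residues_d1=8, n_residues_d2=10))


@pytest.fixture(scope="session")
def subunit_domains(subunit):
    """(fixed_body, d2, pivot_residue): the hinge-refit decomposition."""
    d2_ann = next(d for d in subunit.domains if d.name == "D2")
    fixed = select(
        subunit, residue_range=(subunit.residue_indices()[0], d2_ann.residue_start - 1)
    )
    d2 = select(subunit, residue_range=d2_ann)
    return fixed, d2, d2_ann.residue_start


@pytest.fixture(scope="session")
def c11_ring_and_map(subunit):
    """Planted C11 ring and its noise-free 8.6-Å map."""
    return make_planted_ring_map(subunit, 11, 55.0, resolution=8.6, seed=3)


@pytest.fixture(scope="session")
def c23_noisy_map(subunit):
    """Planted C23 ring map with SNR-1 noise (fixed seed)."""
    return make_planted_ring_map(subunit, 23, 62.0, resolution=8.6, noise_snr=1.0, seed=7)
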