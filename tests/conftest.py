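from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from fodm.scales import get_scale
from fodm.structure import EffectiveAtom, ResidueRef, StructureModel
from fodm.synthetic import FixtureSpec, generate


@pytest.fixture(scope="session")
def kd_scale():
    return get_scale("kyte-doolittle")


def make_model(positions, hydrophobicities, chain="A") -> StructureModel:
    """Assemble a StructureModel directly from arrays (test plumbing)."""
    atoms = tuple(
        EffectiveAtom(
            ref=ResidueRef(chain_id=chain, seq_number=i + 1, aa_code="ALA"),
            position=np.asarray(p, dtype=float),
            intrinsic_h=float(h),
        )
        for i, (p, h) in enumerate(zip(positions, hydrophobicities))
    )
    return StructureModel(id="adhoc", atoms=atoms, source_format="synthetic")


def random_cloud_model(seed: int, n: int = 40):
    """A seeded random fixture StructureModel with noisy hydrophobicities."""
    model, _ = generate(FixtureSpec(n_residues=n, mode="ideal-micelle", seed=seed, noise=0.15))
    return model


@pytest.fixture
def micelle_100():
    model, expect = generate(FixtureSpec(n_residues=100, mode="ideal-micelle", seed=1))
    return model, expect


@pytest.fixture
def planted_20():
    model, expect = generate(FixtureSpec(n_residues=20, mode="planted-outlier", seed=7))
    return model, expect


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """Strictly positive point on the n-simplex."""
    x = rng.gamma(shape=1.0, scale=1.0, size=n) + 1e-9
    return x / x.sum()
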