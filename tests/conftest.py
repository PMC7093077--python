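from __future__ import annotations

import numpy as np
import pytest

from sbmlfit.expr import parse_infix
from sbmlfit.model import (
    Compartment,
    ModelDocument,
    Parameter,
    Reaction,
    Species,
    SpeciesRef,
)
from sbmlfit.synthetic import ChainModelSpec, generate_chain_model, make_study_fixture


def make_decay_model(k: float = 1.0, y0: float = 1.0) -> ModelDocument:
    """A --k*A--> (degradation): y' = -k*y."""
    doc = ModelDocument(model_id="decay")
    doc.compartments.append(Compartment("c", 1.0))
    doc.species.append(Species("A", "c", initial_amount=y0))
    doc.parameters.append(Parameter("k", value=k))
    doc.reactions.append(Reaction(
        "deg", reactants=[SpeciesRef("A")],
        kinetic_law=parse_infix("k * A"), reversible=False))
    return doc


def make_mm_model(vmax: float = 100.0, km: float = 1.0,
                  s0: float = 1.0) -> ModelDocument:
    """S -> P with Michaelis-Menten kinetics."""
    doc = ModelDocument(model_id="mm")
    doc.compartments.append(Compartment("c", 1.0))
    doc.species.append(Species("S", "c", initial_amount=s0))
    doc.species.append(Species("P", "c", initial_amount=0.0))
    doc.parameters.append(Parameter("Vmax", value=vmax))
    doc.parameters.append(Parameter("Km", value=km))
    doc.reactions.append(Reaction(
        "conv", reactants=[SpeciesRef("S")], products=[SpeciesRef("P")],
        kinetic_law=parse_infix("Vmax * S / (Km + S)"), reversible=False))
    return doc


def make_linear_chain_model(k1: float = 1.0, k2: float = 2.0,
                            a0: float = 1.0) -> ModelDocument:
    """A -k1-> B -k2-> (first order, closed form known)."""
    doc = ModelDocument(model_id="linchain")
    doc.compartments.append(Compartment("c", 1.0))
    doc.species.append(Species("A", "c", initial_amount=a0))
    doc.species.append(Species("B", "c", initial_amount=0.0))
    doc.parameters.append(Parameter("k1", value=k1))
    doc.parameters.append(Parameter("k2", value=k2))
    doc.reactions.append(Reaction(
        "r1", reactants=[SpeciesRef("A")], products=[SpeciesRef("B")],
        kinetic_law=parse_infix("k1 * A"), reversible=False))
    doc.reactions.append(Reaction(
        "r2", reactants=[SpeciesRef("B")],
        kinetic_law=parse_infix("k2 * B"), reversible=False))
    return doc


@pytest.fixture
def decay_model() -> ModelDocument:
    return make_decay_model()


@pytest.fixture
def mm_model() -> ModelDocument:
    return make_mm_model()


@pytest.fixture
def linear_chain_model() -> ModelDocument:
    return make_linear_chain_model()


@pytest.fixture(scope="session")
def chain_model_and_truth():
    return generate_chain_model(ChainModelSpec(n_pairs=3, seed=1))


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture(ChainModelSpec(n_pairs=3, seed=1))


@pytest.fixture(scope="session")
def fixture_models(chain_model_and_truth):
    """Battery of parsed-equivalent fixture models for oracle sweeps."""
    chain, _ = chain_model_and_truth
    return {
        "decay": make_decay_model(),
        "mm": make_mm_model(),
        "linear_chain": make_linear_chain_model(),
        "chain3": chain,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(1234))
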