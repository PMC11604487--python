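import numpy as np
import pytest

from hepatoflux import (
    ContextConfig,
    EffectConfig,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_chain_model,
    build_toy_hepatocyte,
)


@pytest.fixture
def toy_model():
    return build_toy_hepatocyte()


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def ctx_cfg():
    return ContextConfig()


@pytest.fixture
def effect_cfg():
    return EffectConfig(seed=42)


def make_subject(t2d=False, bmi=28.0, sex="male", height=170.0, **over):
    """Minimal subject record with a consistent weight for the given BMI."""
    subj = {
        "id": "S0000",
        "sex": sex,
        "age": 50,
        "height": height,
        "weight": bmi * (height / 100.0) ** 2,
        "bmi": bmi,
        "t2d": t2d,
        "fibrosis": 0,
        "steatosis": 1,
        "activity_score": 0,
        "group": "MASL",
        "glucose": 90.0,
        "insulin": 10.0,
        "ffa": 0.5,
        "alt": 25.0,
        "ast": 22.0,
    }
    subj.update(over)
    return subj


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """Random small stoichiometric model for oracle-equivalence checks.

    All bounds finite, zero flux always feasible, a handful of reversible
    reactions so the splitting path is exercised.
    """
    n_mets = rng.integers(2, 5)
    n_rxns = rng.integers(4, 9)
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        which = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=k)
        stoich = {f"m{i}": float(c) for i, c in zip(which, coefs)}
        lb = float(rng.choice([0.0, 0.0, -rng.uniform(0.5, 3.0)]))
        ub = float(rng.uniform(0.5, 5.0))
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    exchange = {r.id for r in rxns if len(r.stoich) == 1}
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=f"r{rng.integers(0, n_rxns)}",
        exchange_ids=exchange,
    )
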