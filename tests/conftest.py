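import numpy as np
import pytest

from shelfweb.balance import (
    DietMatrix,
    EcopathModel,
    Fleet,
    FunctionalGroup,
    solve_mass_balance,
)
from shelfweb.dynamics import calibrate
from shelfweb.synth import (
    GeneratorConfig,
    generate_baseline_forcing,
    generate_web,
    new_alien_k_overrides,
)


def make_model(groups, diet, imports=None, fleets=()):
    """Convenience constructor for small hand-built webs.

    ``groups`` is a list of (name, category, B, PB, QB, GS[, tags]);
    ``diet`` maps predator -> {prey: fraction}.
    """
    fg = []
    for row in groups:
        name, cat, b, pb, qb, gs = row[:6]
        tags = frozenset(row[6]) if len(row) > 6 else frozenset()
        fg.append(
            FunctionalGroup(name=name, category=cat, biomass=b, pb=pb, qb=qb,
                            gs=gs, role_tags=tags)
        )
    names = [g.name for g in fg]
    n = len(names)
    dc = np.zeros((n, n))
    imp = np.zeros(n)
    for pred, prey_map in diet.items():
        for prey, frac in prey_map.items():
            dc[names.index(prey), names.index(pred)] = frac
    for pred, frac in (imports or {}).items():
        imp[names.index(pred)] = frac
    return EcopathModel(
        groups=fg, diet=DietMatrix(dc=dc, import_fraction=imp), fleets=list(fleets)
    )


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_web(default_config):
    """Default 12-group balanced web with responses and pedigree."""
    return generate_web(default_config)


@pytest.fixture(scope="session")
def calibrated(synthetic_web):
    model, responses, pedigree = synthetic_web
    params, dyn = calibrate(model, k_overrides=new_alien_k_overrides(model))
    return model, params, dyn


@pytest.fixture(scope="session")
def baseline_forcings(default_config, synthetic_web):
    model, _, _ = synthetic_web
    return generate_baseline_forcing(default_config, model=model)


@pytest.fixture()
def chain_model():
    """producer -> herbivore -> carnivore chain with pure diets."""
    m = make_model(
        [
            ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
            ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
            ("grazer", "consumer", 1.0, 2.0, 10.0, 0.2),
            ("hunter", "consumer", 0.2, 1.0, 4.0, 0.2),
        ],
        {"grazer": {"algae": 1.0}, "hunter": {"grazer": 1.0}},
    )
    return solve_mass_balance(m)


__all__ = ["make_model", "Fleet"]
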