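"""Shared fixtures: one synthetic study and one fitted model per session."""

import numpy as np
import pytest

import invasdm as iv


@pytest.fixture(scope="session")
def study():
    """Canonical synthetic invasion: stack, true suitability, records, polygon."""
    stack, suit, occ, poly = iv.make_synthetic_study(seed=0, n_years=45)
    return {"stack": stack, "suit": suit, "occ": occ, "poly": poly}


@pytest.fixture(scope="session")
def background(study):
    return iv.build_background(study["occ"], study["stack"], buffer_km=150,
                               n=800, seed=7)


@pytest.fixture(scope="session")
def fitted(study, background):
    """A model fitted on the canonical study (all feature classes)."""
    stack, occ = study["stack"], study["occ"]
    Xp = stack.extract(occ.lon, occ.lat)
    Xb = stack.extract(background.lon, background.lat)
    model = iv.MaxentSDM(n_knots=5).fit_presence_background(
        Xp, Xb, list(stack.variables))
    return {"model": model, "Xp": Xp, "Xb": Xb}


@pytest.fixture(scope="session")
def fitted_equilibrium(study):
    """Model fitted on presences sampled from the true suitability law
    (no dispersal limitation), for parameter-recovery checks."""
    stack, suit = study["stack"], study["suit"]
    occ = iv.sample_occurrences(suit, stack, n=500, seed=17)
    # buffer wide enough to admit the whole landscape as background
    bg = iv.build_background(occ, stack, buffer_km=20_000, n=1500, seed=18)
    Xp = stack.extract(occ.lon, occ.lat)
    Xb = stack.extract(bg.lon, bg.lat)
    model = iv.MaxentSDM(n_knots=5).fit_presence_background(
        Xp, Xb, list(stack.variables))
    return {"model": model, "Xp": Xp, "Xb": Xb}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
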