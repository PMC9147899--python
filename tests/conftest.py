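import numpy as np
import pytest

from spotfit.model_core import TwoDimParams
from spotfit.preprocess import aggregate_replicates
from spotfit.synthetic_data import (
    ArrayLayout,
    BindingModelParams,
    simulate_from_surface,
)


@pytest.fixture
def surface_truth() -> TwoDimParams:
    """A 2D surface with the inflection inside the printed antigen range."""
    return TwoDimParams(C=5e4, B=50.0, m=1.0, x_i=-10.4, d=1.7)


@pytest.fixture
def igg_layout() -> ArrayLayout:
    """Default geometry restricted to a single channel."""
    return ArrayLayout(
        antigen_concs=tuple(2e-4 * 0.5**j for j in range(7)),
        n_replicates=5,
        dilutions=(100.0, 300.0, 900.0, 2700.0, 8100.0),
        channels=("IgG",),
    )


@pytest.fixture
def binding_truth() -> BindingModelParams:
    """Equilibrium-model parameters with the midpoint inside the range."""
    return BindingModelParams(
        ab_conc=1e-6, kd=1e-8, d_const=4e5, alpha=5e9, beta=1.0, noise_sigma=0.0
    )


@pytest.fixture
def noiseless_surface_table(igg_layout, surface_truth):
    """BindingTable from a noiseless 2D-surface simulation."""
    spots = simulate_from_surface(igg_layout, surface_truth, 0.0, seed=0)
    return aggregate_replicates(spots)


def make_surface_table(layout, truth, noise_sigma, seed, background=0.0):
    spots = simulate_from_surface(
        layout, truth, noise_sigma, seed=seed, background=background
    )
    return aggregate_replicates(spots)
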