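import numpy as np
import pytest

from chromashade import surface_geometry as sg


@pytest.fixture(scope="session")
def bumpy_field():
    """The canonical bumpy plane used across rendering tests."""
    return sg.generate_bumpy_heightfield(67, seed=11)


@pytest.fixture(scope="session")
def bumpy_shape_index(bumpy_field):
    return sg.shape_index(sg.principal_curvatures(bumpy_field))


@pytest.fixture(scope="session")
def flat_field():
    return sg.HeightField(np.zeros((67, 67)), 0.25)


@pytest.fixture(scope="session")
def elevation_sweep_09(bumpy_field):
    """0.09-albedo channel renders at the seven elevations, 1e6 photons."""
    from chromashade import translucent_renderer as tr

    mat = tr.MaterialSpec()
    return {
        e: tr.render_channel(bumpy_field, 0.09, mat,
                             tr.Illumination(float(e)),
                             n_photons=1_000_000, seed=0)
        for e in range(0, 91, 15)
    }


@pytest.fixture(scope="session")
def exp1_stimuli(bumpy_field):
    """The 14-stimulus illumination-elevation set at a desk-scale budget."""
    from chromashade import translucent_renderer as tr

    return tr.make_stimulus_set("exp1", bumpy_field, n_photons=300_000,
                                seed=0)


@pytest.fixture(scope="session")
def exp2_stimuli(bumpy_field):
    """The 21-stimulus albedo-ladder set at a desk-scale budget."""
    from chromashade import translucent_renderer as tr

    return tr.make_stimulus_set("exp2", bumpy_field, n_photons=200_000,
                                seed=0)
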