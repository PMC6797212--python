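import pytest

from reflexgait.msk_model import build_default_model
from reflexgait.planar_dynamics import PlanarModel, rollout
from reflexgait.reflex_controller import ControllerTopology, GaitController


@pytest.fixture(scope="session")
def model_spec():
    return build_default_model()


@pytest.fixture(scope="session")
def planar_model(model_spec):
    return PlanarModel(model_spec)


@pytest.fixture(scope="session")
def topology():
    return ControllerTopology.from_yaml()


@pytest.fixture(scope="session")
def default_init_params(topology):
    """The shipped default initial state (split stance, forward speed)."""
    from reflexgait import shooting_optimizer as so

    return so.DesignVector.default(topology).split()[1]


@pytest.fixture(scope="session")
def short_rollout(planar_model, topology, default_init_params):
    """A 2 s closed-loop rollout with the shipped default controller values."""
    controller = GaitController(topology)
    return rollout(planar_model, controller, default_init_params, t_des=2.0)
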