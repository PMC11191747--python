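import pytest

from porenet.chemistry import assign_donors_acceptors
from porenet.synthetic import build_pore_system, default_pore_spec


@pytest.fixture(scope="session")
def octamer():
    """Stock synthetic octamer pore (30 frames), with annotated topology."""
    spec = default_pore_spec(n_frames=30, seed=11)
    topology, frames, manifest = build_pore_system(spec)
    assign_donors_acceptors(topology)
    return spec, topology, frames, manifest
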