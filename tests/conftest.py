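import numpy as np
import pytest

from lipshell import MembraneFrame, partition
from lipshell.synth import GasMixtureSpec, LipidSpec, SceneSpec, build_scene


@pytest.fixture(scope="session")
def trimer_scene():
    """Reference trimer scene: one lipid per location class plus a gas cloud."""
    spec = SceneSpec(
        seed=11,
        lipids=(
            LipidSpec(location="inner_compartment", lipid_class="archaeal_diphytanyl", d0=4.0),
            LipidSpec(location="inter_protomer", d0=4.0),
            LipidSpec(location="peripheral", d0=4.0),
            LipidSpec(location="peripheral", d0=4.5, branched=True),
        ),
        gas=GasMixtureSpec(n_atoms=2000),
    )
    structure, truth = build_scene(spec)
    return spec, structure, truth


@pytest.fixture(scope="session")
def trimer_structure(trimer_scene):
    return trimer_scene[1]


@pytest.fixture(scope="session")
def trimer_truth(trimer_scene):
    return trimer_scene[2]


@pytest.fixture(scope="session")
def trimer_partition(trimer_structure):
    return partition(trimer_structure)


@pytest.fixture(scope="session")
def flat_frame(trimer_truth):
    f = trimer_truth["frame"]
    return MembraneFrame(np.array(f["normal"]), f["z_origin"], f["z_lower"], f["z_upper"])


@pytest.fixture(scope="session")
def monomer_scene():
    spec = SceneSpec(seed=5, trimer=False,
                     lipids=(LipidSpec(location="peripheral", d0=4.0),
                             LipidSpec(location="peripheral", d0=4.0, branched=True)))
    structure, truth = build_scene(spec)
    return spec, structure, truth
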