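import numpy as np
import pytest

from tetherdock import restraints, symdock, synthdata

from _geom import ASSEMBLY_MAP  # noqa: E402


@pytest.fixture(scope="session")
def toy7():
    """The standard toy tetramer (seed 7) with planted links and UIRs."""
    spec = synthdata.ToyComplexSpec(seed=7)
    assembly, receptor, ligand, pose = synthdata.make_toy_tetramer(spec)
    links = synthdata.plant_crosslinks(
        receptor, ligand, pose, synthdata.PlantedCrossLinkSpec(n_true=4, seed=7)
    )
    uirs = restraints.uirs_from_crosslinks(links, ASSEMBLY_MAP, fallback_slack=0.0)
    return {
        "spec": spec,
        "assembly": assembly,
        "receptor": receptor,
        "ligand": ligand,
        "pose": pose,
        "links": links,
        "uirs": uirs,
        "prepared": symdock.prepare_receptor(receptor),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
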