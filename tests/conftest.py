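import numpy as np
import pytest

from dnaenm.params import HelicalParameterSet, PairParameters, StepParameters, load_parameter_set


@pytest.fixture(scope="session")
def param_set_i():
    return load_parameter_set("i")


@pytest.fixture(scope="session")
def flat_params():
    """Synthetic parameter set: zero pair parameters, uniform B-like steps.

    Useful for closed-form geometry checks (pure translation/rotation)."""
    steps = {
        a + b: StepParameters(0.0, 0.0, 3.4, 0.0, 0.0, 36.0)
        for a in "ACGT" for b in "ACGT"
    }
    pairs = {b: PairParameters(0, 0, 0, 0, 0, 0) for b in "ACGT"}
    return HelicalParameterSet("flat", steps, pairs)


@pytest.fixture(scope="session")
def duplex_16(param_set_i):
    """All-atom build of a 16-bp sequence containing varied steps."""
    from dnaenm.builder import build_structure

    return build_structure("AACAGATTCTGCCGGT", param_set_i)


@pytest.fixture(scope="session")
def random_network():
    """Small random restrained elastic network for oracle tests."""
    from dnaenm.enm import ElasticNetwork

    rng = np.random.default_rng(42)
    n = 8
    pos = rng.uniform(-4, 4, size=(n, 3))
    # ring of ±1/±2 neighbors (degree ≥ 4 everywhere: no floppy mechanisms)
    # plus a few random chords
    pairs = {(i, (i + d) % n) for i in range(n) for d in (1, 2)}
    pairs = {(min(a, b), max(a, b)) for a, b in pairs}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.2:
                pairs.add((i, j))
    pairs = np.array(sorted(pairs))
    rest = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    # all-positive restraints: kills rigid-body modes and any central-force
    # mechanism, so the spectrum is strictly positive
    restraints = rng.uniform(0.05, 0.5, size=n)
    return ElasticNetwork(
        model="AAENM", positions=pos, springs=pairs, rest_lengths=rest,
        spring_constant=2.3, restraints=restraints,
    )
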