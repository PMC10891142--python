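import pytest

import fibromotif as fm
from fibromotif import metrics


@pytest.fixture(scope="session")
def shallow():
    return fm.MyocyteParams.shallow()


@pytest.fixture(scope="session")
def steep():
    return fm.MyocyteParams.steep()


@pytest.fixture(scope="session")
def fib24():
    """Fibroblast calibrated to the depolarized resting potential (-24.5 mV)."""
    return fm.fibroblast_params_for_vfr(-24.5)


@pytest.fixture(scope="session")
def fib49():
    return fm.fibroblast_params_for_vfr(-49.0)


@pytest.fixture(scope="session")
def short_spec():
    """Cheap pacing spec for structural (non-quantitative) checks."""
    return fm.PacingSpec(t1=600.0, n_beats=3, n_discard=1)


@pytest.fixture(scope="session")
def study_spec():
    """The study's pacing protocol: 20 beats, first 10 discarded."""
    return fm.PacingSpec(t1=600.0, n_beats=20, n_discard=10)


def mean_apd_of(trace, cell="m1", n_discard=10):
    events = metrics.detect_aps(trace.voltage(cell), trace.time)
    return metrics.mean_apd(events, n_discard)


@pytest.fixture(scope="session")
def motif1_steep_reduction(steep, fib24, study_spec):
    """Uncoupled-minus-coupled mean APD for Motif-1, Steep, (4,4) nS."""
    uncoupled = fm.run_paced(fm.build_motif(1, 0.0, 0.0), study_spec, steep, fib24)
    coupled = fm.run_paced(fm.build_motif(1, 4.0, 4.0), study_spec, steep, fib24)
    return (mean_apd_of(uncoupled), mean_apd_of(coupled))


@pytest.fixture(scope="session")
def restitution_steep(steep):
    return fm.s1s2_restitution(steep, t_s1=600.0)


@pytest.fixture(scope="session")
def restitution_shallow(shallow):
    return fm.s1s2_restitution(shallow, t_s1=600.0)
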