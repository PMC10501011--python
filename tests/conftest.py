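import numpy as np
import pytest

from chmfit.chm import Dataset, NonlinearParams, fit_chm
from chmfit.datagen import (
    TrajectorySpec,
    h3_plus_surrogate,
    h3_plus_typing,
    initial_geometry,
    relax,
    run_nve,
)
from chmfit.molsys import AtomTyping


@pytest.fixture(scope="session")
def heh_typing():
    return AtomTyping(
        classes={"H": (1,), "He": (0,)},
        populations={"He": 2.0, "H": 0.0},
        formal_charge=1,
        exponents={"He": 1.2, "H": 0.8},
    )


@pytest.fixture(scope="session")
def h3_typing():
    return h3_plus_typing()


@pytest.fixture(scope="session")
def ch5_typing():
    return AtomTyping(
        classes={"C": (0,), "H": (1, 2, 3, 4, 5)},
        populations={"C": 6.0, "H": 0.8},
        formal_charge=1,
        exponents={"C": 1.0, "H": 1.0},
    )


@pytest.fixture(scope="session")
def formamide_typing():
    # H2NCHO with all three hydrogens in one class: H x3, C, N, O
    return AtomTyping(
        classes={"H": (0, 1, 2), "C": (3,), "N": (4,), "O": (5,)},
        populations={"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0},
        formal_charge=0,
        exponents={"H": 1.0, "C": 1.0, "N": 1.0, "O": 1.0},
    )


@pytest.fixture(scope="session")
def h3_dataset():
    """~600-point NVE sample of the stock surrogate H3+ surface."""
    pes = h3_plus_surrogate()
    start = relax(pes, initial_geometry("h3+"))
    spec = TrajectorySpec(
        initial=start, kinetic_energy=7335.0, timestep=0.25,
        steps=2400, stride=4, seed=7,
    )
    frames = run_nve(pes, spec)
    return Dataset(
        configs=[c for c, _ in frames],
        energies=np.array([e for _, e in frames]),
    )


@pytest.fixture(scope="session")
def h3_nlparams():
    return NonlinearParams(d0=1.0, t0=1.5, alpha={"H": 0.6})


@pytest.fixture(scope="session")
def h3_chm2_report(h3_dataset, h3_typing, h3_nlparams):
    return fit_chm(h3_dataset, h3_typing, 2, h3_nlparams)


@pytest.fixture(scope="session")
def h3_chm2_model(h3_chm2_report):
    return h3_chm2_report.model
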