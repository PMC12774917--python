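import numpy as np
import pytest

from fullersense import (
    PromolecularField,
    SyntheticAtom,
    make_dimer,
    reference_dataset,
)


@pytest.fixture(scope="session")
def fixture():
    """The bundled printed-value dataset."""
    return reference_dataset()


@pytest.fixture(scope="session")
def single_gaussian():
    """Unit-amplitude, unit-exponent Gaussian atom at the origin."""
    return PromolecularField([SyntheticAtom(center=np.zeros(3))])


@pytest.fixture(scope="session")
def dimer():
    """Symmetric Gaussian dimer, separation 2 bohr, plus its sampled cube."""
    atoms, grid = make_dimer(2.0, grid_spacing=0.25)
    return PromolecularField(atoms), grid


@pytest.fixture
def summary_records():
    """A minimal bare-sensor + analyte + complex record set with totals."""
    from fullersense import QCRecord

    # raw complexation energy back-solved to -47.01 kJ/mol (= -34.30 - 12.71)
    e_raw_hartree = -47.01 / 2625.4996
    return [
        QCRecord(label="sensor", e_homo=-5.38, e_lumo=-3.70, e_total=-2284.0),
        QCRecord(label="xylene", e_homo=-6.0, e_lumo=-0.5, e_total=-310.0),
        QCRecord(
            label="sensor@xylene",
            e_homo=-5.08,
            e_lumo=-3.54,
            e_total=-2594.0 + e_raw_hartree,
            e_bsse=12.71,
            components={"sensor": "sensor", "analyte": "xylene"},
        ),
    ]
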