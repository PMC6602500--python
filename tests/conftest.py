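import numpy as np
import pytest

from srnaprof import simdata
from srnaprof.librarymap import MatureAnnotation, ReferenceLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_library():
    """Five random ~70 nt precursors, one 22 nt mature window each."""
    r = np.random.default_rng(424242)
    lib, annots = simdata.make_reference(r, n_precursors=5)
    return lib, annots


@pytest.fixture
def tiny_library():
    """Hand-built precursor with known mature window for exact checks."""
    #           0         1         2         3         4         5
    #           0123456789012345678901234567890123456789012345678901234
    prec = "GGCTAAACTGACCTGCAGTACTGGAATTCTAGGCATACCGGTATTCAGGTACCAT"
    lib = ReferenceLibrary("mirna", {"prec-X": prec})
    mature = MatureAnnotation("mir-X", "prec-X", 10, 32)
    return lib, mature
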