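import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from leutfold.structures_io import AtomRecord, Structure
from leutfold.synthetic_fixtures import FixtureSpec, toy_transporter


@pytest.fixture(scope="session")
def toy_pair():
    """Deterministic two-state toy transporter with planted 17°/8° tilts."""
    return toy_transporter(FixtureSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_structure(records):
    """Compact helper: records are (name, element, resname, resid, chain, xyz)."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            element=element,
            resname=resname,
            resid=resid,
            chain=chain,
            altloc="",
            coords=np.asarray(xyz, dtype=float),
        )
        for i, (name, element, resname, resid, chain, xyz) in enumerate(records)
    ]
    return Structure(atoms, source="test")


@pytest.fixture
def two_residue_structure():
    """Two PHE-like residues with full backbones 10 Å apart."""
    recs = []
    for resid, x0 in ((334, 0.0), (335, 10.0)):
        recs += [
            ("N", "N", "PHE", resid, "A", (x0, 0.0, 0.0)),
            ("CA", "C", "PHE", resid, "A", (x0 + 1.46, 0.0, 0.0)),
            ("C", "C", "PHE", resid, "A", (x0 + 2.0, 1.4, 0.0)),
            ("O", "O", "PHE", resid, "A", (x0 + 1.5, 2.5, 0.0)),
            ("CB", "C", "PHE", resid, "A", (x0 + 2.0, -1.2, 0.9)),
        ]
    return make_structure(recs)
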