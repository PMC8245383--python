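import re

import numpy as np
import pytest

from cmglyco.records import STANDARD_AA, ProteinRecord

# Independent sliding-window reference scanner: regex with lookahead so
# overlapping sequons are all reported. Kept deliberately separate from the
# package's scanning code path.
_ORACLE_PATTERNS = {
    "NxS": re.compile(r"(?=N[^PX]S)"),
    "NxT": re.compile(r"(?=N[^PX]T)"),
    "NxC": re.compile(r"(?=N[^PX]C)"),
    "NxV": re.compile(r"(?=N[^PX]V)"),
}


def oracle_sites(sequence: str, motif_class: str):
    """1-based Asn positions of all sequons of one class (regex oracle)."""
    pat = _ORACLE_PATTERNS[motif_class]
    return sorted(m.start() + 1 for m in pat.finditer(sequence))


@pytest.fixture
def uniform_composition():
    return {a: 1.0 / 20.0 for a in STANDARD_AA}


@pytest.fixture
def random_records():
    """200 random uniform-composition proteins, lengths 50-600, fixed seed."""
    rng = np.random.default_rng(2024)
    letters = list(STANDARD_AA)
    records = []
    for i in range(200):
        L = int(rng.integers(50, 601))
        seq = "".join(rng.choice(letters, size=L))
        records.append(ProteinRecord(id=f"R{i:03d}", sequence=seq))
    return records
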