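import numpy as np
import pytest

from eegtopo.homology import PersistenceDiagram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    """Distance matrix of four points on a unit square (sides 1, diagonals sqrt 2)."""
    s = np.sqrt(2.0)
    return np.array(
        [
            [0, 1, s, 1],
            [1, 0, 1, s],
            [s, 1, 0, 1],
            [1, s, 1, 0],
        ],
        dtype=float,
    )


def diagram(pairs, n_nodes=None, max_filtration=None):
    """Build a PersistenceDiagram from a list of (birth, death, dim) triples."""
    arr = np.array(pairs, dtype=float).reshape(-1, 3)
    if n_nodes is None:
        n_nodes = max(int((arr[:, 2] == 0).sum()), 1)
    if max_filtration is None:
        finite = arr[np.isfinite(arr[:, 1])]
        max_filtration = float(finite[:, 1].max()) if len(finite) else 1.0
    return PersistenceDiagram(pairs=arr, n_nodes=n_nodes, max_filtration=max_filtration)


@pytest.fixture
def make_diagram():
    return diagram


def random_dissimilarity(rng, n):
    """Random symmetric matrix with zero diagonal and entries in [0, 1]."""
    A = rng.uniform(0, 1, (n, n))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


@pytest.fixture
def make_dissimilarity():
    return random_dissimilarity


def write_minimal_edf(path, data, fs):
    """Hand-rolled single-record EDF writer for test inputs.

    ``data`` is channels x samples with n_samples == fs (one 1-second data
    record).  Physical range is fixed at +-1000 units.
    """
    n_sig, n_samp = data.shape
    assert n_samp == int(fs)

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("test patient", 80),
            pad("test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_sig), 8),
            pad("", 44),
            pad("1", 8),  # number of data records
            pad("1", 8),  # record duration, seconds
            pad(str(n_sig), 4),
        ]
    )
    labels = b"".join(pad(f"ch{i}", 16) for i in range(n_sig))
    transducer = b"".join(pad("", 80) for _ in range(n_sig))
    dim = b"".join(pad("uV", 8) for _ in range(n_sig))
    phys_min = b"".join(pad("-1000", 8) for _ in range(n_sig))
    phys_max = b"".join(pad("1000", 8) for _ in range(n_sig))
    dig_min = b"".join(pad("-32768", 8) for _ in range(n_sig))
    dig_max = b"".join(pad("32767", 8) for _ in range(n_sig))
    prefilter = b"".join(pad("", 80) for _ in range(n_sig))
    n_samples = b"".join(pad(str(n_samp), 8) for _ in range(n_sig))
    reserved = b"".join(pad("", 32) for _ in range(n_sig))

    scaled = np.clip(data / 1000.0 * 32767, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + phys_min + phys_max)
        fh.write(dig_min + dig_max + prefilter + n_samples + reserved)
        fh.write(scaled.tobytes())
    return path


@pytest.fixture
def edf_writer():
    return write_minimal_edf
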