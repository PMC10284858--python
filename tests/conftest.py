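import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermotrait.seqio import ProteinSeq

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_proteome():
    return [
        ProteinSeq("p1", "MKVIVYWREL"),
        ProteinSeq("p2", "DESTNQAAGG"),
    ]


@pytest.fixture
def nt_fasta(tmp_path):
    def _write(records, name="genome.fna"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path
    return _write
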