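import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pocp import ProteinRecord, Proteome

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, rec_id: str = "p") -> ProteinRecord:
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id=rec_id, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


@pytest.fixture
def tiny_proteome():
    return Proteome(
        label="tiny",
        records=[
            ProteinRecord("p1", "MKVLAATGLREQWPASDNKI" * 4),
            ProteinRecord("p2", "ACDEFGHIKLMNPQRSTVWY" * 4),
            ProteinRecord("p3", "WYVTSRQPNMLKIHGFEDCA" * 4),
        ],
    )


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, sequence) pairs."""

    def _write(records, name="genome.faa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
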