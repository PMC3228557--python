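import pytest
from hypothesis import HealthCheck, settings

from promotif import consensus_to_pwm, hbs_motif

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hbs():
    return hbs_motif()


@pytest.fixture(scope="session")
def hbs_pwm(hbs):
    return consensus_to_pwm(hbs)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as handle:
            for gene_id, seq in records:
                handle.write(f">{gene_id}\n{seq}\n")
        return path

    return _write
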