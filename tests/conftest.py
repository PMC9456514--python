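import pytest

from pepmap.registry import load_registry
from pepmap.xlms import bundled_dipeptide_table, parse_crosslink_table


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def printed_dipeptides():
    """The bundled 12-row printed hetero-dipeptide table."""
    return parse_crosslink_table(bundled_dipeptide_table())


@pytest.fixture()
def fasta_writer(tmp_path):
    def write(records, name="aln.fasta"):
        path = tmp_path / name
        with path.open("w") as fh:
            for tid, seq in records:
                fh.write(f">{tid}\n{seq}\n")
        return path

    return write
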