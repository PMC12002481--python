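import pytest

from hrmtm import load_paper_dataset


@pytest.fixture(scope="session")
def dataset():
    """The bundled study dataset, loaded once per session."""
    return load_paper_dataset()


@pytest.fixture()
def fasta_file(tmp_path):
    """Factory writing a FASTA file from {id: sequence} into tmp_path."""

    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in entries.items()))
        return path

    return _write
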