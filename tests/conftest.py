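import io

import pytest

from seqcol.analysis import CollectionManifest
from seqcol.fasta import digest_fasta_entries, parse_fasta
from seqcol.synthfix import build_test_universe

UNIVERSE_SEED = 1


@pytest.fixture(scope="session")
def universe():
    return build_test_universe(UNIVERSE_SEED)


@pytest.fixture(scope="session")
def manifest(universe):
    return CollectionManifest.from_universe(universe)


@pytest.fixture(scope="session")
def collections(manifest):
    return manifest.resolve()


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(content, name="test.fa"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def digest_text(fasta_text, **kwargs):
    """Digest in-memory FASTA content (test helper)."""
    return digest_fasta_entries(parse_fasta(io.StringIO(fasta_text)), **kwargs)
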