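import pytest

from sira.design import build_cassette
from sira.fixtures import FixtureSpec, generate_fixtures


def make_fixture(n_parts, seed=1, labels=None, small=True):
    spec = FixtureSpec(
        seed=seed,
        n_parts=n_parts,
        part_labels=labels,
        payload_length_range=(40, 70) if small else (60, 120),
        vector_backbone_length=150 if small else 300,
    )
    return generate_fixtures(spec)


def cassettes_of(fx):
    return [build_cassette(p, s) for p, s in zip(fx.parts, fx.scheme.position_sites)]


@pytest.fixture(scope="session")
def fx3():
    """Three-part toy assembly (lycopene-pathway scale)."""
    return make_fixture(3)


@pytest.fixture(scope="session")
def fx5crt():
    """Five-part array labelled like the zeaxanthin pathway, for edits."""
    return make_fixture(5, labels=("crtB", "crtE", "crtI", "crtZ", "crtY"))
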