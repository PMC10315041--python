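import pytest

from fairchecker import fixtures


@pytest.fixture(scope="session")
def server():
    """One ephemeral HTTP server serving every fixture page the suite needs,
    so protocol-level metrics are exercised against real requests."""
    pages = {
        "/bare.html": fixtures.make_bare_page(),
        "/tool.html": fixtures.make_computational_tool_page(),
        "/tool-licensed.html": fixtures.make_computational_tool_page(
            include_license=True),
    }
    with fixtures.FixtureServer(pages, redirects={"/moved.html": "/bare.html"}) as srv:
        yield srv


@pytest.fixture(scope="session")
def tool_profile():
    return fixtures.computational_tool_profile()


@pytest.fixture(scope="session")
def gene_profile():
    return fixtures.gene_profile()
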