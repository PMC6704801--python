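import pytest

from fiberfam import mybscan, synth


@pytest.fixture(scope="session")
def repeat_profile():
    """PSSM built from the seed=1 synthetic repeat family (default threshold)."""
    return mybscan.build_profile(synth.gen_repeat_family(1))


@pytest.fixture(scope="session")
def table1():
    from fiberfam import io

    return io.load_table1()
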