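import pytest

from urimod import WindowConfig, default_table, windows_for_task
from urimod.synthetic import generate, null_signal_spec, strong_signal_spec


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def strong_corpus():
    return generate(strong_signal_spec(seed=1))


@pytest.fixture(scope="session")
def null_corpus():
    return generate(null_signal_spec(seed=1))


@pytest.fixture(scope="session")
def um_windows(strong_corpus, table):
    return windows_for_task(strong_corpus, table, WindowConfig(L=17, task="UM"))


@pytest.fixture(scope="session")
def um_hybrid_windows(strong_corpus, table):
    return windows_for_task(
        strong_corpus, table, WindowConfig(L=17, task="UM", L_struct=19)
    )
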