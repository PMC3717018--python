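import pytest

from unitops import (
    build_fdg_program,
    build_fdg_with_install,
    compile_program,
    default_config,
    default_table,
)


@pytest.fixture(scope="session")
def fdg_program():
    return build_fdg_program()


@pytest.fixture(scope="session")
def fdg_with_install():
    return build_fdg_with_install()


@pytest.fixture(scope="session")
def fdg_compiled(fdg_program):
    return compile_program(fdg_program)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def table():
    return default_table()
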