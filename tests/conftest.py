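import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    from isofrag.loss_annotation import default_loss_library

    return default_loss_library()


@pytest.fixture(scope="session")
def rule_set():
    from isofrag.rule_classifier import load_rule_set

    return load_rule_set()


@pytest.fixture(scope="session")
def config():
    from isofrag.rule_classifier import ClassifierConfig

    return ClassifierConfig()


# ---------------------------------------------------------------------------
# Independent brute-force mass oracle (deliberately separate from the package
# implementation: its own mass table and its own summation loop).
# ---------------------------------------------------------------------------

_ORACLE_MASSES = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
    "Na": 22.98976928,
    "Cl": 34.96885268,
}
_ORACLE_ELECTRON = 0.00054858


def brute_force_neutral_mass(counts: dict[str, int]) -> float:
    total = 0.0
    for sym, n in counts.items():
        for _ in range(n):
            total += _ORACLE_MASSES[sym]
    return total


def brute_force_cation_mz(counts: dict[str, int]) -> float:
    return brute_force_neutral_mass(counts) - _ORACLE_ELECTRON


@pytest.fixture(scope="session")
def oracle():
    return {"neutral": brute_force_neutral_mass, "cation": brute_force_cation_mz}
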