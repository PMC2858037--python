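import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plexprimer.design import DesignConstraints, Primer, PrimerSet
from plexprimer.fixtures import FixtureSpec, generate_fixture, random_template
from plexprimer.interaction import CompatibilityMatrix, Reason, build_index
from plexprimer.thermo import NNParameterTable, ReactionConditions

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table() -> NNParameterTable:
    return NNParameterTable.default()


@pytest.fixture(scope="session")
def cond() -> ReactionConditions:
    return ReactionConditions()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def rand600():
    """A 600 bp uniform random template with a full default candidate pool."""
    return random_template(3, length=600, gc=0.5)


@pytest.fixture(scope="session")
def clean3():
    """3 zoned templates, dimer/seed-screened, clean background (all-ones matrix)."""
    spec = FixtureSpec(n_templates=3, purine_bias=0.8, ensure_clean=True,
                       seed=7, background_pad=1000)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def decoy3():
    """Same templates as clean3 (same seed) but a ~20 kb background with 2 planted decoys."""
    spec = FixtureSpec(n_templates=3, purine_bias=0.8, ensure_clean=True,
                       seed=7, background_pad=18000, n_decoys=2)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def clean5():
    """5 zoned templates mirroring a 5-plex panel, clean background."""
    spec = FixtureSpec(n_templates=5, purine_bias=0.8, ensure_clean=True,
                       seed=11, background_pad=4000)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def clean3_index(clean3):
    return build_index(clean3.background, 9)


# ---- factories for hand-built search instances --------------------------------

def make_primer(tid: str, strand: str, start: int, length: int = 20,
                penalty: float = 0.0) -> Primer:
    seq = ("ACGTTGCAGGTCACTAGGCTAACGGATCGA" * 2)[:length]
    return Primer(seq, tid, strand, start, tm=60.0, gc=50.0, end_dg=-6.0,
                  self_any=0.0, self_3p=0.0, penalty=penalty / 2.0)


def make_ps(tid: str, rank: int, penalty: float, amplicon: int) -> PrimerSet:
    fwd = make_primer(tid, "+", 0, penalty=penalty)
    rev = make_primer(tid, "-", amplicon - 1, penalty=penalty)
    return PrimerSet(fwd, rev, amplicon, penalty, rank)


def make_matrix(ps_list, incompatible=()):
    """Hand-built compatibility matrix; ``incompatible`` holds {i, j} index pairs."""
    n = len(ps_list)
    values = np.zeros((n, n), dtype=np.int8)
    reasons = [[Reason("same_template")] * n for _ in range(n)]
    blocked = {frozenset(p) for p in incompatible}
    for i in range(n):
        for j in range(i + 1, n):
            if ps_list[i].template_id == ps_list[j].template_id:
                continue
            bad = frozenset((i, j)) in blocked
            values[i, j] = values[j, i] = 0 if bad else 1
            r = Reason("dimer", "hand-built") if bad else Reason("compatible")
            reasons[i][j] = reasons[j][i] = r
    return CompatibilityMatrix(list(ps_list), values, reasons)


@pytest.fixture
def factories():
    return make_primer, make_ps, make_matrix
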