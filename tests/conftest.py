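import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ancl_exome.variant_io import Individual, Pedigree, SampleExome, VariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(20111104)


@pytest.fixture
def nuclear_family():
    """Two parents, two children, one unrelated founder."""
    return Pedigree(
        [
            Individual("dad", "male", None, None, "affected"),
            Individual("mom", "female", None, None, "unaffected"),
            Individual("kid1", "male", "dad", "mom", "affected"),
            Individual("kid2", "female", "dad", "mom", "unaffected"),
            Individual("stranger", "male", None, None, "unaffected"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """Grandparents -> two sibling parents -> first cousins."""
    return Pedigree(
        [
            Individual("gp1", "male"),
            Individual("gp2", "female"),
            Individual("p1", "male", "gp1", "gp2"),
            Individual("p2", "female", "gp1", "gp2"),
            Individual("s1", "female"),
            Individual("s2", "male"),
            Individual("c1", "male", "p1", "s1", "affected"),
            Individual("c2", "female", "s2", "p2", "affected"),
        ]
    )


def make_call(i, **kw):
    defaults = dict(
        chrom="1",
        pos=1000 + i,
        ref="A",
        alt="G",
        zygosity="het",
        depth=50,
        qual=100.0,
        var_class="missense",
    )
    defaults.update(kw)
    return VariantCall(**defaults)


def random_exome(rng, n, sample_id="s", status="affected"):
    classes = ["missense", "nonsense", "splice", "synonymous", "intronic",
               "intergenic", "coding-indel"]
    calls = []
    for i in range(n):
        calls.append(
            make_call(
                i,
                depth=int(rng.integers(0, 200)),
                qual=float(rng.integers(0, 500)),
                zygosity="hom" if rng.random() < 0.2 else "het",
                var_class=str(rng.choice(classes)),
                db_flags={"dbSNP": float(rng.random())} if rng.random() < 0.5 else {},
            )
        )
    return SampleExome(sample_id, status, calls)
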