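import pytest
from hypothesis import HealthCheck, settings

from mytilus_id.dataset import Dataset, Individual, MarkerGenotype
from mytilus_id.markers import marker_registry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def registry():
    """Fresh five-marker registry (function-scoped: open registries mutate)."""
    return marker_registry()


def build_dataset(registry, rows, populations=None):
    """rows: iterable of (id, population, marker, alleles tuple or None)."""
    inds = {}
    for ind_id, pop, marker, alleles in rows:
        ind = inds.setdefault(ind_id, Individual(id=ind_id, population=pop))
        if alleles is None:
            ind.genotypes[marker] = MarkerGenotype(marker, (), missing=True)
        else:
            ind.genotypes[marker] = MarkerGenotype(marker, tuple(alleles))
    return Dataset(list(inds.values()), registry, populations or {})


@pytest.fixture
def make_dataset(registry):
    def _make(rows, populations=None):
        return build_dataset(registry, rows, populations)

    return _make
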