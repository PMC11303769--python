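import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enamelsex import chem, load_panel
from enamelsex.simulate import SampleSpec, simulate_run

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def registry():
    return chem.ModificationRegistry.default()


@pytest.fixture(scope="session")
def male_run():
    """Default male modern sample (markers + deamidated background + decoys)."""
    spec = SampleSpec(sample_id="male42", sex="male", era="modern", seed=42)
    return simulate_run(spec)


@pytest.fixture(scope="session")
def female_run():
    spec = SampleSpec(sample_id="female43", sex="female", era="modern", seed=43)
    return simulate_run(spec)


@pytest.fixture(scope="session")
def envelope_oracle():
    """Exhaustive enumeration over isotopologue count combinations —
    independent of the convolution implementation."""

    def oracle(comp: chem.ElementalComposition, n_peaks: int) -> np.ndarray:
        total = {0: 1.0}
        for el in chem.ELEMENTS:
            n = getattr(comp, el)
            if n == 0:
                continue
            abundances = chem.ISOTOPE_ABUNDANCE[el]
            dist = {0: 1.0}
            for _ in range(n):  # add atoms one at a time
                nxt = {}
                for shift, p in dist.items():
                    for s, a in enumerate(abundances):
                        nxt[shift + s] = nxt.get(shift + s, 0.0) + p * a
                dist = nxt
            merged = {}
            for s1, p1 in total.items():
                for s2, p2 in dist.items():
                    merged[s1 + s2] = merged.get(s1 + s2, 0.0) + p1 * p2
            total = merged
        arr = np.array([total.get(i, 0.0) for i in range(n_peaks)])
        return arr / arr.sum()

    return oracle


@pytest.fixture(scope="session")
def random_compositions():
    """Random small elemental compositions (<= 20 atoms) for oracle checks."""

    def gen(n: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n:
            counts = rng.multinomial(rng.integers(1, 21), np.ones(6) / 6)
            comp = chem.ElementalComposition(*(int(c) for c in counts))
            if comp.n_atoms > 0:
                out.append(comp)
        return out

    return gen
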