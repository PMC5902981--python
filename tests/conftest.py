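import numpy as np
import pytest
from hypothesis import settings

from edsim import ScenarioSpec, builtin_scenarios, run_experiment

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20180416)


@pytest.fixture
def small_spec():
    """Desk-sized design for fast end-to-end runs."""
    return ScenarioSpec(
        name="small_test",
        n_sires=4,
        n_dams=12,
        n_off_per_mating=8,
        founder_allele_freq=0.2,
        n_burnin_generations=2,
        n_selection_generations=4,
        n_replicates=3,
        base_seed=7,
    )


@pytest.fixture(scope="session")
def experiments():
    """Session cache of full-scale scenario runs shared by the acceptance
    checks; all scenarios share seeds so comparisons are paired through the
    common burn-in phase."""
    cache: dict = {}
    scenarios = builtin_scenarios()

    def get(name: str, n_reps: int = 20, base_seed: int = 2018, **overrides):
        key = (name, n_reps, base_seed, tuple(sorted(overrides.items())))
        if key not in cache:
            spec = scenarios[name].replace(**overrides) if overrides else scenarios[name]
            cache[key] = run_experiment(spec, n_reps=n_reps, base_seed=base_seed)
        return cache[key]

    return get


def tabular_relationship_matrix(ids, sire_ids, dam_ids):
    """Independent oracle: the classic tabular method over a whole pedigree.

    ``ids`` must be topologically sorted (parents before offspring);
    unknown parents are coded 0.  Returns the full additive-relationship
    matrix in pedigree order.
    """
    ids = np.asarray(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    n = ids.size
    a = np.zeros((n, n))
    for k in range(n):
        s = pos.get(int(sire_ids[k]), -1)
        d = pos.get(int(dam_ids[k]), -1)
        for j in range(k):
            a_js = a[j, s] if s >= 0 else 0.0
            a_jd = a[j, d] if d >= 0 else 0.0
            a[j, k] = a[k, j] = 0.5 * (a_js + a_jd)
        a[k, k] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
    return a


def tabular_inbreeding(ids, sire_ids, dam_ids):
    """Per-animal inbreeding coefficients from the tabular oracle."""
    a = tabular_relationship_matrix(ids, sire_ids, dam_ids)
    return np.diag(a) - 1.0


def brute_force_select(ebv, g, sex, ids, n_sires, n_dams, b1, b2):
    """Oracle truncation selection: exhaustive sort by (index desc, id asc)."""
    index = b1 * np.asarray(ebv, dtype=float) + b2 * np.asarray(g, dtype=float)
    chosen = {}
    for want_sex, n_sel in ((1, n_sires), (0, n_dams)):
        cand = [i for i in range(len(ids)) if sex[i] == want_sex]
        cand.sort(key=lambda i: (-index[i], ids[i]))
        chosen[want_sex] = cand[:n_sel]
    return chosen[1], chosen[0]
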