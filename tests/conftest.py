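import numpy as np
import pandas as pd
import pytest

import panorama as pn


def make_cohort(
    seed: int = 0,
    n_samples: int = 100,
    n_mut: int = 30,
    n_features: int = 200,
    shift_features: dict[str, float] | None = None,
    name: str = "TEST",
    layer_kind: str = "rna",
) -> pn.Cohort:
    """Hand-rolled single-layer cohort: one mutation, Gaussian features,
    optional planted mean shifts in the mutant samples. Normalized."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    features = [f"F{i:03d}" for i in range(n_features)]
    status = np.zeros(n_samples, dtype=np.int8)
    status[:n_mut] = 1
    vals = rng.standard_normal((n_features, n_samples))
    for feat, delta in (shift_features or {}).items():
        vals[features.index(feat), status.astype(bool)] += delta
    layer, _ = pn.zscore_normalize(
        pn.OmicsMatrix(pd.DataFrame(vals, index=features, columns=samples), layer_kind)
    )
    mm = pn.MutationMatrix(pd.DataFrame([status], index=["MUT1"], columns=samples))
    return pn.assemble_cohort(name, mm, {layer_kind: layer})


@pytest.fixture(scope="session")
def sim_cohort():
    """One planted-driver synthetic cohort, normalized (shared, read-only)."""
    cfg = pn.driver_fixture_config(seed=7, n_samples=80, n_genes=200,
                                   n_phospho_sites=100, n_mutations=6)
    cohort, truth = pn.simulate_cohort(cfg)
    cohort, _ = pn.normalize_cohort(cohort)
    return cohort, truth


@pytest.fixture(scope="session")
def sim_profiles(sim_cohort):
    cohort, truth = sim_cohort
    return [pn.evaluate_mutation(cohort, g) for g in cohort.mutations.genes]
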