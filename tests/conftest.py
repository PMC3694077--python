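import numpy as np
import pandas as pd
import pytest

from rfiwgas.simlines import SimConfig, simulate_dataset


def random_pedigree(n: int, n_founders: int, rng: np.random.Generator) -> pd.DataFrame:
    """Topologically ordered random pedigree for relationship-matrix oracles."""
    rows = []
    for i in range(n):
        if i < n_founders:
            sire = dam = "0"
        else:
            males = [j for j in range(i) if j % 2 == 0]
            females = [j for j in range(i) if j % 2 == 1]
            sire = f"A{rng.choice(males)}"
            dam = f"A{rng.choice(females)}"
        rows.append(
            dict(animal_id=f"A{i}", sire_id=sire, dam_id=dam,
                 generation=0 if i < n_founders else 1,
                 line="LOW", sex="M" if i % 2 == 0 else "F",
                 parity=1, pen="P1", group="G", age_on_test=90)
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-generation divergent-selection dataset shared across tests."""
    cfg = SimConfig(
        n_founders=100, n_per_line_per_gen=100, n_generations=9,
        n_snps=400, n_chroms=4, chrom_length_bp=20_000_000,
        h2_target=0.5, selection_fraction=0.3, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_phenotypes(small_dataset):
    from rfiwgas import pheno

    tab = pheno.derive_phenotypes(
        small_dataset.weights, small_dataset.intakes,
        small_dataset.traits, small_dataset.pedigree,
    )
    return pheno.compute_rfi(
        tab, small_dataset.pedigree,
        pheno.RfiModelSpec(variance_ratios={"animal": 1.5, "dam": 20.0, "pen": 20.0}),
    )
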