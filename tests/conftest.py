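import warnings

import numpy as np
import pytest

import scresilience as sr


@pytest.fixture(scope="session")
def de_cohort():
    """Single-cluster cohort with planted DE genes (early contrast ~600 cells)."""
    cfg = sr.CohortConfig(
        n_donors_per_group=14, n_celltypes=1, n_cells_per_donor=22,
        n_genes=500, n_de_genes=25, de_log2fc=1.0,
        n_marker_genes_per_type=0, seed=42,
    )
    ds, truth = sr.simulate_cohort(cfg)
    nm = sr.normalize_log(ds)
    return ds, nm, truth


@pytest.fixture(scope="session")
def module_cohort():
    """Single-group cohort with two planted 50-gene co-expression modules."""
    cfg = sr.CohortConfig(
        n_donors_per_group=5, n_celltypes=1, n_cells_per_donor=150,
        n_genes=500, n_modules=2, module_size=50, module_strength=0.9,
        n_marker_genes_per_type=0, seed=7,
    )
    ds, truth = sr.simulate_cohort(cfg)
    nm = sr.normalize_log(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mc = sr.build_metacells(nm, ds.cell_meta["donor_id"], k=25, min_cells=50, seed=0)
    return nm, mc, truth


@pytest.fixture(scope="session")
def marker_cohort():
    """Multi-type cohort with planted marker genes for annotation tests."""
    cfg = sr.CohortConfig(
        n_donors_per_group=3, n_celltypes=3, n_cells_per_donor=150,
        n_genes=300, n_marker_genes_per_type=10, marker_log2fc=4.0, seed=11,
    )
    ds, truth = sr.simulate_cohort(cfg)
    nm = sr.normalize_log(ds)
    return ds, nm, truth


@pytest.fixture(scope="session")
def spatial_section():
    """Noiseless three-type spatial section with one-hot marker panels."""
    import pandas as pd

    genes = [f"g{i}" for i in range(12)]
    profiles = pd.DataFrame(np.zeros((3, 12)), index=["Ex5", "Ex2", "Astro"],
                            columns=genes)
    for i in range(3):
        profiles.iloc[i, i * 4:(i + 1) * 4] = 20.0
    layout = [("Ex2", 0.0, 200.0), ("Ex5", 200.0, 400.0), ("Astro", 400.0, 600.0)]
    sd = sr.simulate_spatial(300, profiles, layout, noise_rate=0.0, seed=5)
    marker_map = {t: genes[i * 4:(i + 1) * 4] for i, t in enumerate(profiles.index)}
    return sd, profiles, layout, marker_map
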