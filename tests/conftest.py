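import numpy as np
import pytest

from bfmap.quantify import InjectionSite
from bfmap.synthetic import EXCLUDED_AREA_ACRONYM, child_rng, make_atlas, random_transform


@pytest.fixture(scope="session")
def atlas12():
    """Default 12-subdivision / 53-named-area atlas."""
    return make_atlas(seed=0)


@pytest.fixture(scope="session")
def two_region_atlas():
    """Large two-area atlas for render-then-count checks."""
    return make_atlas(n_sections=1, shape=(256, 256), n_subdivisions=2,
                      areas_per_subdivision=(1, 1), seed=0)


@pytest.fixture(scope="session")
def true_transforms(atlas12):
    field, _ = atlas12
    rng = child_rng(3, 5)
    return {
        sec: random_transform(rng, (0.85, 1.15), 10.0, 8.0)
        for sec in range(field.n_sections)
    }


@pytest.fixture(scope="session")
def injection_site(atlas12):
    _, onto = atlas12
    excluded = tuple(r.id for r in onto.regions if r.acronym == EXCLUDED_AREA_ACRONYM)
    return InjectionSite(ap_mm=0.45, exclusion_um=850.0, excluded_region_ids=excluded)


@pytest.fixture(scope="session")
def populated_cells(atlas12, true_transforms, injection_site):
    """One simulated cohort: cells + ground truth, fixed seed."""
    from bfmap.synthetic import make_cell_populations

    field, onto = atlas12
    cells, gt = make_cell_populations(
        field, onto, true_transforms, injection_site,
        n_cells_range=(900, 3000), n_contamination=200,
        n_starters_range=(50, 150), seed=7,
    )
    return cells, gt
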