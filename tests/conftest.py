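import pytest

from bvfit.core import (
    BindingSite,
    BondTypeKey,
    LigandContact,
    ParameterEntry,
    ParameterSet,
)


def set_unchecked(params: ParameterSet, key: BondTypeKey, r0: float) -> None:
    """Insert an entry bypassing the (1.0, 3.5) sanity window.

    Property tests drive the closed forms over wider synthetic ranges than
    any real parameter occupies.
    """
    entry = ParameterEntry.__new__(ParameterEntry)
    entry.r0, entry.uncertainty, entry.n_sites, entry.valid_cn = r0, 0.0, 0, None
    params.entries[key] = entry

# Printed ligand distances of the two worked hemoglobin examples (A).
DEOXY_DISTANCES = [2.03, 2.06, 2.15, 2.15, 2.16, 3.39]  # five N + one O
OXY_DISTANCES = [1.75, 1.99, 2.00, 2.01, 2.01, 2.26]  # six N


def make_site(
    distances,
    elements=None,
    metal="Fe",
    oxidation_state=2,
    entry_id="TEST",
    site_id="M1",
    **kwargs,
):
    elements = elements or ["N"] * len(distances)
    return BindingSite(
        entry_id=entry_id,
        site_id=site_id,
        metal_element=metal,
        contacts=[LigandContact(e, d) for e, d in zip(elements, distances)],
        oxidation_state=oxidation_state,
        **kwargs,
    )


def single_r0_params(r0, metal="Fe", oxidation_state=2, ligands=("N", "O"), b=0.37):
    """One shared R0 across the given ligand elements (as the worked
    examples do: a single Fe-N parameter applied to all six contacts)."""
    params = ParameterSet(b=b)
    for ligand in ligands:
        params.set(BondTypeKey(metal, oxidation_state, ligand), r0)
    return params


@pytest.fixture
def deoxy_site():
    return make_site(
        DEOXY_DISTANCES, ["N", "N", "N", "N", "N", "O"], oxidation_state=2,
        entry_id="2hhb",
    )


@pytest.fixture
def oxy_site():
    return make_site(OXY_DISTANCES, oxidation_state=3, entry_id="1buw")
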