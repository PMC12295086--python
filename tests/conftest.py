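import warnings

import numpy as np
import pytest

from glycomap.structure_io import StructureModel, classify_residues
from glycomap.synthetic_data import (
    ComplexSpec,
    GlycanSpec,
    make_complex,
    make_scaffold,
    make_sugar,
)


@pytest.fixture(scope="session")
def scaffold():
    return make_scaffold()


@pytest.fixture(scope="session")
def planted(scaffold):
    """Three soaks with one sugar per subsite (GlcN at +1), jitter 0.3 Å."""
    placements = [
        ("GlcN" if lbl == 1 else "Man", i, 0.3) for i, lbl in enumerate(scaffold.labels)
    ]
    models, truth = make_complex(
        ComplexSpec(placements=placements, n_soaks=3, seed=11, scaffold=scaffold)
    )
    return models, truth


@pytest.fixture(scope="session")
def subsite_map(scaffold, planted):
    from glycomap import subsite_mapping as sm

    models, truth = planted
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        composite = sm.transfer_ligands(models, scaffold.model)
    annotation = sm.ActiveSiteAnnotation.detect(
        scaffold.model, wing_regions={"WR1": scaffold.wr1}
    )
    return sm.build_subsite_map(composite, scaffold.model, annotation), composite, truth


def single_sugar_model(sugar_type="Man", **kwargs) -> StructureModel:
    model = StructureModel(id="ONE", residues=[make_sugar(sugar_type, **kwargs)])
    return classify_residues(model)


@pytest.fixture
def mannobiose_a16() -> StructureModel:
    from glycomap.synthetic_data import make_glycan

    return make_glycan(
        GlycanSpec(residues=["Man", "Man"], linkages=[(0, 1, 6, "alpha")])
    )


@pytest.fixture
def gpi_core_spec() -> GlycanSpec:
    # Man(a1-2)Man(a1-6)Man(a1-4)GlcN, residue 0 = reducing-end GlcN
    return GlycanSpec(
        residues=["GlcN", "Man", "Man", "Man"],
        linkages=[(1, 0, 4, "alpha"), (2, 1, 6, "alpha"), (3, 2, 2, "alpha")],
    )
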