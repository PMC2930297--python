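"""Shared fixtures: analytic solids and the (expensive) cup-protein pipeline."""

from __future__ import annotations

import numpy as np
import pytest

import cavcsg
from cavcsg.fixtures import box_mesh, icosphere, toy_protein

CUP_SPACING = 0.7  # Å — cup-pipeline resolution used across the suite


@pytest.fixture(scope="session")
def sphere6():
    return icosphere(radius=6.0, subdivisions=3)


@pytest.fixture(scope="session")
def sphere6_fine():
    return icosphere(radius=6.0, subdivisions=4)


@pytest.fixture(scope="session")
def unit_box():
    return box_mesh((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def cup():
    return toy_protein("cup", seed=0)


@pytest.fixture(scope="session")
def cup_pipeline(cup):
    """Run the full cavity-extraction pipeline once for the whole suite."""
    st = cup.structure
    mol = cavcsg.molecular_surface(st, spacing=CUP_SPACING)
    env = cavcsg.envelope_surface(st, spacing=CUP_SPACING)
    patches = cavcsg.find_patches(mol, env)
    patch = cavcsg.select_patch(patches, mol, np.array([[0.0, 0.0, 8.0]]))
    lining = cavcsg.lining_residues(patch, mol, st)
    hull = cavcsg.hull_region(st, lining)
    cavity = cavcsg.assemble_cavity(hull, mol, env, CUP_SPACING, lining=lining)
    return {
        "toy": cup,
        "structure": st,
        "mol": mol,
        "env": env,
        "patches": patches,
        "patch": patch,
        "lining": lining,
        "hull": hull,
        "cavity": cavity,
        "spacing": CUP_SPACING,
    }
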