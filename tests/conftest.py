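"""Shared fixtures: a small planted family and its conformation database."""

from __future__ import annotations

import pytest

from barrelforge.assembly_design import DesignParams
from barrelforge.family_db import (
    Segment,
    SegmentationScheme,
    align_family,
    build_pssm,
    extract_fragments,
)
from barrelforge.synthetic_fixtures import FamilySpec, generate_family


def truth_scheme(truth) -> SegmentationScheme:
    """The planted segmentation of a generated family, as a scheme object."""
    return SegmentationScheme(
        truth.reference_id,
        [Segment(name, [tuple(rng)]) for name, rng in truth.segments.items()],
        catalytic=[tuple(c) for c in truth.catalytic],
    )


def family_db(structs, msa, truth, conf_radius=1.5):
    ref = structs[0]
    aligned = align_family(structs, ref, msa=msa)
    return extract_fragments(aligned, ref, truth_scheme(truth), conf_radius=conf_radius)


@pytest.fixture(scope="session")
def small_family():
    """10-member, 3-unit family with 3/2/2 planted conformational modes and
    tight in-mode noise — the workhorse fixture for clustering and design."""
    spec = FamilySpec(
        n_members=10,
        n_units=3,
        anchor_sigma=0.08,
        loop_sigma=0.15,
        n_conformational_modes=[3, 2, 2],
        seed=11,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def small_db(small_family):
    structs, msa, truth = small_family
    return family_db(structs, msa, truth)


@pytest.fixture(scope="session")
def small_params(small_db):
    return DesignParams.from_db(small_db)


@pytest.fixture(scope="session")
def planted_optimum_db(small_family):
    """A tiny DB with a uniquely optimal fragment combination.

    Built from a 4-member, 2-unit family; the fragment from source 'ref' in
    each sampled segment gets a sharp PSSM (fifty copies of its own
    sequence, ~4.3 bits per position) while all other fragments get flat
    PSSMs from random sequences, so the all-'ref' selection is the unique,
    well-separated energy optimum.  Returns (db, optimal_selection).
    """
    import numpy as np

    spec = FamilySpec(
        n_members=4,
        n_units=2,
        anchor_sigma=0.08,
        loop_sigma=0.15,
        n_conformational_modes=[3, 3],
        seed=29,
    )
    structs, msa, truth = generate_family(spec)
    db = family_db(structs, msa, truth)
    rng = np.random.default_rng(0)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    optimal = {}
    for name, frags in db.fragments.items():
        for i, f in enumerate(frags):
            if f.source_id == "ref":
                f.pssm_slice = build_pssm([f.sequence] * 50)
                optimal[name] = i
            else:
                noise = [
                    "".join(rng.choice(list(aa), size=len(f))) for _ in range(20)
                ]
                f.pssm_slice = build_pssm(noise)
    return db, optimal
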