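from itertools import combinations

import numpy as np
import pytest

import mitogeo as mg


@pytest.fixture(scope="session")
def reference():
    return mg.ReferenceGenome.synthetic(seed=0)


@pytest.fixture(scope="session")
def small_reference():
    return mg.ReferenceGenome.synthetic(length=200, seed=3, name="tiny-ref")


@pytest.fixture(scope="session")
def tree():
    return mg.toy_tree()


def random_profiles(rng: np.random.Generator, n_samples: int, n_sites: int = 40,
                    mut_prob: float = 0.15, focal_frac: float = 0.6,
                    length: int = 16569):
    """Random variant profiles plus focal/external metadata for oracle tests.

    Mutations are drawn from a small shared site alphabet so that shared
    carrier sets arise often.
    """
    positions = rng.choice(np.arange(100, length, 7), size=n_sites, replace=False)
    alleles = {int(p): ("A", "G") for p in positions}
    profiles, metadata = [], {}
    for i in range(n_samples):
        sid = f"s{i:02d}"
        muts = [
            mg.make_profile("x", [f"{alleles[int(p)][0]}{int(p)}{alleles[int(p)][1]}"]).mutations[0]
            for p in positions
            if rng.random() < mut_prob
        ]
        profiles.append(mg.VariantProfile(sid, tuple(sorted(muts))))
        focal = i < int(round(focal_frac * n_samples))
        metadata[sid] = mg.SampleMetadata(
            sid, "Loc" if focal else "Ext", "NorthAfrica" if focal else "Europe")
    return profiles, metadata


def exhaustive_clades(profiles, metadata, focal_region, mask=mg.EMPTY_MASK, min_size=2):
    """Independent clade oracle: test every focal subset against the definition.

    A focal subset S qualifies when some unmasked mutation is carried by all
    of S and by nobody outside S; maximal qualifying subsets are the clades,
    each with exactly the mutations whose carrier set is S.
    """
    focal = [p for p in profiles
             if metadata[p.sample_id].macro_region == focal_region]
    muts_of = {
        p.sample_id: {m.canonical() for m in p.mutations if not mask.is_masked(m)}
        for p in profiles
    }
    qualifying = {}
    for size in range(min_size, len(focal) + 1):
        for combo in combinations(focal, size):
            ids = frozenset(p.sample_id for p in combo)
            shared = set.intersection(*(muts_of[p.sample_id] for p in combo))
            outside = set().union(*(muts_of[sid] for sid in muts_of if sid not in ids), set())
            defining = frozenset(shared - outside)
            if defining:
                qualifying[ids] = defining
    maximal = {
        ids: defs for ids, defs in qualifying.items()
        if not any(ids < other for other in qualifying)
    }
    return maximal
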