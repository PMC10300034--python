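"""Region-specific clade detection inside haplogroups.

A focal-region-specific clade is a group of at least ``min_size``
focal-region sequences that belong to the same haplogroup and share at
least one non-recurrent mutation absent from every other sequence under
consideration. Detection is the carrier-set algorithm: for every unmasked
mutation v, let C(v) be its carrier set; keep v when C(v) is non-empty,
contains only focal samples, and has at least ``min_size`` members; group
kept mutations by identical carrier set; emit the maximal carrier sets as
clades (nested kept sets are reported as internal substructure, not as
separate clades).

The same machinery runs with roles swapped to find external-specific
clades inside the autochthonous (M1/U6-type) haplogroups, and a
minimum-spanning haplotype network is provided for reporting only — clade
calls never depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .refio import EMPTY_MASK, RecurrentSiteMask, SampleMetadata, VariantProfile
from .diversity import pairwise_difference


class CladeError(ValueError):
    pass


@dataclass
class CladeCall:
    """A detected clade with the mutations that separate it from the rest."""

    haplogroup: str
    member_ids: frozenset[str]
    defining_mutations: frozenset[str]
    is_identical_cluster: bool = False
    closest_external: tuple[str, str, int] | None = None  # (id, macro_region, distance)
    substructure: list[tuple[frozenset[str], frozenset[str]]] = field(default_factory=list)
    near_misses: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _haplotype_key(profile: VariantProfile, mask: RecurrentSiteMask) -> tuple[str, ...]:
    return tuple(m.canonical() for m in profile.mutations if not mask.is_masked(m))


def select_haplogroups(calls: Mapping[str, str], metadata: Mapping[str, SampleMetadata],
                       focal_region: str, min_count: int = 2) -> list[str]:
    """Haplogroups with at least ``min_count`` focal samples.

    ``calls`` maps sample id to haplogroup name. Sorted by focal count
    descending, then name, for deterministic output.
    """
    counts: dict[str, int] = {}
    for sid, hg in calls.items():
        md = metadata.get(sid)
        if md is not None and md.macro_region == focal_region:
            counts[hg] = counts.get(hg, 0) + 1
    keep = [(hg, n) for hg, n in counts.items() if n >= min_count]
    return [hg for hg, _ in sorted(keep, key=lambda t: (-t[1], t[0]))]


def _carrier_set_clades(profiles: Sequence[VariantProfile], focal_ids: frozenset[str],
                        mask: RecurrentSiteMask, min_size: int,
                        haplogroup: str) -> list[CladeCall]:
    carriers: dict[str, frozenset[str]] = {}
    for p in profiles:
        for m in p.mutations:
            if mask.is_masked(m):
                continue
            v = m.canonical()
            carriers[v] = carriers.get(v, frozenset()) | {p.sample_id}
    kept: dict[frozenset[str], set[str]] = {}
    for v, cset in carriers.items():
        if cset and cset <= focal_ids and len(cset) >= min_size:
            kept.setdefault(cset, set()).add(v)

    keys = list(kept)
    maximal = [c for c in keys if not any(c < other for other in keys)]
    haplotypes = {p.sample_id: _haplotype_key(p, mask) for p in profiles}
    by_id = {p.sample_id: p for p in profiles}

    out: list[CladeCall] = []
    for cset in sorted(maximal, key=lambda c: (-len(c), sorted(c))):
        defining = frozenset(kept[cset])
        nested = [
            (other, frozenset(kept[other]))
            for other in keys
            if other < cset
        ]
        identical = len({haplotypes[sid] for sid in cset}) == 1
        # focal samples just outside the clade: carry all but one defining mutation
        near = []
        if len(defining) > 1:
            for sid in sorted(focal_ids - cset):
                if sid not in by_id:
                    continue
                have = {m.canonical() for m in by_id[sid].mutations} & defining
                if len(have) >= len(defining) - 1:
                    near.append(sid)
        out.append(CladeCall(
            haplogroup=haplogroup,
            member_ids=cset,
            defining_mutations=defining,
            is_identical_cluster=identical,
            substructure=sorted(nested, key=lambda t: sorted(t[0])),
            near_misses=near,
        ))
    return out


def find_focal_clades(
    profiles: Sequence[VariantProfile],
    metadata: Mapping[str, SampleMetadata],
    focal_region: str,
    mask: RecurrentSiteMask = EMPTY_MASK,
    min_size: int = 2,
    haplogroup: str = "",
    calls: Mapping[str, str] | None = None,
) -> list[CladeCall]:
    """Focal-region-specific clades among profiles of one haplogroup.

    ``calls`` (sample id -> haplogroup) is optional; when given, all
    profiles must carry the same label, which becomes the clade haplogroup.
    """
    if calls is not None:
        labels = {calls[p.sample_id] for p in profiles if p.sample_id in calls}
        if len(labels) > 1:
            raise CladeError(f"mixed haplogroup labels {sorted(labels)}")
        if labels:
            haplogroup = labels.pop()
    focal = frozenset(
        p.sample_id for p in profiles
        if p.sample_id in metadata and metadata[p.sample_id].macro_region == focal_region
    )
    return _carrier_set_clades(profiles, focal, mask, min_size, haplogroup)


def find_identical_clusters(
    profiles: Sequence[VariantProfile],
    mask: RecurrentSiteMask = EMPTY_MASK,
    min_size: int = 2,
    haplogroup: str = "",
    other_profiles: Sequence[VariantProfile] = (),
) -> list[CladeCall]:
    """Groups of focal samples with identical unmasked profiles.

    Defining mutations are the members' shared mutations absent from every
    profile in ``other_profiles``; the set may be empty (the cluster flag
    still marks the call).
    """
    groups: dict[tuple[str, ...], list[str]] = {}
    for p in profiles:
        groups.setdefault(_haplotype_key(p, mask), []).append(p.sample_id)
    other_sets = [
        {m.canonical() for m in p.mutations if not mask.is_masked(m)} for p in other_profiles
    ]
    out: list[CladeCall] = []
    for key, ids in sorted(groups.items(), key=lambda t: sorted(t[1])):
        if len(ids) < min_size:
            continue
        shared = set(key)
        private = frozenset(v for v in shared if not any(v in o for o in other_sets))
        out.append(CladeCall(
            haplogroup=haplogroup,
            member_ids=frozenset(ids),
            defining_mutations=private if other_profiles else frozenset(),
            is_identical_cluster=True,
        ))
    return out


def closest_external(
    clade: CladeCall,
    panel: Sequence[VariantProfile],
    metadata: Mapping[str, SampleMetadata],
    focal_region: str,
    mask: RecurrentSiteMask = EMPTY_MASK,
) -> tuple[str, str, int]:
    """The non-focal panel sample closest to the clade.

    Distance is the minimum unmasked pairwise difference to any member;
    ties break by smallest mean distance to all members, then id.
    """
    members = [p for p in panel if p.sample_id in clade.member_ids]
    externals = [
        p for p in panel
        if p.sample_id in metadata and metadata[p.sample_id].macro_region != focal_region
    ]
    if not externals:
        raise CladeError("panel contains no non-focal samples")
    if not members:
        raise CladeError("panel contains no clade members")
    best: tuple[float, float, str] | None = None
    for ext in externals:
        ds = [pairwise_difference(ext, m, mask) for m in members]
        key = (min(ds), sum(ds) / len(ds), ext.sample_id)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2], metadata[best[2]].macro_region, int(best[0])


def attach_closest_externals(
    clades: Iterable[CladeCall],
    panel: Sequence[VariantProfile],
    metadata: Mapping[str, SampleMetadata],
    focal_region: str,
    mask: RecurrentSiteMask = EMPTY_MASK,
) -> list[CladeCall]:
    out = []
    for c in clades:
        c.closest_external = closest_external(c, panel, metadata, focal_region, mask)
        out.append(c)
    return out


def reverse_direction_clades(
    profiles: Sequence[VariantProfile],
    metadata: Mapping[str, SampleMetadata],
    focal_region: str,
    mask: RecurrentSiteMask = EMPTY_MASK,
    min_size: int = 2,
    haplogroup: str = "",
) -> tuple[list[CladeCall], list[tuple[str, str, str, int]]]:
    """External-specific clades plus external singletons, roles swapped.

    Used inside the autochthonous haplogroups: detects clades specific to
    the *non*-focal samples, and pairs every external sequence outside any
    such clade with its closest focal sequence. Singletons are returned as
    (external id, closest focal id, external macro_region, distance).
    """
    external = frozenset(
        p.sample_id for p in profiles
        if p.sample_id in metadata and metadata[p.sample_id].macro_region != focal_region
    )
    clades = _carrier_set_clades(profiles, external, mask, min_size, haplogroup)
    in_clade = set().union(*(c.member_ids for c in clades)) if clades else set()
    focal_profiles = [p for p in profiles if p.sample_id not in external]
    singletons: list[tuple[str, str, str, int]] = []
    for p in profiles:
        if p.sample_id not in external or p.sample_id in in_clade:
            continue
        if not focal_profiles:
            raise CladeError("no focal samples to pair singletons with")
        best = min(
            ((pairwise_difference(p, f, mask), f.sample_id) for f in focal_profiles),
        )
        singletons.append((p.sample_id, best[1], metadata[p.sample_id].macro_region, int(best[0])))
    return clades, sorted(singletons)


def subset_panel(
    focal_profiles: Sequence[VariantProfile],
    external_profiles: Sequence[VariantProfile],
    mask: RecurrentSiteMask = EMPTY_MASK,
    k: int = 20,
) -> list[str]:
    """Ids of the k nearest external sequences per distinct focal haplotype.

    Mirrors neighbourhood construction by sequence similarity: the union
    over focal haplotypes of their k closest externals.
    """
    reps: dict[tuple[str, ...], VariantProfile] = {}
    for p in focal_profiles:
        reps.setdefault(_haplotype_key(p, mask), p)
    keep: set[str] = set()
    for rep in reps.values():
        ranked = sorted(
            ((pairwise_difference(rep, e, mask), e.sample_id) for e in external_profiles)
        )
        keep.update(sid for _, sid in ranked[:k])
    return sorted(keep)


# ---------------------------------------------------------------------------
# Minimum-spanning haplotype network (reporting only)
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Haplotype network: collapsed haplotypes and all minimum-spanning edges."""

    nodes: dict[tuple[str, ...], list[str]]  # haplotype -> member ids
    edges: list[tuple[tuple[str, ...], tuple[str, ...], int]]


def build_network(profiles: Sequence[VariantProfile],
                  mask: RecurrentSiteMask = EMPTY_MASK) -> Network:
    """Minimum-spanning network over collapsed haplotypes, ties retained.

    An edge belongs to the network iff it belongs to *some* minimum
    spanning tree, i.e. its endpoints lie in different components of the
    graph restricted to strictly lighter edges (Kruskal with whole weight
    classes admitted together).
    """
    nodes: dict[tuple[str, ...], list[str]] = {}
    reps: dict[tuple[str, ...], VariantProfile] = {}
    for p in profiles:
        key = _haplotype_key(p, mask)
        nodes.setdefault(key, []).append(p.sample_id)
        reps.setdefault(key, p)
    keys = sorted(nodes)
    if len(keys) < 2:
        return Network(nodes, [])
    weighted = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = pairwise_difference(reps[keys[i]], reps[keys[j]], mask)
            weighted.append((max(d, 1), i, j))
    weighted.sort()
    uf = nx.utils.UnionFind(range(len(keys)))
    edges: list[tuple[tuple[str, ...], tuple[str, ...], int]] = []
    pos = 0
    while pos < len(weighted):
        w = weighted[pos][0]
        batch = []
        while pos < len(weighted) and weighted[pos][0] == w:
            _, i, j = weighted[pos]
            if uf[i] != uf[j]:
                batch.append((i, j))
                edges.append((keys[i], keys[j], w))
            pos += 1
        for i, j in batch:
            uf.union(i, j)
    return Network(nodes, edges)
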