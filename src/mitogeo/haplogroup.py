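"""Haplogroup classification against a phylotree-style tree.

A haplogroup tree is data, not code: a TSV of (node, parent, defining
mutations). The cumulative expected profile of a node is the fold of its
root-to-node defining mutations, where a trailing ``!`` (the phylotree
back-mutation marker) removes whatever earlier mutation sits at that site,
and a later mutation at an already-mutated site replaces the earlier one.

Calls use the Kulczynski match score, the measure behind the Haplogrep
quality score:

    score = 1/2 * (|found| / |expected| + |found| / |observed|)

with found = expected ∩ observed, computed after removing masked mutations
from both sides and after dropping expected mutations at the sample's
missing sites. Exact hotspot weighting of the original tool is not
replicated; the recurrent-site mask plays that role. Ties are broken by
greater node depth, then lexicographically, for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .refio import (
    EMPTY_MASK,
    Mutation,
    RecurrentSiteMask,
    RefIOError,
    SampleMetadata,
    VariantProfile,
    parse_mutation,
)


class HaplotreeError(ValueError):
    pass


@dataclass
class Haplotree:
    """Rooted haplogroup tree; ``nodes`` maps name -> (parent or None, tokens)."""

    nodes: dict[str, tuple[str | None, tuple[str, ...]]]

    def __post_init__(self) -> None:
        roots = [n for n, (p, _) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise HaplotreeError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for name, (parent, _) in self.nodes.items():
            if parent is not None and parent not in self.nodes:
                raise HaplotreeError(f"node '{name}' has unknown parent '{parent}'")
        # cycle check + depth computation in one walk
        self._depth: dict[str, int] = {}
        for name in self.nodes:
            seen: list[str] = []
            cur: str | None = name
            while cur is not None and cur not in self._depth:
                if cur in seen:
                    raise HaplotreeError(f"cycle through node '{cur}'")
                seen.append(cur)
                cur = self.nodes[cur][0]
            base = self._depth.get(cur, -1) if cur is not None else -1
            for i, n in enumerate(reversed(seen)):
                self._depth[n] = base + 1 + i
        self._profiles: dict[str, frozenset[Mutation]] = {}

    def depth(self, name: str) -> int:
        return self._depth[name]

    def path(self, name: str) -> list[str]:
        out: list[str] = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur][0]
        return out[::-1]

    def cumulative_profile(self, name: str) -> frozenset[Mutation]:
        """Expected mutations of a node: fold of root->node defining tokens."""
        if name in self._profiles:
            return self._profiles[name]
        if name not in self.nodes:
            raise HaplotreeError(f"unknown node '{name}'")
        parent, tokens = self.nodes[name]
        state: dict[tuple[int, int], Mutation] = (
            {} if parent is None else {m.site: m for m in self.cumulative_profile(parent)}
        )
        for tok in tokens:
            if tok.endswith("!"):
                site = parse_mutation(tok[:-1]).site
                state.pop(site, None)
            else:
                mut = parse_mutation(tok)
                state[mut.site] = mut
        prof = frozenset(state.values())
        self._profiles[name] = prof
        return prof


def load_haplotree(path: str | Path) -> Haplotree:
    """Load a haplogroup tree TSV: node, parent ('.' for root), mutations.

    Mutations are space-separated phylotree tokens; '.' or empty means none.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(".")
    needed = {"node", "parent", "mutations"}
    if not needed <= set(df.columns):
        raise HaplotreeError(f"haplotree missing columns {sorted(needed - set(df.columns))}")
    nodes: dict[str, tuple[str | None, tuple[str, ...]]] = {}
    for row in df.itertuples(index=False):
        if row.node in nodes:
            raise HaplotreeError(f"duplicate node '{row.node}'")
        parent = None if row.parent in (".", "") else row.parent
        tokens = tuple(t for t in row.mutations.split() if t != ".")
        for t in tokens:  # validate notation early
            try:
                parse_mutation(t[:-1] if t.endswith("!") else t)
            except RefIOError as exc:
                raise HaplotreeError(f"node '{row.node}': {exc}") from exc
        nodes[row.node] = (parent, tokens)
    return Haplotree(nodes)


def toy_tree() -> Haplotree:
    """The small synthetic tree bundled for tests and examples."""
    return load_haplotree(Path(__file__).parent / "data" / "toy_tree.tsv")


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    score: float
    found: tuple[str, ...]
    missing: tuple[str, ...]
    private: tuple[str, ...]


def _kulczynski(n_found: int, n_expected: int, n_observed: int) -> float:
    term1 = 1.0 if n_expected == 0 else n_found / n_expected
    term2 = 1.0 if n_observed == 0 else n_found / n_observed
    return 0.5 * (term1 + term2)


def classify(profile: VariantProfile, tree: Haplotree,
             mask: RecurrentSiteMask = EMPTY_MASK) -> HaplogroupCall:
    """Best-scoring haplogroup for one profile.

    Masked mutations are excluded from both the observed profile and every
    expected profile; expected mutations at the sample's missing positions
    are not penalised.
    """
    if not tree.nodes:
        raise HaplotreeError("empty tree")
    observed = {m.canonical() for m in profile.mutations if not mask.is_masked(m)}
    best_key: tuple[float, int] | None = None
    best_name = ""
    best_sets: tuple[set[str], set[str]] = (set(), set())
    # iterate in name order so that on (score, depth) ties the
    # lexicographically smallest name wins deterministically
    for name in sorted(tree.nodes):
        expected = {
            m.canonical()
            for m in tree.cumulative_profile(name)
            if not mask.is_masked(m) and m.position not in profile.missing
        }
        found = expected & observed
        score = _kulczynski(len(found), len(expected), len(observed))
        key = (score, tree.depth(name))
        if best_key is None or key > best_key:
            best_key = key
            best_name = name
            best_sets = (found, expected - found)
    assert best_key is not None
    found, miss = best_sets
    return HaplogroupCall(
        sample_id=profile.sample_id,
        haplogroup=best_name,
        score=best_key[0],
        found=tuple(sorted(found)),
        missing=tuple(sorted(miss)),
        private=tuple(sorted(observed - found)),
    )


def classify_all(profiles: Iterable[VariantProfile], tree: Haplotree,
                 mask: RecurrentSiteMask = EMPTY_MASK) -> list[HaplogroupCall]:
    return [classify(p, tree, mask) for p in profiles]


@dataclass(frozen=True)
class SuperGroupScheme:
    """Ordered prefix rules mapping haplogroup names to coarse categories.

    The default reproduces the usual North African summary bins: the
    autochthonous M1 and U6 lineages, sub-Saharan L, H/HV, and a catch-all
    for the remaining West Eurasian haplogroups.
    """

    rules: tuple[tuple[str, str], ...] = (
        ("M1", "M1"),
        ("U6", "U6"),
        ("L", "L"),
        ("HV", "H/HV"),
        ("H", "H/HV"),
    )
    default: str = "other WE"

    def category(self, haplogroup: str) -> str:
        for prefix, label in self.rules:
            if haplogroup.startswith(prefix):
                return label
        return self.default

    def categories(self) -> list[str]:
        seen: list[str] = []
        for _, label in self.rules:
            if label not in seen:
                seen.append(label)
        seen.append(self.default)
        return seen


DEFAULT_SCHEME = SuperGroupScheme()


def composition_table(
    calls: Sequence[HaplogroupCall],
    metadata: Mapping[str, SampleMetadata],
    scheme: SuperGroupScheme = DEFAULT_SCHEME,
    by: str = "locality",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population supergroup composition.

    Returns (fractions, counts); fraction rows sum to 1. ``by`` selects the
    grouping metadata field ('locality' or 'macro_region').
    """
    rows = []
    for call in calls:
        md = metadata.get(call.sample_id)
        if md is None:
            raise HaplotreeError(f"sample '{call.sample_id}' has no metadata")
        pop = getattr(md, by)
        rows.append((pop, scheme.category(call.haplogroup)))
    df = pd.DataFrame(rows, columns=["population", "category"])
    counts = (
        df.groupby(["population", "category"]).size().unstack(fill_value=0)
        .reindex(columns=[c for c in scheme.categories() if c in set(df["category"])],
                 fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return fractions, counts
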