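"""Synthetic mitogenome panels with known clade structure and node ages.

The generator plants focal-region-specific clades under a strict molecular
clock: every branch of length ``t`` years accumulates ``Poisson(rate x
genome_length x t)`` substitutions, placed at sites drawn with optional
hotspot weighting. Time is expressed in years directly (the clock rate is
per site per year), so no generation-time conversion exists anywhere.

The infinite-sites assumption is *not* made: repeated hits at the same
site are allowed and resolved last-event-wins along each root-to-tip path,
which is precisely what makes the recurrent-site mask meaningful.

Each planted clade records its true membership, true internal TMRCA, true
split age, and the anchor mutations that define it, so that clade
detection and rho dating can be scored against ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import (
    ReferenceGenome,
    SampleMetadata,
    VariantProfile,
    call_variants,
    write_metadata,
    write_sequences,
)

_BASE_LIST = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}

DEFAULT_RATE = 2.355e-8  # substitutions per site per year, selection-corrected
DEFAULT_FOCAL_REGION = "NorthAfrica"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ClockParams:
    """Strict molecular clock: one rate for every branch."""

    rate_per_site_per_year: float = DEFAULT_RATE
    genome_length: int = 16569

    def __post_init__(self) -> None:
        if self.rate_per_site_per_year <= 0 or self.genome_length <= 0:
            raise SimulationError("clock rate and genome length must be positive")

    @property
    def lam(self) -> float:
        """Expected substitutions per genome per year."""
        return self.rate_per_site_per_year * self.genome_length


@dataclass(frozen=True)
class HotspotModel:
    """Mutation hotspots: listed sites mutate ``rate_multiplier`` times faster."""

    sites: frozenset[int] = frozenset()
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_multiplier < 1.0:
            raise SimulationError("rate_multiplier must be >= 1")

    def site_weights(self, genome_length: int) -> np.ndarray:
        w = np.ones(genome_length)
        for s in self.sites:
            if 1 <= s <= genome_length:
                w[s - 1] = self.rate_multiplier
        return w / w.sum()


UNIFORM_SITES = HotspotModel()


@dataclass(frozen=True)
class SimCladeSpec:
    """One planted clade: focal tips, optional external sister tips, ages."""

    label: str
    n_focal_by_locality: Mapping[str, int]
    n_external: int = 0
    external_region: str = "Europe"
    true_internal_tmrca_years: float = 2000.0
    true_split_years: float = 6000.0
    tree_shape: str = "star"
    n_anchor_mutations: int = 1

    def __post_init__(self) -> None:
        if self.true_split_years < self.true_internal_tmrca_years:
            raise SimulationError(
                f"clade {self.label}: split age {self.true_split_years} < "
                f"internal TMRCA {self.true_internal_tmrca_years}"
            )
        if self.tree_shape not in ("star", "coalescent"):
            raise SimulationError(f"unknown tree_shape {self.tree_shape!r}")
        if self.n_focal() + self.n_external < 2:
            raise SimulationError(f"clade {self.label}: needs at least 2 tips")

    def n_focal(self) -> int:
        return sum(self.n_focal_by_locality.values())


@dataclass(frozen=True)
class CladeTruth:
    label: str
    member_ids: tuple[str, ...]
    defining_mutations: tuple[str, ...]
    true_internal_tmrca_years: float
    true_split_years: float
    is_identical_cluster: bool


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    clades: list[CladeTruth] = field(default_factory=list)
    tip_metadata: dict[str, SampleMetadata] = field(default_factory=dict)
    seed: int = 0

    def clade_by_label(self, label: str) -> CladeTruth:
        for c in self.clades:
            if c.label == label:
                return c
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.label, ",".join(c.member_ids), ",".join(c.defining_mutations) or ".",
             c.true_internal_tmrca_years, c.true_split_years, int(c.is_identical_cluster))
            for c in self.clades
        ]
        return pd.DataFrame(rows, columns=[
            "label", "member_ids", "defining_mutations",
            "true_internal_tmrca_years", "true_split_years", "is_identical_cluster"])


def _clade_rng(seed: int, label: str) -> np.random.Generator:
    """Per-clade substream keyed by label hash, order-independent."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF])


def _mutate_branch(seq: np.ndarray, t_years: float, clock: ClockParams,
                   weights: np.ndarray, rng: np.random.Generator,
                   forbidden: frozenset[int] = frozenset()) -> np.ndarray:
    """Apply Poisson(lam*t) substitutions to a copy of ``seq`` (0-based array).

    Repeated hits are last-event-wins; ``forbidden`` sites (1-based) are
    never hit (used to keep anchor mutations clean on the stem).
    """
    seq = seq.copy()
    if t_years < 0:
        if t_years < -1e-6:
            raise SimulationError(f"negative branch length {t_years}")
        t_years = 0.0  # rescaling round-off
    n = rng.poisson(clock.lam * t_years)
    if n == 0:
        return seq
    if forbidden:
        w = weights.copy()
        for s in forbidden:
            w[s - 1] = 0.0
        w = w / w.sum()
    else:
        w = weights
    sites = rng.choice(len(seq), size=n, p=w)
    for s in sites:
        current = seq[s]
        alts = [b for b in "ACGT" if b != current]
        # 10:1 transition:transversion odds, the classic mtDNA bias
        ts = _TRANSITION_OF[current]
        tv = [b for b in alts if b != ts]
        probs = np.array([10.0 if b == ts else 1.0 for b in alts])
        seq[s] = rng.choice(alts, p=probs / probs.sum())
    return seq


def _coalescent_heights(n: int, rng: np.random.Generator) -> tuple[list[tuple], float]:
    """Random Kingman topology over ``n`` tips; returns (tree, root height).

    The tree is nested tuples of (left, right, height); tips are integers
    at height 0. Heights are in coalescent units and rescaled by callers.
    """
    nodes: list[tuple | int] = list(range(n))
    heights = {i: 0.0 for i in range(n)}
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        merged = (left, right, t)
        nodes.append(merged)
    return nodes[0], t


def _drop_tips(node, parent_height: float, seq: np.ndarray, clock: ClockParams,
               weights: np.ndarray, rng: np.random.Generator,
               out: list[np.ndarray]) -> None:
    if isinstance(node, tuple):
        left, right, height = node
        child_seq = _mutate_branch(seq, parent_height - height, clock, weights, rng)
        _drop_tips(left, height, child_seq, clock, weights, rng, out)
        _drop_tips(right, height, child_seq, clock, weights, rng, out)
    else:
        out.append(_mutate_branch(seq, parent_height, clock, weights, rng))


def simulate_clade(
    spec: SimCladeSpec,
    clock: ClockParams = ClockParams(),
    hotspots: HotspotModel = UNIFORM_SITES,
    seed: int = 0,
    reference: ReferenceGenome | None = None,
    focal_region: str = DEFAULT_FOCAL_REGION,
    root_sequence: np.ndarray | None = None,
) -> tuple[list[tuple[str, str]], list[SampleMetadata], SimTruth]:
    """Simulate one planted clade; same seed gives byte-identical output.

    Focal tips coalesce at ``true_internal_tmrca_years`` (star or rescaled
    Kingman topology); external tips attach at the split node at
    ``true_split_years``. Anchor mutations — the private ancestral variants
    that make the clade detectable — sit on the focal stem branch at
    non-hotspot sites.
    """
    if reference is None:
        reference = ReferenceGenome.synthetic(clock.genome_length, seed=0)
    rng = _clade_rng(seed, spec.label)
    weights = hotspots.site_weights(reference.length)
    base_seq = (np.array(list(reference.bases)) if root_sequence is None
                else root_sequence.copy())

    # stem: split node -> focal clade root, carrying the anchor mutations
    anchor_sites: list[int] = []
    candidates = [p for p in range(1, reference.length + 1) if p not in hotspots.sites]
    picks = rng.choice(len(candidates), size=spec.n_anchor_mutations, replace=False)
    anchor_sites = [candidates[i] for i in sorted(picks)]
    stem_seq = base_seq.copy()
    anchors: list[str] = []
    for s in anchor_sites:
        ref_base = stem_seq[s - 1]
        stem_seq[s - 1] = _TRANSITION_OF[ref_base]
        anchors.append(f"{ref_base}{s}{_TRANSITION_OF[ref_base]}")
    stem_len = spec.true_split_years - spec.true_internal_tmrca_years
    # anchors consume part of the stem's clock budget: deduct their
    # years-equivalent so the total stem mutation count keeps the strict
    # clock expectation lam * stem_len (exact whenever the stem is long
    # enough to afford the anchors; otherwise detectability wins)
    stem_rand_len = max(stem_len - spec.n_anchor_mutations / clock.lam, 0.0)
    stem_seq = _mutate_branch(stem_seq, stem_rand_len, clock, weights, rng,
                              forbidden=frozenset(anchor_sites))

    # focal subtree below the clade root
    focal_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    for loc, n in sorted(spec.n_focal_by_locality.items()):
        for i in range(n):
            sid = f"{spec.label}_F{len(focal_ids) + 1}_{loc}"
            focal_ids.append(sid)
            metadata.append(SampleMetadata(sid, loc, focal_region))
    tip_seqs: list[np.ndarray] = []
    n_focal = len(focal_ids)
    if spec.tree_shape == "star" or n_focal <= 2:
        for _ in range(n_focal):
            tip_seqs.append(_mutate_branch(stem_seq, spec.true_internal_tmrca_years,
                                           clock, weights, rng))
    else:
        tree, root_h = _coalescent_heights(n_focal, rng)
        scale = spec.true_internal_tmrca_years / root_h

        def rescale(node):
            if isinstance(node, tuple):
                return (rescale(node[0]), rescale(node[1]), node[2] * scale)
            return node

        _drop_tips(rescale(tree), spec.true_internal_tmrca_years, stem_seq,
                   clock, weights, rng, tip_seqs)

    # external tips hang from the split node
    ext_ids: list[str] = []
    for i in range(spec.n_external):
        sid = f"{spec.label}_X{i + 1}"
        ext_ids.append(sid)
        metadata.append(SampleMetadata(sid, spec.external_region, spec.external_region))
        tip_seqs.append(_mutate_branch(base_seq, spec.true_split_years, clock, weights, rng))

    records = [(sid, "".join(seq)) for sid, seq in zip(focal_ids + ext_ids, tip_seqs)]
    truth = SimTruth(
        clades=[CladeTruth(
            label=spec.label,
            member_ids=tuple(focal_ids),
            defining_mutations=tuple(anchors),
            true_internal_tmrca_years=spec.true_internal_tmrca_years,
            true_split_years=spec.true_split_years,
            is_identical_cluster=spec.true_internal_tmrca_years == 0,
        )],
        tip_metadata={m.sample_id: m for m in metadata},
        seed=seed,
    )
    return records, metadata, truth


@dataclass(frozen=True)
class BackgroundSpec:
    """Unrelated background sequences: independent draws at a fixed divergence."""

    groups: tuple[tuple[str, str, int], ...] = ()  # (locality, macro_region, n)
    divergence_years: float = 20000.0


def simulate_panel(
    clade_specs: Sequence[SimCladeSpec],
    clock: ClockParams = ClockParams(),
    hotspots: HotspotModel = UNIFORM_SITES,
    seed: int = 0,
    background: BackgroundSpec = BackgroundSpec(),
    reference: ReferenceGenome | None = None,
    focal_region: str = DEFAULT_FOCAL_REGION,
) -> tuple[list[tuple[str, str]], list[SampleMetadata], SimTruth]:
    """Union of planted clades plus unrelated background sequences."""
    labels = [s.label for s in clade_specs]
    if len(set(labels)) != len(labels):
        raise SimulationError("clade labels must be unique")
    if reference is None:
        reference = ReferenceGenome.synthetic(clock.genome_length, seed=0)
    records: list[tuple[str, str]] = []
    metadata: list[SampleMetadata] = []
    truth = SimTruth(seed=seed)
    for spec in clade_specs:
        r, m, t = simulate_clade(spec, clock, hotspots, seed, reference, focal_region)
        records.extend(r)
        metadata.extend(m)
        truth.clades.extend(t.clades)
        truth.tip_metadata.update(t.tip_metadata)
    rng = _clade_rng(seed, "__background__")
    weights = hotspots.site_weights(reference.length)
    base_seq = np.array(list(reference.bases))
    k = 0
    for loc, region, n in background.groups:
        for _ in range(n):
            k += 1
            sid = f"BG{k}_{loc}"
            seq = _mutate_branch(base_seq, background.divergence_years, clock, weights, rng)
            records.append((sid, "".join(seq)))
            md = SampleMetadata(sid, loc, region)
            metadata.append(md)
            truth.tip_metadata[sid] = md
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise SimulationError("sample id collision across clades/background")
    return records, metadata, truth


def simulate_locality_structure(
    n_per_locality: Mapping[str, int],
    differentiation: float,
    seed: int = 0,
    clock: ClockParams = ClockParams(),
    reference: ReferenceGenome | None = None,
    pool_size: int = 8,
    pool_divergence_years: float = 15000.0,
    within_pool_years: float = 1500.0,
    macro_region: str = DEFAULT_FOCAL_REGION,
) -> tuple[list[tuple[str, str]], list[SampleMetadata]]:
    """Multi-locality panel with tunable among-locality differentiation.

    ``differentiation = 0`` draws every sample's haplotype from one shared
    pool (an exchangeable null, so AMOVA among-locality variance is
    centred at zero); ``differentiation = f`` draws from a locality-private
    pool with probability ``f`` and the shared pool otherwise. Each pool
    descends from its own founder (``pool_divergence_years`` from the
    reference) with shallow internal diversity (``within_pool_years``), so
    large pool divergence with ``differentiation`` near 1 drives Φst
    toward 1.
    """
    if not 0.0 <= differentiation < 1.0 + 1e-12:
        raise SimulationError("differentiation must lie in [0, 1]")
    if len(n_per_locality) < 2:
        raise SimulationError("need at least 2 localities")
    if reference is None:
        reference = ReferenceGenome.synthetic(clock.genome_length, seed=0)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    weights = UNIFORM_SITES.site_weights(reference.length)
    base_seq = np.array(list(reference.bases))

    def make_pool() -> list[str]:
        founder = _mutate_branch(base_seq, pool_divergence_years, clock, weights, rng)
        return ["".join(_mutate_branch(founder, within_pool_years, clock, weights, rng))
                for _ in range(pool_size)]

    shared = make_pool()
    private = {loc: make_pool() for loc in sorted(n_per_locality)}
    records: list[tuple[str, str]] = []
    metadata: list[SampleMetadata] = []
    for loc in sorted(n_per_locality):
        for i in range(n_per_locality[loc]):
            pool = private[loc] if rng.random() < differentiation else shared
            hap = pool[rng.integers(len(pool))]
            sid = f"{loc}_{i + 1}"
            records.append((sid, hap))
            metadata.append(SampleMetadata(sid, loc, macro_region))
    return records, metadata


def profiles_from_records(records: Sequence[tuple[str, str]],
                          reference: ReferenceGenome) -> list[VariantProfile]:
    """Convenience: variant-call every simulated sequence.

    Identical sequences (frequent in pool-based simulations) are diffed
    against the reference only once.
    """
    cache: dict[str, VariantProfile] = {}
    out: list[VariantProfile] = []
    for sid, seq in records:
        hit = cache.get(seq)
        if hit is None:
            hit = call_variants(seq, reference, sid)
            cache[seq] = hit
        out.append(VariantProfile(sid, hit.mutations, hit.missing))
    return out


def write_panel(outdir: str | Path, records: Sequence[tuple[str, str]],
                metadata: Sequence[SampleMetadata], truth: SimTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sequences(outdir / "sequences.fasta", records)
    write_metadata(outdir / "metadata.tsv", metadata)
    if truth is not None:
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
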