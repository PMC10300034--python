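"""Reference coordinates, mutation notation, and file IO.

Everything downstream works on :class:`VariantProfile` objects: a sample's
mutations relative to a fixed mitochondrial reference coordinate system
(by convention the 16,569-base rCRS). Conventions used throughout the
package:

* coordinates are 1-based and intervals are closed on both ends;
* mutations are written phylotree-style: ``A16183C`` (substitution),
  ``309.1C`` (first inserted base after position 309), ``16189d``
  (deletion);
* ``N`` and IUPAC ambiguity codes are missing data — they never produce a
  mutation and their positions are excluded from pairwise comparisons
  (pairwise deletion);
* input mitogenomes must already be aligned to reference coordinates; the
  FASTA mode cannot represent insertions, so the variant-table input mode
  must be used when insertions matter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

RCRS_LENGTH = 16569
HVS1_WINDOW = (16024, 16365)

_BASES = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
# IUPAC ambiguity codes (plus N): treated as missing data, not as variants.
_AMBIGUOUS = frozenset("RYSWKMBDHVN")
_MUT_RE = re.compile(
    r"^(?:(?P<ref>[ACGT])(?P<pos>\d+)(?P<alt>[ACGT])"  # substitution A263G
    r"|(?P<ipos>\d+)\.(?P<idx>\d+)(?P<ibase>[ACGT])"   # insertion 309.1C
    r"|(?P<dpos>\d+)(?:d|del|DEL)"                     # deletion 16189d
    r")(?P<back>!?)$"
)


class RefIOError(ValueError):
    """Malformed sequence, variant, or table input."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular mitochondrial reference of fixed length."""

    name: str = "rCRS"
    length: int = RCRS_LENGTH
    circular: bool = True
    bases: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != self.length:
            raise RefIOError(
                f"reference '{self.name}': bases length {len(self.bases)} != declared {self.length}"
            )
        bad = set(self.bases) - _BASES
        if bad:
            raise RefIOError(f"reference '{self.name}': non-ACGT characters {sorted(bad)}")

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise RefIOError(f"position {position} outside [1, {self.length}]")
        return self.bases[position - 1]

    @classmethod
    def synthetic(cls, length: int = RCRS_LENGTH, seed: int = 0, name: str = "synthetic-ref") -> "ReferenceGenome":
        """Deterministic synthetic reference (random ACGT string).

        A stand-in used for simulation and testing; it is *not* the rCRS.
        Real-data runs must load the actual reference with
        :func:`load_reference`.
        """
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGT"), size=length))
        return cls(name=name, length=length, bases=bases)


def load_reference(path: str | Path, name: str | None = None) -> ReferenceGenome:
    """Load a single-record reference FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise RefIOError(f"reference FASTA must hold exactly 1 record, found {len(records)}")
    seq = str(records[0].seq).upper()
    return ReferenceGenome(name=name or records[0].id, length=len(seq), bases=seq)


@dataclass(frozen=True, order=True)
class Mutation:
    """One mutation in phylotree-style notation, relative to the reference.

    ``insertion_index`` is 0 for substitutions/deletions and k for the k-th
    base inserted after ``position``.
    """

    position: int
    insertion_index: int
    ref_allele: str
    alt_allele: str
    kind: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("transition", "transversion", "insertion", "deletion"):
            raise RefIOError(f"unknown mutation kind {self.kind!r}")
        if (self.kind == "insertion") != (self.insertion_index > 0):
            raise RefIOError(f"insertion_index {self.insertion_index} inconsistent with kind {self.kind}")
        if self.kind in ("transition", "transversion"):
            pair = (self.ref_allele, self.alt_allele)
            is_ts = pair in _TRANSITIONS
            if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
                raise RefIOError(f"substitution alleles must be bases: {self.canonical()}")
            if self.ref_allele == self.alt_allele:
                raise RefIOError(f"ref equals alt at {self.position}")
            if is_ts != (self.kind == "transition"):
                raise RefIOError(f"kind {self.kind} inconsistent with alleles {pair}")
        elif self.kind == "deletion" and self.alt_allele != "-":
            raise RefIOError("deletion must have alt '-'")
        elif self.kind == "insertion" and self.ref_allele != "-":
            raise RefIOError("insertion must have ref '-'")

    def canonical(self) -> str:
        if self.kind == "insertion":
            return f"{self.position}.{self.insertion_index}{self.alt_allele}"
        if self.kind == "deletion":
            return f"{self.position}d"
        return f"{self.ref_allele}{self.position}{self.alt_allele}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()

    @property
    def site(self) -> tuple[int, int]:
        """(position, insertion_index) — the unit of site identity."""
        return (self.position, self.insertion_index)


def substitution(ref: str, position: int, alt: str) -> Mutation:
    kind = "transition" if (ref, alt) in _TRANSITIONS else "transversion"
    return Mutation(position, 0, ref, alt, kind)


def parse_mutation(text: str, reference: ReferenceGenome | None = None) -> Mutation:
    """Parse phylotree-style notation (``A263G``, ``309.1C``, ``16189d``).

    A trailing ``!`` (phylotree back-mutation marker) is rejected here; it
    is meaningful only inside haplogroup-tree files, where the tree loader
    strips it before calling this function.
    """
    m = _MUT_RE.match(text.strip())
    if not m or m.group("back"):
        raise RefIOError(f"unparseable mutation {text!r}")
    if m.group("ref"):
        mut = substitution(m.group("ref"), int(m.group("pos")), m.group("alt"))
    elif m.group("ipos"):
        mut = Mutation(int(m.group("ipos")), int(m.group("idx")), "-", m.group("ibase"), "insertion")
    else:
        pos = int(m.group("dpos"))
        ref = reference.base_at(pos) if reference is not None else "N"
        mut = Mutation(pos, 0, ref if ref in _BASES else "A", "-", "deletion")
    if reference is not None and mut.kind != "insertion" and not 1 <= mut.position <= reference.length:
        raise RefIOError(f"mutation {text!r} outside reference [1, {reference.length}]")
    return mut


@dataclass(frozen=True)
class VariantProfile:
    """A sample's mutations, canonically sorted by (position, insertion_index).

    ``missing`` holds 1-based positions where the sample carries N or an
    ambiguity code; those sites are unknown rather than reference-equal.
    Canonical ordering makes profile equality textual equality.
    """

    sample_id: str
    mutations: tuple[Mutation, ...]
    missing: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        sites = [m.site for m in self.mutations]
        if sorted(sites) != sites:
            object.__setattr__(self, "mutations", tuple(sorted(self.mutations)))
            sites = [m.site for m in self.mutations]
        if len(set(sites)) != len(sites):
            dup = [s for s in sites if sites.count(s) > 1][0]
            raise RefIOError(f"sample {self.sample_id}: duplicate mutation at site {dup}")

    def canonical_strings(self) -> tuple[str, ...]:
        return tuple(m.canonical() for m in self.mutations)

    def mutation_set(self) -> frozenset[Mutation]:
        return frozenset(self.mutations)

    def with_mutations(self, mutations: Iterable[Mutation]) -> "VariantProfile":
        return VariantProfile(self.sample_id, tuple(sorted(mutations)), self.missing)


def make_profile(sample_id: str, mutations: Iterable[Mutation | str],
                 missing: Iterable[int] = (), reference: ReferenceGenome | None = None) -> VariantProfile:
    """Build a canonical profile from Mutation objects or notation strings."""
    muts = [parse_mutation(m, reference) if isinstance(m, str) else m for m in mutations]
    return VariantProfile(sample_id, tuple(sorted(muts)), frozenset(missing))


# ---------------------------------------------------------------------------
# Sequence IO and variant calling
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path, reference: ReferenceGenome) -> list[tuple[str, str]]:
    """Read reference-aligned mitogenomes from FASTA.

    Each record must have exactly the reference length (gaps ``-`` encode
    deletions). Record ids are FASTA headers up to the first whitespace.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) != reference.length:
            raise RefIOError(
                f"record '{rec.id}': length {len(seq)} != reference length {reference.length}"
            )
        if rec.id in seen:
            raise RefIOError(f"duplicate sequence id '{rec.id}'")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_sequences(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def call_variants(sequence: str, reference: ReferenceGenome, sample_id: str = "sample") -> VariantProfile:
    """Diff an aligned sequence against the reference.

    One mutation per differing position; ``-`` yields a deletion; N and
    ambiguity codes yield no mutation but are recorded as missing.
    """
    sequence = sequence.upper()
    if len(sequence) != reference.length:
        raise RefIOError(f"sample {sample_id}: length {len(sequence)} != {reference.length}")
    seq_arr = np.frombuffer(sequence.encode("ascii"), dtype="S1")
    ref_arr = np.frombuffer(reference.bases.encode("ascii"), dtype="S1")
    muts: list[Mutation] = []
    missing: set[int] = set()
    for idx in np.nonzero(seq_arr != ref_arr)[0]:
        i = int(idx) + 1
        obs, ref = sequence[idx], reference.bases[idx]
        if obs in _AMBIGUOUS:
            missing.add(i)
        elif obs == "-":
            muts.append(Mutation(i, 0, ref, "-", "deletion"))
        elif obs in _BASES:
            muts.append(substitution(ref, i, obs))
        else:
            raise RefIOError(f"sample {sample_id}: non-IUPAC character {obs!r} at position {i}")
    return VariantProfile(sample_id, tuple(muts), frozenset(missing))


def reconstruct_sequence(profile: VariantProfile, reference: ReferenceGenome) -> str:
    """Invert :func:`call_variants` (substitutions and deletions only)."""
    seq = list(reference.bases)
    for m in profile.mutations:
        if m.kind == "insertion":
            raise RefIOError("cannot place insertions in fixed-coordinate sequence")
        seq[m.position - 1] = m.alt_allele
    for pos in profile.missing:
        seq[pos - 1] = "N"
    return "".join(seq)


def extract_hvs1(profile: VariantProfile, window: tuple[int, int] = HVS1_WINDOW) -> VariantProfile:
    """Restrict a profile to the HVS-I control-region window (closed interval)."""
    lo, hi = window
    if lo > hi:
        raise RefIOError(f"empty window [{lo}, {hi}]")
    muts = tuple(m for m in profile.mutations if lo <= m.position <= hi)
    missing = frozenset(p for p in profile.missing if lo <= p <= hi)
    return VariantProfile(profile.sample_id, muts, missing)


# ---------------------------------------------------------------------------
# Recurrent-site mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrentSiteMask:
    """Positions and specific mutations excluded from clade definitions and
    mutation counts because they recur across the mtDNA phylogeny.

    ``masked_insertions`` masks every insertion after a given position
    regardless of index or base (the classic 309/315/573 poly-C stutter).
    """

    masked_positions: frozenset[int] = frozenset()
    masked_mutations: frozenset[str] = frozenset()
    masked_insertions: frozenset[int] = frozenset()

    def is_masked(self, mutation: Mutation) -> bool:
        return (
            mutation.position in self.masked_positions
            or mutation.canonical() in self.masked_mutations
            or (mutation.kind == "insertion" and mutation.position in self.masked_insertions)
        )

    def filter(self, profile: VariantProfile) -> VariantProfile:
        return profile.with_mutations(m for m in profile.mutations if not self.is_masked(m))

    def __or__(self, other: "RecurrentSiteMask") -> "RecurrentSiteMask":
        return RecurrentSiteMask(
            self.masked_positions | other.masked_positions,
            self.masked_mutations | other.masked_mutations,
            self.masked_insertions | other.masked_insertions,
        )


EMPTY_MASK = RecurrentSiteMask()


def load_mask(path: str | Path) -> RecurrentSiteMask:
    """Load a two-column TSV mask: kind in {position, mutation, insertion}."""
    positions: set[int] = set()
    mutations: set[str] = set()
    insertions: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("kind\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RefIOError(f"{path}:{lineno}: expected 2 tab-separated fields")
            kind, value = parts[0].strip(), parts[1].strip()
            try:
                if kind == "position":
                    positions.add(int(value))
                elif kind == "insertion":
                    insertions.add(int(value))
                elif kind == "mutation":
                    parse_mutation(value)
                    mutations.add(value)
                else:
                    raise ValueError(f"unknown kind {kind!r}")
            except (ValueError, RefIOError) as exc:
                raise RefIOError(f"{path}:{lineno}: {exc}") from exc
    return RecurrentSiteMask(frozenset(positions), frozenset(mutations), frozenset(insertions))


def default_mask() -> RecurrentSiteMask:
    """The bundled default recurrent-site mask (user-overridable data)."""
    return load_mask(Path(__file__).parent / "data" / "default_mask.tsv")


# ---------------------------------------------------------------------------
# Tables: variant tables and sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMetadata:
    """Sampling locality and macro-region label for one sample."""

    sample_id: str
    locality: str
    macro_region: str

    def is_focal(self, focal_region: str) -> bool:
        return self.macro_region == focal_region


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    needed = {"sample_id", "locality", "macro_region"}
    if not needed <= set(df.columns):
        raise RefIOError(f"metadata missing columns {sorted(needed - set(df.columns))}")
    out: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        if row.sample_id in out:
            raise RefIOError(f"duplicate metadata sample_id '{row.sample_id}'")
        out[row.sample_id] = SampleMetadata(row.sample_id, row.locality, row.macro_region)
    return out


def write_metadata(path: str | Path, metadata: Iterable[SampleMetadata]) -> None:
    pd.DataFrame(
        [(m.sample_id, m.locality, m.macro_region) for m in metadata],
        columns=["sample_id", "locality", "macro_region"],
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path, reference: ReferenceGenome | None = None) -> list[VariantProfile]:
    """Read a long-format variant table: sample, position, insertion_index, ref, alt.

    This mode (unlike FASTA) can represent insertions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    needed = {"sample_id", "position", "insertion_index", "ref", "alt"}
    if not needed <= set(df.columns):
        raise RefIOError(f"variant table missing columns {sorted(needed - set(df.columns))}")
    by_sample: dict[str, list[Mutation]] = {}
    for row in df.itertuples(index=False):
        by_sample.setdefault(row.sample_id, [])
        pos, idx = int(row.position), int(row.insertion_index)
        ref, alt = row.ref, row.alt
        if idx > 0:
            mut = Mutation(pos, idx, "-", alt, "insertion")
        elif alt == "-":
            mut = Mutation(pos, 0, ref, "-", "deletion")
        else:
            mut = substitution(ref, pos, alt)
        by_sample[row.sample_id].append(mut)
    return [make_profile(sid, muts) for sid, muts in by_sample.items()]


def write_variant_table(path: str | Path, profiles: Iterable[VariantProfile]) -> None:
    rows = [
        (p.sample_id, m.position, m.insertion_index, m.ref_allele, m.alt_allele, m.kind)
        for p in profiles
        for m in p.mutations
    ]
    pd.DataFrame(rows, columns=["sample_id", "position", "insertion_index", "ref", "alt", "kind"]).to_csv(
        path, sep="\t", index=False
    )
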